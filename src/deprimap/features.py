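"""Land-cover feature extraction.

Derives the five land-cover variables used by the canonical analysis —
the percentages of corrugated-roof (CO), white-painted-roof (WP),
tile-roof (TR) and pavement (PA) pixels among impervious pixels, plus a
texture statistic TX (standard deviation of the high-pass-filtered red
band) — at two supports: per census tract, and per pixel over a moving
3x3 window for map downscaling. Also includes a Gaussian
maximum-likelihood classifier for producing a land-cover grid from
multiband imagery.

Composition percentages use the impervious denominator ("proportion of
corrugated roofs per impervious surfaces"); an all-pixels denominator is
available as a sensitivity switch. Window statistics use shrunken
windows at grid borders — no wrap-around, no fabricated pixels — and
population (divide-by-n) standard deviations throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

from .classes import IMPERVIOUS_CLASSES, LANDCOVER_FEATURES, LandCover, is_impervious

__all__ = [
    "ClassModel",
    "classify_max_likelihood",
    "high_pass_filter",
    "texture_sd",
    "tract_composition",
    "window_feature_stack",
    "WindowFeatureStack",
]

log = logging.getLogger(__name__)

_ONES3 = np.ones((3, 3))


@dataclass(frozen=True)
class ClassModel:
    """Gaussian class model for maximum-likelihood classification."""

    name: str
    mean: np.ndarray
    cov: np.ndarray
    prior: float = 1.0

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if cov.shape != (mean.size, mean.size):
            raise ValueError(f"class {self.name!r}: covariance shape {cov.shape} "
                             f"does not match mean dimension {mean.size}")
        if not np.allclose(cov, cov.T):
            raise ValueError(f"class {self.name!r}: covariance not symmetric")


def classify_max_likelihood(bands: np.ndarray, models: Sequence[ClassModel],
                            codes: Sequence[int] | None = None) -> np.ndarray:
    """Assign each pixel the class maximizing Gaussian log-likelihood + log prior.

    *bands* has shape ``(height, width, n_bands)`` (a trailing axis of 1 may
    be omitted for single-band input). Ties are broken by declared model
    order. *codes* maps model index to output code (default 1..len(models)).
    """
    bands = np.asarray(bands, dtype=float)
    if bands.ndim == 2:
        bands = bands[:, :, None]
    h, w, d = bands.shape
    flat = bands.reshape(-1, d)
    scores = np.empty((len(models), h * w))
    for k, m in enumerate(models):
        if m.mean.size != d:
            raise ValueError(f"class {m.name!r}: model dimension {m.mean.size} "
                             f"does not match band count {d}")
        try:
            chol = np.linalg.cholesky(m.cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"class {m.name!r}: singular covariance matrix") from exc
        z = np.linalg.solve(chol, (flat - m.mean).T)
        maha = (z**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        scores[k] = np.log(m.prior) - 0.5 * (maha + logdet + d * np.log(2 * np.pi))
    best = scores.argmax(axis=0)  # argmax takes the FIRST maximal index: declared order
    if codes is None:
        codes = range(1, len(models) + 1)
    code_arr = np.asarray(list(codes))
    return code_arr[best].reshape(h, w)


def high_pass_filter(red: np.ndarray) -> np.ndarray:
    """3x3 high-pass (edge-enhancing) filter of the red band.

    Interior kernel: center 8, each of the 8 neighbours -1 (zero-sum, so
    constant and linear-ramp fields map to zero). Border cells use the
    shrunken-window analogue: center weighted by the number of available
    neighbours, each available neighbour -1.
    """
    red = np.asarray(red, dtype=float)
    if red.size == 0:
        raise ValueError("empty grid")
    window_sum = convolve(red, _ONES3, mode="constant", cval=0.0)
    window_n = convolve(np.ones_like(red), _ONES3, mode="constant", cval=0.0)
    neighbour_sum = window_sum - red
    neighbour_n = window_n - 1.0
    return neighbour_n * red - neighbour_sum


def texture_sd(filtered: np.ndarray, region: np.ndarray | None = None) -> float:
    """Population standard deviation of filtered values over a region.

    *region* is a boolean mask (None = whole grid). Shift-invariant by
    construction; zero for constant regions.
    """
    filtered = np.asarray(filtered, dtype=float)
    values = filtered if region is None else filtered[region]
    if values.size == 0:
        raise ValueError("empty region")
    return float(np.std(values))


def tract_composition(landcover: np.ndarray, tracts: np.ndarray,
                      filtered: np.ndarray) -> pd.DataFrame:
    """Per-tract land-cover feature table (CO, WP, TR, PA, TX).

    CO/WP/TR/PA are percentages of the tract's impervious pixels in each
    built class; TX is the population SD of the high-pass-filtered red band
    over ALL tract pixels. Tracts without any impervious pixel get
    ``defined=False`` and NaN compositions (they cannot enter the canonical
    analysis).
    """
    if not (landcover.shape == tracts.shape == filtered.shape):
        raise ValueError("landcover, tracts and filtered grids must be aligned")
    ids = tracts.ravel()
    n = int(ids.max())
    counts = {}
    for cls in IMPERVIOUS_CLASSES:
        counts[cls] = np.bincount(ids, weights=(landcover == cls).ravel().astype(float),
                                  minlength=n + 1)[1:]
    imperv = sum(counts.values())
    records = []
    fgrid = filtered.ravel()
    order = np.argsort(ids, kind="stable")
    bounds = np.searchsorted(ids[order], np.arange(1, n + 2))
    for t in range(1, n + 1):
        sel = order[bounds[t - 1]:bounds[t]]
        tx = float(np.std(fgrid[sel])) if sel.size else np.nan
        denom = imperv[t - 1]
        if denom > 0:
            rec = {
                "tract_id": t,
                "CO": 100.0 * counts[LandCover.CORRUGATED][t - 1] / denom,
                "WP": 100.0 * counts[LandCover.WHITE_PAINTED][t - 1] / denom,
                "TR": 100.0 * counts[LandCover.TILE][t - 1] / denom,
                "PA": 100.0 * counts[LandCover.PAVEMENT][t - 1] / denom,
                "TX": tx,
                "defined": True,
            }
        else:
            rec = {"tract_id": t, "CO": np.nan, "WP": np.nan, "TR": np.nan,
                   "PA": np.nan, "TX": tx, "defined": False}
        records.append(rec)
    table = pd.DataFrame(records)
    n_undef = int((~table["defined"]).sum())
    if n_undef:
        log.warning("%d tract(s) have no impervious pixels; composition undefined", n_undef)
    return table


@dataclass
class WindowFeatureStack:
    """Per-pixel 3x3-window land-cover features.

    ``features`` maps each of CO, WP, TR, PA, TX to a grid aligned with the
    source land-cover grid; ``mask`` is True where the features are defined
    (at least one impervious pixel in the window).
    """

    features: dict[str, np.ndarray]
    mask: np.ndarray

    def as_array(self) -> np.ndarray:
        """Stack in canonical variable order, shape (height, width, 5)."""
        return np.stack([self.features[k] for k in LANDCOVER_FEATURES], axis=-1)


def window_feature_stack(landcover: np.ndarray, filtered: np.ndarray,
                         *, denominator: str = "impervious") -> WindowFeatureStack:
    """Moving 3x3-window analogue of :func:`tract_composition`.

    Windows shrink at the borders. With the default ``denominator=
    "impervious"`` the composition percentages divide by the impervious
    pixel count in the window, mirroring the tract-level definition; pixels
    whose window holds no impervious pixel are masked. ``denominator=
    "all"`` divides by the window pixel count instead (sensitivity mode; no
    masking from the denominator). TX is the population SD of the filtered
    values in the window.
    """
    if landcover.shape != filtered.shape:
        raise ValueError("landcover and filtered grids must be aligned")
    if denominator not in ("impervious", "all"):
        raise ValueError("denominator must be 'impervious' or 'all'")
    window_n = convolve(np.ones(landcover.shape), _ONES3, mode="constant", cval=0.0)

    class_counts = {}
    for name, cls in zip(("CO", "WP", "TR", "PA"),
                         IMPERVIOUS_CLASSES):
        class_counts[name] = convolve((landcover == cls).astype(float), _ONES3,
                                      mode="constant", cval=0.0)
    imperv_n = convolve(is_impervious(landcover).astype(float), _ONES3,
                        mode="constant", cval=0.0)

    if denominator == "impervious":
        denom = imperv_n
        mask = imperv_n > 0
    else:
        denom = window_n
        mask = np.ones_like(imperv_n, dtype=bool)
    safe = np.where(denom > 0, denom, 1.0)

    feats = {name: np.where(mask, 100.0 * cnt / safe, np.nan)
             for name, cnt in class_counts.items()}

    fsum = convolve(filtered, _ONES3, mode="constant", cval=0.0)
    fsq = convolve(filtered**2, _ONES3, mode="constant", cval=0.0)
    mean = fsum / window_n
    var = np.maximum(fsq / window_n - mean**2, 0.0)
    feats["TX"] = np.where(mask, np.sqrt(var), np.nan)
    return WindowFeatureStack(features=feats, mask=mask)
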