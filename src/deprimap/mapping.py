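"""Pixel-level deprivation mapping from a fitted canonical model.

The first canonical dimension is strongly driven by land cover, so it is
mapped at the pixel level: each pixel's 3x3-window land-cover features
(CO, WP, TR, PA, TX) are combined linearly using the dimension-1
land-cover loadings as weights. The second dimension is dominated by
socioeconomic variables, so it is computed per census tract from the
dimension-2 socioeconomic loadings and broadcast to every pixel of the
tract. The combined deprivation score weights the two dimension scores
by their canonical correlations. Non-urban pixels (water, vegetation,
sand, exposed soil, cloud, nodata) are masked out.

Two modes are offered. ``"standardized"`` (default) applies the loadings
to transformed-and-standardized variable values using the constants
captured when the model was fitted — the scale on which the loadings
were estimated. ``"raw"`` applies the loadings directly to raw percent /
raw variable values, reproducing the published map-algebra equations
literally; note that on raw scales a large-valued variable (income, in
currency units) dominates the linear combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classes import LANDCOVER_FEATURES, SOCIO_FEATURES, is_impervious
from .features import WindowFeatureStack
from .transforms import TransformSpec, apply_standardization, transform_feature_values

__all__ = [
    "DeprivationGrid",
    "dimension1_grid",
    "dimension2_grid",
    "combine_dimensions",
    "urban_mask",
    "tract_mean_scores",
    "score_feature_rows",
]


@dataclass
class DeprivationGrid:
    """Per-pixel deprivation scores; masked (invalid) cells hold NaN."""

    d1: np.ndarray
    d2: np.ndarray
    combined: np.ndarray
    mask: np.ndarray  # True = valid urban pixel with defined scores


def _check_loadings(loadings: np.ndarray, expected: int, what: str) -> np.ndarray:
    loadings = np.asarray(loadings, dtype=float).ravel()
    if loadings.size != expected:
        raise ValueError(f"{what} loading vector must have {expected} entries, "
                         f"got {loadings.size}")
    return loadings


def score_feature_rows(values: np.ndarray, loadings: np.ndarray,
                       names: list[str], *, mode: str = "raw",
                       spec: TransformSpec | None = None) -> np.ndarray:
    """Linear deprivation score of feature rows (last axis = variables)."""
    loadings = _check_loadings(loadings, len(names), "feature")
    values = np.asarray(values, dtype=float)
    if mode == "raw":
        return values @ loadings
    if mode == "standardized":
        if spec is None:
            raise ValueError("standardized mode requires a fitted TransformSpec")
        transformed = transform_feature_values(values, names, spec)
        return apply_standardization(transformed, names, spec) @ loadings
    raise ValueError(f"unknown mode {mode!r}; expected 'raw' or 'standardized'")


def dimension1_grid(stack: WindowFeatureStack, loadings1: np.ndarray,
                    *, mode: str = "standardized",
                    spec: TransformSpec | None = None) -> np.ndarray:
    """Dimension-1 score per pixel from window land-cover features.

    ``loadings1`` is the first-dimension land-cover loading vector over
    (CO, WP, TR, PA, TX), taken from a fitted model (or a published
    reference). Pixels masked in the stack come back NaN.
    """
    loadings1 = _check_loadings(loadings1, 5, "land-cover")
    values = stack.as_array()
    scores = score_feature_rows(values, loadings1, list(LANDCOVER_FEATURES),
                                mode=mode, spec=spec)
    return np.where(stack.mask, scores, np.nan)


def dimension2_grid(census: pd.DataFrame, tracts: np.ndarray,
                    loadings2: np.ndarray, *, mode: str = "standardized",
                    spec: TransformSpec | None = None) -> np.ndarray:
    """Dimension-2 score broadcast from tracts to pixels.

    Each tract's socioeconomic record (BA, WA, GA, IN, CR) is combined
    with the second-dimension socioeconomic loadings, then painted onto
    all of the tract's pixels (the raster analogue of a polygon fill).
    """
    loadings2 = _check_loadings(loadings2, 5, "socioeconomic")
    ids_in_grid = np.unique(tracts)
    ids_in_grid = ids_in_grid[ids_in_grid > 0]
    table_ids = set(int(t) for t in census["tract_id"])
    missing = [int(t) for t in ids_in_grid if int(t) not in table_ids]
    if missing:
        raise ValueError(f"tract id(s) present in grid but missing from census table: "
                         f"{missing[:20]}{'...' if len(missing) > 20 else ''}")
    values = census[list(SOCIO_FEATURES)].to_numpy(dtype=float)
    tract_scores = score_feature_rows(values, loadings2, list(SOCIO_FEATURES),
                                      mode=mode, spec=spec)
    lut = np.full(int(tracts.max()) + 1, np.nan)
    lut[census["tract_id"].to_numpy(dtype=int)] = tract_scores
    return lut[tracts]


def combine_dimensions(d1: np.ndarray, d2: np.ndarray,
                       w1: float, w2: float) -> np.ndarray:
    """``w1*d1 + w2*d2`` per pixel; the weights are the canonical correlations."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError(f"dimension grids misaligned: {d1.shape} vs {d2.shape}")
    return w1 * d1 + w2 * d2


def urban_mask(landcover: np.ndarray) -> np.ndarray:
    """True exactly for the built classes (roofs, pavement).

    Water, vegetation, sand, exposed soil, cloud and nodata are all
    excluded from the final deprivation map.
    """
    return is_impervious(landcover)


def make_deprivation_grid(d1: np.ndarray, d2: np.ndarray, w1: float, w2: float,
                          landcover: np.ndarray) -> DeprivationGrid:
    """Combine the dimension grids and apply the urban mask."""
    combined = combine_dimensions(d1, d2, w1, w2)
    mask = urban_mask(landcover) & ~np.isnan(combined)
    return DeprivationGrid(
        d1=np.where(mask, d1, np.nan),
        d2=np.where(mask, d2, np.nan),
        combined=np.where(mask, combined, np.nan),
        mask=mask,
    )


def tract_mean_scores(grid: DeprivationGrid, tracts: np.ndarray) -> pd.DataFrame:
    """Per-tract mean scores over valid pixels (canonical-space summaries).

    Tracts with no valid (urban, defined) pixel are flagged
    ``defined=False`` with NaN means.
    """
    if grid.combined.shape != tracts.shape:
        raise ValueError("score grid and tract grid must be aligned")
    n = int(tracts.max())
    ids = tracts.ravel()
    valid = grid.mask.ravel()
    rows = []
    counts = np.bincount(ids[valid], minlength=n + 1)
    sums = {
        name: np.bincount(ids[valid], weights=layer.ravel()[valid], minlength=n + 1)
        for name, layer in (("d1", grid.d1), ("d2", grid.d2),
                            ("combined", grid.combined))
    }
    for t in range(1, n + 1):
        c = int(counts[t])
        rows.append({
            "tract_id": t,
            "mean_d1": sums["d1"][t] / c if c else np.nan,
            "mean_d2": sums["d2"][t] / c if c else np.nan,
            "mean_combined": sums["combined"][t] / c if c else np.nan,
            "n_valid": c,
            "defined": c > 0,
        })
    return pd.DataFrame(rows)
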