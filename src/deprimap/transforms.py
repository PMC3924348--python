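"""Variable transformations and the linearity screen.

Income is natural-log transformed; proportion variables (both the census
proportions and the land-cover composition percentages rescaled to
[0, 1]) are arcsine-square-root transformed, the standard
variance-stabilising choice for 0- and 1-inflated proportions; texture
is left as is. Transformed variables are then column-standardised
(z-scores, population SD) and the fit-time constants are retained so the
same affine map can later be applied to per-pixel features when
projecting canonical scores onto the map.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classes import LANDCOVER_FEATURES, SOCIO_FEATURES

__all__ = [
    "TransformSpec",
    "arcsine_sqrt",
    "transform_variables",
    "standardize",
    "apply_standardization",
    "linearity_screen",
]

#: transform kind per variable; land-cover percents are rescaled by 1/100 first.
VARIABLE_TRANSFORMS: dict[str, str] = {
    "BA": "arcsine_sqrt", "WA": "arcsine_sqrt", "GA": "arcsine_sqrt",
    "IN": "log", "CR": "arcsine_sqrt",
    "CO": "arcsine_sqrt", "WP": "arcsine_sqrt", "TR": "arcsine_sqrt",
    "PA": "arcsine_sqrt", "TX": "identity",
}

PERCENT_SCALE_VARS = frozenset({"CO", "WP", "TR", "PA"})


@dataclass
class TransformSpec:
    """Transform kinds plus standardization constants captured at fit time."""

    transforms: dict[str, str] = field(default_factory=lambda: dict(VARIABLE_TRANSFORMS))
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"transforms": self.transforms, "means": self.means,
                           "sds": self.sds}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TransformSpec":
        d = json.loads(text)
        return cls(transforms=d["transforms"], means=d["means"], sds=d["sds"])


def arcsine_sqrt(p: np.ndarray | float) -> np.ndarray | float:
    """asin(sqrt(p)): 0 -> 0, 0.5 -> pi/4, 1 -> pi/2; monotone on [0, 1]."""
    return np.arcsin(np.sqrt(p))


def _transform_column(values: np.ndarray, name: str, kind: str) -> np.ndarray:
    if kind == "log":
        if (values <= 0).any():
            bad = int(np.flatnonzero(values <= 0)[0])
            raise ValueError(f"variable {name}: non-positive value at row {bad}; "
                             "log transform requires positive input")
        return np.log(values)
    if kind == "arcsine_sqrt":
        p = values / 100.0 if name in PERCENT_SCALE_VARS else values
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            bad = int(np.flatnonzero((p < -1e-12) | (p > 1 + 1e-12))[0])
            raise ValueError(f"variable {name}: proportion outside [0, 1] at row {bad}")
        return np.asarray(arcsine_sqrt(np.clip(p, 0.0, 1.0)))
    if kind == "identity":
        return values.astype(float)
    raise ValueError(f"unknown transform kind {kind!r} for variable {name}")


def transform_variables(census: pd.DataFrame, features: pd.DataFrame,
                        spec: TransformSpec | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, TransformSpec]:
    """Apply per-variable transforms to the paired census / land-cover tables.

    Rows are aligned on ``tract_id`` (tracts with undefined land-cover
    features, flagged ``defined=False``, are dropped from both sides).
    Returns the transformed socioeconomic table, the transformed land-cover
    table, and the spec used.
    """
    spec = spec or TransformSpec()
    feats = features
    if "defined" in feats.columns:
        feats = feats[feats["defined"].astype(bool)]
    merged_ids = pd.Index(census["tract_id"]).intersection(pd.Index(feats["tract_id"]))
    cen = census.set_index("tract_id").loc[merged_ids]
    lc = feats.set_index("tract_id").loc[merged_ids]

    socio = pd.DataFrame({
        v: _transform_column(cen[v].to_numpy(dtype=float), v, spec.transforms[v])
        for v in SOCIO_FEATURES
    }, index=merged_ids)
    land = pd.DataFrame({
        v: _transform_column(lc[v].to_numpy(dtype=float), v, spec.transforms[v])
        for v in LANDCOVER_FEATURES
    }, index=merged_ids)
    socio.index.name = land.index.name = "tract_id"
    return socio, land, spec


def standardize(table: pd.DataFrame, spec: TransformSpec) -> pd.DataFrame:
    """Column z-scores with population SD; constants stored on *spec*."""
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        mu, sd = float(x.mean()), float(x.std())
        if sd == 0.0:
            raise ValueError(f"variable {col} has zero variance; cannot standardize")
        spec.means[col], spec.sds[col] = mu, sd
        out[col] = (x - mu) / sd
    return pd.DataFrame(out, index=table.index)


def apply_standardization(values: np.ndarray, names: list[str],
                          spec: TransformSpec) -> np.ndarray:
    """Apply stored fit-time constants to new data (last axis = variables)."""
    mu = np.array([spec.means[v] for v in names])
    sd = np.array([spec.sds[v] for v in names])
    return (np.asarray(values, dtype=float) - mu) / sd


def transform_feature_values(values: np.ndarray, names: list[str],
                             spec: TransformSpec) -> np.ndarray:
    """Apply the per-variable transforms to an array (last axis = variables).

    NaN cells propagate (used for masked window features).
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for j, name in enumerate(names):
        kind = spec.transforms[name]
        col = values[..., j]
        valid = ~np.isnan(col)
        res = np.full(col.shape, np.nan)
        if valid.any():
            res[valid] = _transform_column(col[valid].ravel(), name, kind)
        out[..., j] = res
    return out


def linearity_screen(socio: pd.DataFrame, landcover: pd.DataFrame,
                     threshold: float = 0.1) -> pd.DataFrame:
    """All cross-set Pearson correlations, flagging weakly linear pairs.

    The canonical analysis assumes an (approximately) linear relation
    between the two variable sets; this screen operationalises the visual
    scatter-plot check as a report. It is advisory only — it never drops a
    variable.
    """
    if len(socio) != len(landcover):
        raise ValueError("tables must have equal row counts")
    if len(socio) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    rows = []
    for sv in socio.columns:
        x = socio[sv].to_numpy(dtype=float)
        for lv in landcover.columns:
            y = landcover[lv].to_numpy(dtype=float)
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"socio": sv, "landcover": lv, "pearson_r": r,
                         "flagged": bool(abs(r) < threshold or math.isnan(r))})
    return pd.DataFrame(rows)
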