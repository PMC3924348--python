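"""Canonical correlation analysis with a sequential dimensionality test.

Given two variable sets measured on the same observations — here the
socioeconomic set (bathroom, water, garbage, income, crowding) and the
land-cover set (CO, WP, TR, PA, TX) per census tract — CCA finds paired
linear combinations ("canonical variates") ``Xa_k`` and ``Yb_k`` that
maximise their mutual Pearson correlation ``r_k``, subject to each new
pair being uncorrelated with all earlier pairs within its own set.

The implementation whitens the within-set correlation matrices with
symmetric inverse square roots and takes the singular value
decomposition of the whitened cross-correlation matrix

    K = Rxx^{-1/2} Rxy Ryy^{-1/2} = U diag(r) V',

so the canonical correlations are the singular values of ``K`` and the
standardized weights are ``A = Rxx^{-1/2} U``, ``B = Ryy^{-1/2} V``.
Dimensionality is assessed by the sequential Wilks'-lambda test with
Bartlett's chi-squared approximation.

Canonical directions are sign-indeterminate; see :func:`fit_cca` for the
anchor rule used to fix orientation reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CCAModel",
    "fit_cca",
    "canonical_loadings",
    "canonical_scores",
    "dimensionality_test",
    "n_significant",
]


@dataclass
class CCAModel:
    """Fitted canonical correlation model.

    Coefficients are *standardized* weights: they apply to column z-scores
    of the input tables (the fit-time centers/scales are stored). Loadings
    are the Pearson correlations between each original variable and its own
    set's canonical variates.
    """

    n_obs: int
    x_names: list[str]
    y_names: list[str]
    correlations: np.ndarray  # (m,) descending, in [0, 1]
    x_coefficients: np.ndarray  # (p, m)
    y_coefficients: np.ndarray  # (q, m)
    x_loadings: np.ndarray  # (p, m)
    y_loadings: np.ndarray  # (q, m)
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    transform_spec: object | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return len(self.x_names)

    @property
    def q(self) -> int:
        return len(self.y_names)

    @property
    def m(self) -> int:
        return len(self.correlations)

    def to_json(self) -> str:
        d = {
            "n_obs": self.n_obs,
            "x_names": self.x_names, "y_names": self.y_names,
            "correlations": self.correlations.tolist(),
            "x_coefficients": self.x_coefficients.tolist(),
            "y_coefficients": self.y_coefficients.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_center": self.x_center.tolist(), "x_scale": self.x_scale.tolist(),
            "y_center": self.y_center.tolist(), "y_scale": self.y_scale.tolist(),
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CCAModel":
        d = json.loads(text)
        arrays = {k: np.asarray(d[k], dtype=float)
                  for k in ("correlations", "x_coefficients", "y_coefficients",
                            "x_loadings", "y_loadings", "x_center", "x_scale",
                            "y_center", "y_scale")}
        return cls(n_obs=int(d["n_obs"]), x_names=list(d["x_names"]),
                   y_names=list(d["y_names"]), **arrays)


def _as_matrix(table: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), [str(c) for c in table.columns]
    arr = np.asarray(table, dtype=float)
    return arr, [f"v{j}" for j in range(arr.shape[1])]

def _inv_sqrt(R: np.ndarray, name: str, ridge: float) -> np.ndarray:
    if ridge:
        R = R + ridge * np.eye(len(R))
    w, V = np.linalg.eigh(R)
    if w.min() <= 1e-10 * w.max():
        raise np.linalg.LinAlgError(
            f"{name} within-set correlation matrix is (near-)singular "
            f"(min eigenvalue {w.min():.3e}); consider the ridge option")
    return (V / np.sqrt(w)) @ V.T


def fit_cca(X: pd.DataFrame | np.ndarray, Y: pd.DataFrame | np.ndarray,
            *, ridge: float = 0.0, anchor: str | int | None = None,
            transform_spec: object | None = None) -> CCAModel:
    """Fit canonical correlations between variable sets *X* and *Y*.

    Columns are standardized internally (population SD), so results are
    invariant to positive rescaling of any input column. ``ridge`` adds a
    diagonal term to the within-set correlation matrices for near-singular
    inputs (default 0: exact CCA).

    Orientation: each canonical pair ``(a_k, b_k)`` is flipped jointly
    (which leaves ``r_k`` unchanged) so that dimension 1 has a *negative*
    loading on the anchor variable (default: the column named ``IN`` —
    income — when present, so deprivation loads positive; otherwise the
    last X column), and every later dimension has its largest-magnitude X
    loading positive.
    """
    Xm, x_names = _as_matrix(X)
    Ym, y_names = _as_matrix(Y)
    if Xm.ndim != 2 or Ym.ndim != 2 or Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y must be 2-D with equal row counts")
    n, p = Xm.shape
    q = Ym.shape[1]
    if n <= p + q:
        raise ValueError(f"need more observations than variables (n={n}, p+q={p + q})")
    if not (np.isfinite(Xm).all() and np.isfinite(Ym).all()):
        raise ValueError("inputs contain non-finite values")

    x_center, x_scale = Xm.mean(axis=0), Xm.std(axis=0)
    y_center, y_scale = Ym.mean(axis=0), Ym.std(axis=0)
    for scale, names in ((x_scale, x_names), (y_scale, y_names)):
        if (scale == 0).any():
            bad = [names[j] for j in np.flatnonzero(scale == 0)]
            raise ValueError(f"constant column(s): {bad}")
    Zx = (Xm - x_center) / x_scale
    Zy = (Ym - y_center) / y_scale

    Rxx = Zx.T @ Zx / n
    Ryy = Zy.T @ Zy / n
    Rxy = Zx.T @ Zy / n
    Wx = _inv_sqrt(Rxx, "X", ridge)
    Wy = _inv_sqrt(Ryy, "Y", ridge)
    U, s, Vt = np.linalg.svd(Wx @ Rxy @ Wy)
    m = min(p, q)
    r = np.clip(s[:m], 0.0, 1.0)
    A = Wx @ U[:, :m]
    B = Wy @ Vt[:m].T

    # loadings: correlation of each (standardized) variable with its variate
    x_load = Rxx @ A
    y_load = Ryy @ B

    # orientation anchor rule
    if anchor is None:
        anchor_idx = x_names.index("IN") if "IN" in x_names else p - 1
    elif isinstance(anchor, int):
        anchor_idx = anchor
    else:
        if anchor not in x_names:
            raise ValueError(f"anchor variable {anchor!r} not among X columns {x_names}")
        anchor_idx = x_names.index(anchor)
    for k in range(m):
        if k == 0:
            flip = x_load[anchor_idx, 0] > 0
        else:
            j = int(np.abs(x_load[:, k]).argmax())
            flip = x_load[j, k] < 0
        if flip:
            A[:, k] *= -1
            B[:, k] *= -1
            x_load[:, k] *= -1
            y_load[:, k] *= -1

    return CCAModel(
        n_obs=n, x_names=x_names, y_names=y_names,
        correlations=r, x_coefficients=A, y_coefficients=B,
        x_loadings=np.clip(x_load, -1.0, 1.0), y_loadings=np.clip(y_load, -1.0, 1.0),
        x_center=x_center, x_scale=x_scale, y_center=y_center, y_scale=y_scale,
        transform_spec=transform_spec,
    )


def canonical_scores(model: CCAModel, X: pd.DataFrame | np.ndarray,
                     Y: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation canonical variate values ``Xa_k`` and ``Yb_k``."""
    Xm, _ = _as_matrix(X)
    Ym, _ = _as_matrix(Y)
    if Xm.shape[1] != model.p or Ym.shape[1] != model.q:
        raise ValueError(
            f"column mismatch: expected p={model.p}, q={model.q}, "
            f"got {Xm.shape[1]}, {Ym.shape[1]}")
    Zx = (Xm - model.x_center) / model.x_scale
    Zy = (Ym - model.y_center) / model.y_scale
    return Zx @ model.x_coefficients, Zy @ model.y_coefficients


def canonical_loadings(model: CCAModel, X: pd.DataFrame | np.ndarray,
                       Y: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Loadings recomputed as direct Pearson correlations on the data.

    Entry ``(j, k)`` is the correlation between variable *j* and its own
    set's *k*-th canonical variate. On the fitting data this equals the
    stored ``model.x_loadings`` / ``model.y_loadings``.
    """
    xs, ys = canonical_scores(model, X, Y)
    Xm, _ = _as_matrix(X)
    Ym, _ = _as_matrix(Y)

    def corr_cols(vars_: np.ndarray, scores: np.ndarray) -> np.ndarray:
        v = (vars_ - vars_.mean(axis=0)) / vars_.std(axis=0)
        s_sd = scores.std(axis=0)
        s = (scores - scores.mean(axis=0)) / np.where(s_sd > 0, s_sd, 1.0)
        return v.T @ s / len(v)

    return corr_cols(Xm, xs), corr_cols(Ym, ys)


def dimensionality_test(correlations: np.ndarray | "CCAModel",
                        n_obs: int | None = None,
                        p: int | None = None, q: int | None = None) -> pd.DataFrame:
    """Sequential Wilks'-lambda test of the number of canonical dimensions.

    For each dimension k (1-based), tests the null that correlations k..m
    are all zero:

        lambda_k = prod_{j>=k} (1 - r_j^2)
        chi2_k   = -[N - 1 - (p + q + 1)/2] * ln(lambda_k)
        df_k     = (p - k + 1)(q - k + 1)

    with the chi-squared upper-tail p-value (Bartlett's approximation).
    Also reports the eigenvalue ``r_k^2 / (1 - r_k^2)`` of each dimension.
    Accepts either a fitted :class:`CCAModel` or an explicit vector of
    canonical correlations plus ``n_obs``, ``p``, ``q``.
    """
    if isinstance(correlations, CCAModel):
        model = correlations
        r = np.asarray(model.correlations, dtype=float)
        n_obs, p, q = model.n_obs, model.p, model.q
    else:
        r = np.asarray(correlations, dtype=float)
        if n_obs is None or p is None or q is None:
            raise ValueError("n_obs, p and q are required with an explicit r vector")
    m = len(r)
    r2 = r**2
    one_minus = 1.0 - r2
    # lambda_k = prod_{j=k}^{m}(1 - r_j^2), via reversed cumulative product
    lam = np.cumprod(one_minus[::-1])[::-1]
    with np.errstate(divide="ignore"):
        eig = np.where(one_minus > 0, r2 / one_minus, np.inf)
    mult = n_obs - 1 - (p + q + 1) / 2.0
    with np.errstate(divide="ignore"):
        chi2 = -mult * np.log(lam)
    ks = np.arange(1, m + 1)
    df = (p - ks + 1) * (q - ks + 1)
    pval = stats.chi2.sf(chi2, df)
    return pd.DataFrame({
        "dimension": ks,
        "canonical_correlation": r,
        "wilks_lambda": lam,
        "eigenvalue": eig,
        "chi_squared": chi2,
        "df": df,
        "p_value": pval,
    })


def n_significant(test: pd.DataFrame, alpha: float = 0.05) -> int:
    """Number of leading dimensions significant at level *alpha*.

    Counts sequentially from dimension 1 and stops at the first
    non-significant test, matching the nested structure of the hypotheses.
    """
    sig = (test["p_value"].to_numpy() < alpha)
    count = 0
    for flag in sig:
        if not flag:
            break
        count += 1
    return count
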