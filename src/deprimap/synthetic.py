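"""Synthetic city generator.

Simulates the joint structure that the deprivation-mapping analysis
assumes: a latent spatial "deprivation" field drives both the per-pixel
land cover (more corrugated roofing, less pavement and texture where
deprivation is high) and the tract-aggregated socioeconomic variables
(lower income, more crowding, poorer sanitation). Tract geometry is
produced by seeded region growth so that tract pixel counts vary over
orders of magnitude, as real census tracts do.

Every generator is deterministic given its seed. Stage sub-streams are
derived from the master seed through ``numpy`` seed sequences with fixed
per-stage spawn keys, so each stage is independently reproducible.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classes import LandCover, NODATA
from .fuzzy import AssessmentSite

__all__ = [
    "SimConfig",
    "SyntheticCity",
    "generate_latent_field",
    "partition_tracts",
    "sample_landcover",
    "synthesize_red_band",
    "synthesize_census",
    "generate_city",
    "generate_accuracy_fixture",
]

# Stage spawn keys for sub-stream derivation from the master seed.
_STAGE_LATENT, _STAGE_TRACTS, _STAGE_LANDCOVER, _STAGE_RED, _STAGE_CENSUS = range(5)

#: Nominal red-band base reflectance per class code (index = code, 0 unused).
_RED_BASE = np.array([0.0, 60.0, 95.0, 75.0, 55.0, 20.0, 40.0, 90.0, 70.0, 100.0])


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic city.

    The latent field is unitless with typical scale ``latent_sd``; land-cover
    effects are log-odds slopes per unit latent value; census slopes act on
    the logit (proportions) or log (income) scale, with tract-level noise
    ``noise_sd_census`` added on that same transformed scale.
    """

    grid_height: int = 60
    grid_width: int = 60
    n_tracts: int = 100
    latent_mean: float = 0.0
    latent_sd: float = 1.0
    smoothing_radius: int = 2
    # class order: corrugated, white, tile, pavement, water, vegetation, sand, soil, cloud
    landcover_base_probs: tuple[float, ...] = (
        0.20, 0.05, 0.10, 0.15, 0.05, 0.25, 0.05, 0.10, 0.05,
    )
    landcover_effect: tuple[float, ...] = (0.0,) * 9
    income_intercept: float = 6.0
    income_slope: float = 0.0
    # order: BA, WA, GA, CR (logit scale; the WA slope enters with a minus sign)
    proportion_intercepts: tuple[float, float, float, float] = (-3.8, 2.5, -3.1, -1.76)
    proportion_slopes: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    noise_sd_census: float = 0.0
    texture_contrast_slope: float = 0.0
    red_noise_base: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_height <= 0 or self.grid_width <= 0:
            raise ConfigError("grid dimensions must be positive")
        if not (1 <= self.n_tracts <= self.grid_height * self.grid_width):
            raise ConfigError("n_tracts must be in [1, grid_height*grid_width]")
        probs = np.asarray(self.landcover_base_probs, dtype=float)
        if probs.shape != (9,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigError("landcover_base_probs must be 9 non-negative values summing to 1")
        if len(self.landcover_effect) != 9:
            raise ConfigError("landcover_effect must have 9 entries")
        for name in ("latent_sd", "noise_sd_census", "red_noise_base"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.smoothing_radius < 0:
            raise ConfigError("smoothing_radius must be non-negative")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))

    @classmethod
    def null_coupling(cls, seed: int = 0, *, n_tracts: int = 100) -> "SimConfig":
        """City with NO latent coupling: land cover and census are independent.

        Census noise is kept positive so the socioeconomic variables still
        vary between tracts (otherwise they would be constant and the
        correlation analysis degenerate).
        """
        return cls(
            grid_height=48,
            grid_width=48,
            n_tracts=n_tracts,
            noise_sd_census=0.4,
            texture_contrast_slope=0.0,
            seed=seed,
        )

    @classmethod
    def strong_coupling(cls, seed: int = 0, *, n_tracts: int = 500) -> "SimConfig":
        """City with a single strong latent factor coupling both variable sets.

        Effect sizes and census noise were calibrated once so that the
        population canonical correlation between the tract-level land-cover
        composition and the census variables (after the standard transforms)
        is close to 0.7; see :data:`STRONG_COUPLING_POPULATION_R1`.
        """
        return cls(
            grid_height=120,
            grid_width=120,
            n_tracts=n_tracts,
            smoothing_radius=3,
            landcover_effect=(1.5, -0.85, -0.5, -1.0, 0.0, 0.15, 0.0, 0.3, 0.0),
            income_slope=0.8,
            proportion_slopes=(1.0, 1.0, 1.0, 0.8),
            noise_sd_census=0.35,
            texture_contrast_slope=0.3,
            seed=seed,
        )


@dataclass
class SyntheticCity:
    """Bundle of all generated layers plus the generating truth record."""

    latent: np.ndarray
    tracts: np.ndarray
    landcover: np.ndarray
    red_band: np.ndarray
    census: pd.DataFrame
    truth: dict = field(default_factory=dict)


def generate_latent_field(config: SimConfig) -> np.ndarray:
    """Gaussian white noise smoothed by a uniform moving average.

    The moving-average window is ``(2r+1) x (2r+1)`` with reflected borders;
    radius 0 returns plain white noise. The result has spatial
    autocorrelation increasing with the radius, standing in for the smooth
    deprivation gradients of a real city.
    """
    rng = _stage_rng(config.seed, _STAGE_LATENT)
    noise = rng.normal(config.latent_mean, config.latent_sd,
                       size=(config.grid_height, config.grid_width))
    if config.smoothing_radius == 0:
        return noise
    from scipy.ndimage import uniform_filter

    smoothed = uniform_filter(noise, size=2 * config.smoothing_radius + 1, mode="reflect")
    # restore the configured marginal SD lost to averaging
    sd = smoothed.std()
    if sd > 0 and config.latent_sd > 0:
        smoothed = config.latent_mean + (smoothed - smoothed.mean()) * (config.latent_sd / sd)
    return smoothed


def partition_tracts(height: int, width: int, n_tracts: int, seed: int) -> np.ndarray:
    """Partition the grid into 4-connected tracts by seeded region growth.

    ``n_tracts`` seed pixels are drawn at random; regions then grow by
    first-passage competition with per-tract log-normal growth rates, which
    yields tract pixel counts spanning orders of magnitude (real census
    tracts range from a handful to thousands of pixels). Every pixel is
    assigned; ids are exactly ``1..n_tracts``.
    """
    if height <= 0 or width <= 0:
        raise ConfigError("grid dimensions must be positive")
    if not (1 <= n_tracts <= height * width):
        raise ConfigError("n_tracts must be in [1, height*width]")
    rng = _stage_rng(seed, _STAGE_TRACTS)
    ids = np.zeros((height, width), dtype=np.int32)
    starts = rng.choice(height * width, size=n_tracts, replace=False)
    rates = rng.lognormal(mean=0.0, sigma=1.2, size=n_tracts)
    heap: list[tuple[float, int, int, int, int]] = []
    counter = 0
    for t, flat in enumerate(starts, start=1):
        r, c = divmod(int(flat), width)
        heap.append((0.0, counter, r, c, t))
        counter += 1
    heapq.heapify(heap)
    n_assigned = 0
    total = height * width
    while heap and n_assigned < total:
        t_arrive, _, r, c, tract = heapq.heappop(heap)
        if ids[r, c]:
            continue
        ids[r, c] = tract
        n_assigned += 1
        rate = rates[tract - 1]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < height and 0 <= nc < width and not ids[nr, nc]:
                cost = rng.exponential(1.0 / rate)
                heapq.heappush(heap, (t_arrive + cost, counter, nr, nc, tract))
                counter += 1
    return ids


def sample_landcover(latent: np.ndarray, config: SimConfig) -> np.ndarray:
    """Draw a land-cover class per pixel from a latent-shifted multinomial.

    The log-odds of each class relative to its base probability shift
    linearly in the latent value with slope ``landcover_effect``; a positive
    corrugated-roof effect concentrates corrugated roofing where latent
    deprivation is high.
    """
    if latent.shape != (config.grid_height, config.grid_width):
        raise ConfigError("latent field dims do not match config")
    rng = _stage_rng(config.seed, _STAGE_LANDCOVER)
    base = np.asarray(config.landcover_base_probs, dtype=float)
    effect = np.asarray(config.landcover_effect, dtype=float)
    with np.errstate(divide="ignore"):
        logits = np.log(base)[None, None, :] + latent[:, :, None] * effect[None, None, :]
    logits -= logits.max(axis=2, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=2, keepdims=True)
    u = rng.random(size=latent.shape)
    cum = np.cumsum(probs, axis=2)
    codes = (u[:, :, None] >= cum).sum(axis=2) + 1  # class codes 1..9
    return codes.astype(np.int16)


def class_probabilities(latent_value: float, config: SimConfig) -> np.ndarray:
    """Per-class probabilities at a single latent value (for analysis/tests)."""
    base = np.asarray(config.landcover_base_probs, dtype=float)
    effect = np.asarray(config.landcover_effect, dtype=float)
    with np.errstate(divide="ignore"):
        logits = np.log(base) + latent_value * effect
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def synthesize_red_band(latent: np.ndarray, landcover: np.ndarray,
                        config: SimConfig) -> np.ndarray:
    """Red-band intensity: class base reflectance plus latent-damped noise.

    The white-noise amplitude is ``red_noise_base * exp(-slope * latent)``,
    so high-deprivation (high-latent) areas are more spatially homogeneous —
    they show less local texture — matching the observation that informal
    settlements have fewer building/road edges at 30 m than wealthier areas.
    """
    if latent.shape != landcover.shape:
        raise ConfigError("latent and landcover dims do not match")
    rng = _stage_rng(config.seed, _STAGE_RED)
    base = _RED_BASE[landcover]
    amp = config.red_noise_base * np.exp(-config.texture_contrast_slope * latent)
    return base + amp * rng.normal(size=latent.shape)


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def synthesize_census(latent: np.ndarray, tracts: np.ndarray,
                      config: SimConfig) -> pd.DataFrame:
    """Tract socioeconomic table driven by the tract-mean latent value.

    With tract mean latent ``L``: income ``IN = exp(a - b*L + e)``;
    bathroom-less, garbage and crowding proportions ``inv_logit(c + s*L + e)``;
    piped water ``inv_logit(c - s*L + e)`` (access falls with deprivation);
    ``e ~ N(0, noise_sd_census)`` independently per tract and variable, added
    on the log/logit scale so back-transformed values stay in range.
    """
    if latent.shape != tracts.shape:
        raise ConfigError("latent and tract dims do not match")
    rng = _stage_rng(config.seed, _STAGE_CENSUS)
    n = int(tracts.max())
    flat_ids = tracts.ravel()
    sums = np.bincount(flat_ids, weights=latent.ravel(), minlength=n + 1)[1:]
    counts = np.bincount(flat_ids, minlength=n + 1)[1:]
    lbar = sums / counts
    eps = rng.normal(0.0, config.noise_sd_census, size=(n, 5))
    c_ba, c_wa, c_ga, c_cr = config.proportion_intercepts
    s_ba, s_wa, s_ga, s_cr = config.proportion_slopes
    ba = _inv_logit(c_ba + s_ba * lbar + eps[:, 0])
    wa = _inv_logit(c_wa - s_wa * lbar + eps[:, 1])
    ga = _inv_logit(c_ga + s_ga * lbar + eps[:, 2])
    cr = _inv_logit(c_cr + s_cr * lbar + eps[:, 4])
    income = np.exp(config.income_intercept - config.income_slope * lbar + eps[:, 3])
    return pd.DataFrame({
        "tract_id": np.arange(1, n + 1),
        "BA": np.clip(ba, 0.0, 1.0),
        "WA": np.clip(wa, 0.0, 1.0),
        "GA": np.clip(ga, 0.0, 1.0),
        "IN": income,
        "CR": np.clip(cr, 0.0, 1.0),
    })


def generate_city(config: SimConfig) -> SyntheticCity:
    """Compose all generators into a full synthetic city bundle."""
    latent = generate_latent_field(config)
    tracts = partition_tracts(config.grid_height, config.grid_width,
                              config.n_tracts, config.seed)
    landcover = sample_landcover(latent, config)
    red = synthesize_red_band(latent, landcover, config)
    census = synthesize_census(latent, tracts, config)
    truth = {
        "seed": config.seed,
        "n_tracts": config.n_tracts,
        "latent_sd": config.latent_sd,
        "landcover_effect": list(config.landcover_effect),
        "income_slope": config.income_slope,
        "proportion_slopes": list(config.proportion_slopes),
        "noise_sd_census": config.noise_sd_census,
        "texture_contrast_slope": config.texture_contrast_slope,
    }
    return SyntheticCity(latent=latent, tracts=tracts, landcover=landcover,
                         red_band=red, census=census, truth=truth)


def generate_accuracy_fixture(
    n_sites: int,
    classes: Sequence[str],
    confusion: np.ndarray,
    heterogeneity_rate: float,
    seed: int,
) -> list[AssessmentSite]:
    """Simulate map-validation sites with a controlled confusion structure.

    Each site draws a reference (true) class uniformly, then a classified
    label from that reference's row of the row-stochastic *confusion*
    matrix. Matching sites get a high presence fraction of the classified
    class (uniform on [0.5, 1]); mismatches a low one (uniform on [0, 0.5)).
    A ``heterogeneity_rate`` share of sites is flagged as too heterogeneous
    to carry a dominant reference class.
    """
    confusion = np.asarray(confusion, dtype=float)
    k = len(classes)
    if confusion.shape != (k, k) or (confusion < 0).any() or \
            not np.allclose(confusion.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigError("confusion must be a row-stochastic matrix over the classes")
    if not (0.0 <= heterogeneity_rate <= 1.0):
        raise ConfigError("heterogeneity_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sites: list[AssessmentSite] = []
    for i in range(n_sites):
        ref_idx = int(rng.integers(k))
        cls_idx = int(rng.choice(k, p=confusion[ref_idx]))
        heterogeneous = bool(rng.random() < heterogeneity_rate)
        if cls_idx == ref_idx and not heterogeneous:
            fraction = float(rng.uniform(0.5, 1.0))
        else:
            fraction = float(rng.uniform(0.0, 0.5))
        sites.append(AssessmentSite(
            site_id=i + 1,
            classified=classes[cls_idx],
            reference=None if heterogeneous else classes[ref_idx],
            presence_fraction=fraction,
        ))
    return sites
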