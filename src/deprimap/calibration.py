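"""Helpers tying the simulator to the canonical analysis.

Used for calibration-style computations: extracting the paired
tract-level variable tables from a synthetic city, fitting the canonical
model on one city, and estimating the *population* first canonical
correlation of a simulation configuration by pooling tracts from many
independent cities (the pooled fit is effectively unbiased, unlike the
per-city estimate at a few hundred tracts).
"""

from __future__ import annotations

import pandas as pd

from .cca import CCAModel, fit_cca
from .features import high_pass_filter, tract_composition
from .synthetic import SimConfig, SyntheticCity, generate_city
from .transforms import TransformSpec, standardize, transform_variables

__all__ = ["city_variable_tables", "fit_city", "population_canonical_r1"]

#: Pooled-fit estimate of the first population canonical correlation of
#: ``SimConfig.strong_coupling()`` (25k tracts across 60 cities); the preset's
#: effect sizes were chosen so this sits near 0.7.
STRONG_COUPLING_POPULATION_R1 = 0.705


def city_variable_tables(city: SyntheticCity) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transformed (socioeconomic, land-cover) tract tables of a city.

    Tracts without impervious pixels are dropped (their composition is
    undefined); tables are aligned on tract id and transformed but not yet
    standardized.
    """
    filtered = high_pass_filter(city.red_band)
    feats = tract_composition(city.landcover, city.tracts, filtered)
    socio_t, land_t, _ = transform_variables(city.census, feats)
    return socio_t, land_t


def fit_city(config: SimConfig) -> CCAModel:
    """Generate a city and fit the canonical model on its tract tables."""
    socio_t, land_t = city_variable_tables(generate_city(config))
    spec = TransformSpec()
    return fit_cca(standardize(socio_t, spec), standardize(land_t, spec),
                   transform_spec=spec)


def population_canonical_r1(config: SimConfig, n_cities: int = 30,
                            base_seed: int = 0) -> float:
    """Pooled-fit estimate of the first population canonical correlation.

    Concatenates the tract tables of ``n_cities`` independent cities drawn
    from *config* (seeds ``base_seed .. base_seed + n_cities - 1``) and fits
    a single canonical model; with tens of thousands of pooled tracts the
    small-sample upward bias of the per-city estimate vanishes.
    """
    socios, lands = [], []
    for k in range(n_cities):
        s, l = city_variable_tables(generate_city(config.with_seed(base_seed + k)))
        socios.append(s)
        lands.append(l)
    spec = TransformSpec()
    socio = standardize(pd.concat(socios, ignore_index=True), spec)
    land = standardize(pd.concat(lands, ignore_index=True), spec)
    return float(fit_cca(socio, land).correlations[0])
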