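"""End-to-end pipeline orchestration.

Runs simulate (or load) -> land-cover features -> transforms -> CCA ->
dimensionality test -> deprivation map -> tract summaries, writing every
intermediate product plus a JSON manifest of seeds, versions and output
checksums so runs are fully reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cca import dimensionality_test, fit_cca, n_significant
from .features import high_pass_filter, tract_composition, window_feature_stack
from .gridio import read_grid, read_table, write_grid, write_table
from .mapping import (dimension1_grid, dimension2_grid, make_deprivation_grid,
                      tract_mean_scores)
from .synthetic import SimConfig, generate_city
from .transforms import TransformSpec, linearity_screen, standardize, transform_variables

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run.

    Either a ``sim`` block (synthetic city) or explicit input paths
    (``landcover_path``, ``red_band_path``, ``tracts_path``, ``census_path``)
    must be provided.
    """

    out_dir: str = "deprimap_run"
    seed: int = 0
    sim: SimConfig | None = None
    landcover_path: str | None = None
    red_band_path: str | None = None
    tracts_path: str | None = None
    census_path: str | None = None
    screen_threshold: float = 0.1
    ridge: float = 0.0
    anchor: str = "IN"
    alpha: float = 0.05
    mapping_mode: str = "standardized"  # or "raw"
    window_denominator: str = "impervious"
    cellsize: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.mapping_mode not in ("standardized", "raw"):
            raise ValueError("mapping_mode must be 'standardized' or 'raw'")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        sim = data.pop("sim", None)
        cfg = cls(**data)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": []}

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    # --- inputs -----------------------------------------------------------
    if config.sim is not None:
        stage("simulate")
        city = generate_city(config.sim.with_seed(config.seed))
        landcover, red, tracts, census = (city.landcover, city.red_band,
                                          city.tracts, city.census)
        manifest["truth"] = city.truth
        write_grid(out / "landcover.asc", landcover, cellsize=config.cellsize, nodata=0)
        write_grid(out / "red_band.asc", red, cellsize=config.cellsize)
        write_grid(out / "tracts.asc", tracts, cellsize=config.cellsize)
        write_table(out / "census.csv", census)
    else:
        stage("load")
        missing = [p for p in (config.landcover_path, config.red_band_path,
                               config.tracts_path, config.census_path) if p is None]
        if missing:
            raise ValueError("without a sim block, all four input paths are required")
        landcover, _ = read_grid(config.landcover_path, dtype=np.int16)
        red, _ = read_grid(config.red_band_path)
        tracts, _ = read_grid(config.tracts_path, dtype=np.int32)
        census = read_table(config.census_path,
                            columns=("tract_id", "BA", "WA", "GA", "IN", "CR"))

    # --- features ---------------------------------------------------------
    stage("features")
    filtered = high_pass_filter(red)
    feats = tract_composition(landcover, tracts, filtered)
    write_table(out / "tract_features.csv", feats)

    # --- transforms + screen ---------------------------------------------
    stage("transform")
    socio_t, land_t, spec = transform_variables(census, feats)
    screen = linearity_screen(socio_t, land_t, threshold=config.screen_threshold)
    write_table(out / "linearity_screen.csv", screen)
    socio_z = standardize(socio_t, spec)
    land_z = standardize(land_t, spec)
    (out / "transform_spec.json").write_text(spec.to_json())

    # --- CCA + dimensionality --------------------------------------------
    stage("fit")
    model = fit_cca(socio_z, land_z, ridge=config.ridge, anchor=config.anchor,
                    transform_spec=spec)
    (out / "cca_model.json").write_text(model.to_json())
    test = dimensionality_test(model)
    write_table(out / "dimension_test.csv", test)
    k_sig = n_significant(test, config.alpha)
    manifest["n_significant_dimensions"] = int(k_sig)
    manifest["canonical_correlations"] = model.correlations.tolist()

    # --- mapping ----------------------------------------------------------
    stage("map")
    stack = window_feature_stack(landcover, filtered,
                                 denominator=config.window_denominator)
    spec_for_mode = spec if config.mapping_mode == "standardized" else None
    d1 = dimension1_grid(stack, model.y_loadings[:, 0],
                         mode=config.mapping_mode, spec=spec_for_mode)
    d2_dim = 1 if model.m > 1 else 0
    d2 = dimension2_grid(census, tracts, model.x_loadings[:, d2_dim],
                         mode=config.mapping_mode, spec=spec_for_mode)
    w1 = float(model.correlations[0])
    w2 = float(model.correlations[d2_dim])
    grid = make_deprivation_grid(d1, d2, w1, w2, landcover)
    write_grid(out / "dimension1.asc", grid.d1, cellsize=config.cellsize)
    write_grid(out / "dimension2.asc", grid.d2, cellsize=config.cellsize)
    write_grid(out / "combined.asc", grid.combined, cellsize=config.cellsize)

    stage("summaries")
    summary = tract_mean_scores(grid, tracts)
    write_table(out / "tract_scores.csv", summary)

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.suffix in (".asc", ".csv", ".json") and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
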