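"""Shared fixtures: one full default pipeline run per session plus small regions."""

import dataclasses
from pathlib import Path

import pytest

from ecorisk.config import RegionConfig
from ecorisk.pipeline import PipelineConfig, _stage_seeds, run_pipeline
from ecorisk.synthetic import generate_region


def small_region_config(**overrides) -> RegionConfig:
    """A fast 40x44 region (4 km cells) with the default structure."""
    base = dict(
        grid_rows=40,
        grid_cols=44,
        n_units=48,
        cell_area=16_000_000.0,
        urban_core_centers=[(12.0, 14.0), (26.0, 30.0)],
        seed=7,
    )
    base.update(overrides)
    return RegionConfig(**base)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One end-to-end run of the default pipeline (seed 0), outputs on disk."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(seed=0, outdir=str(outdir))
    report = run_pipeline(cfg, write=True)
    return report, Path(outdir), cfg


@pytest.fixture(scope="session")
def default_region():
    """The region dataset exactly as the default seed-0 pipeline generates it."""
    cfg = PipelineConfig(seed=0)
    region_cfg = dataclasses.replace(cfg.region, seed=_stage_seeds(cfg.seed)[0])
    return generate_region(region_cfg)


@pytest.fixture()
def small_region():
    return generate_region(small_region_config())
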