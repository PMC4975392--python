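"""Shared fixtures: one small and one default-scale synthetic study."""
from __future__ import annotations

import pytest

from coldmeth.pipeline import run_pipeline, simulate_inputs
from coldmeth.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_chroms=2,
        chrom_len=120_000,
        n_genes=70,
        n_repeats_per_class=20,
        n_islands=14,
        n_peaks=600,
        lib_size=60_000,
        n_pathways=12,
        go_terms=60,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def default_study():
    """A study at the generator's default conditions."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A complete pipeline run over a default-scale synthetic study."""
    base = tmp_path_factory.mktemp("pipeline")
    cfg = simulate_inputs(11, base)
    run_pipeline(cfg)
    return cfg
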