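import numpy as np
import pandas as pd
import pytest

from cernamod import diffexpr
from cernamod.io import PipelineConfig
from cernamod.pipeline import run_pipeline
from cernamod.simulate import SimulationConfig, generate_dataset


def small_config(**overrides) -> SimulationConfig:
    """A reduced study: quick to simulate and analyse, same structure."""
    base = dict(
        n_pairs=30,
        n_mrna=150,
        n_lncrna=60,
        n_mirna=40,
        n_de_per_class=20,
        n_triplets=10,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_data():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def small_pipeline_run(small_data):
    dataset, truth = small_data
    cfg = PipelineConfig(seed=3, epochs=40, stability_rounds=5)
    return run_pipeline(dataset, cfg), truth


@pytest.fixture(scope="session")
def default_data():
    """The full-scale study conditions: 100 pairs, 50 planted triplets,
    |log2FC| = 2, triplet strength 0.7."""
    return generate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_de_tables(default_data):
    """Stability-selected DE for mRNA/lncRNA and single-pass miRNA at scale."""
    dataset, _ = default_data
    tables = {}
    for i, c in enumerate(("mrna", "lncrna")):
        tables[c] = diffexpr.stability_select(
            dataset.counts[c], dataset.samples, rounds=50, fraction=0.8, seed=100 + i
        )
    t = diffexpr.test_differential(dataset.counts["mirna"], dataset.samples)
    t["stable"] = t["direction"].to_numpy() != "none"
    tables["mirna"] = t
    return tables


@pytest.fixture(scope="session")
def default_pipeline_run(default_data, tmp_path_factory):
    dataset, truth = default_data
    outdir = tmp_path_factory.mktemp("pipeline_default")
    cfg = PipelineConfig(seed=42, epochs=200)
    result = run_pipeline(dataset, cfg, outdir=outdir)
    return result, truth, outdir, cfg


def logab_of(dataset) -> pd.DataFrame:
    frames = [np.log2(dataset.abundance[c] + 1.0) for c in dataset.abundance]
    return pd.concat(frames, axis=0)
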