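import numpy as np
import pytest

from srnakit.config import PipelineConfig
from srnakit.pipeline import run_pipeline
from srnakit.simulate import PlantedTruth, SimulationSpec, generate_reference


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """A scaled-down study for fast unit tests."""
    return SimulationSpec(
        seed=11,
        n_contigs=2,
        contig_length=20_000,
        n_mirna_loci=4,
        n_tas_loci=2,
        n_cisnat_pairs=3,
        n_mrna_genes=12,
    )


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return generate_reference(small_spec)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic study (seed 1)."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = PipelineConfig(seed=1, outdir=str(outdir))
    result = run_pipeline(config)
    truth = PlantedTruth.from_json(result.truth_path)
    return config, result, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
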