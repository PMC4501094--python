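import pytest

from trfscape.config import RunConfig
from trfscape.pipeline import run_pipeline
from trfscape.synthetic_data import SimulationConfig, generate_genome, simulate_reads
from trfscape.trna_catalog import MatureTRNA


@pytest.fixture(scope="session")
def default_sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_bundle(default_sim_config):
    bundle = generate_genome(default_sim_config)
    simulate_reads(bundle, default_sim_config)
    return bundle


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full pipeline run on the default synthetic study, shared by
    mapping/classification/profiling/acceptance tests."""
    outdir = tmp_path_factory.mktemp("pipeline") / "out"
    config = RunConfig(outdir=str(outdir), seed=11, simulate={})
    return run_pipeline(config)


@pytest.fixture
def toy_trna():
    """A 75-nt mature tRNA with the anticodon at 33-35 (loop 31-37)."""
    stem = "G" * 30  # 5' side filler
    seq = stem + "AT" + "GCC" + "TA" + "C" * 35 + "CCA"
    assert len(seq) == 75
    return MatureTRNA(
        gene_id="toy",
        sequence=seq,
        anticodon="GCC",
        anticodon_start=33,
        anticodon_end=35,
        isotype="Gly",
    )
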