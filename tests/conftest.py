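import pytest

from tandemscape.pipeline import RunConfig, run_pipeline
from tandemscape.synthetic_data import SimConfig, simulate, worked_fixture, write_bundle


@pytest.fixture(scope="session")
def fixture_bundle():
    """Tiny deterministic two-genotype dataset with hand-checkable truth."""
    return worked_fixture()


@pytest.fixture(scope="session")
def fixture_dir(fixture_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_bundle")
    write_bundle(fixture_bundle, out)
    return out


@pytest.fixture(scope="session")
def small_sim():
    """Two-genotype, one-chromosome simulation used across module tests."""
    return simulate(
        SimConfig(n_genotypes=2, n_chromosomes=1, genes_per_chromosome=60, seed=7)
    )


@pytest.fixture(scope="session")
def fixture_result(fixture_dir):
    """Full pipeline result on the worked fixture."""
    return run_pipeline(fixture_dir, RunConfig(seed=1))
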