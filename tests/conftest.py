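import pytest

from targetfuse.pipeline import PipelineConfig, run_pipeline
from targetfuse.synthetic import ScenarioConfig, generate_scenario, write_fixture


def small_config(seed: int = 11) -> ScenarioConfig:
    """Desk-scale scenario for fast integration tests: same structure as
    the default, an order of magnitude smaller."""
    return ScenarioConfig(
        chrom_length=12_000_000,
        n_genes=400,
        n_a_genes=40,
        n_b_genes=15,
        n_c_genes=20,
        n_group1_peaks=120,
        n_group2_peaks=20,
        n_group3_peaks=30,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_scenario():
    return generate_scenario(small_config())


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory, small_scenario):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(small_scenario, d)
    return d


@pytest.fixture(scope="session")
def small_run_dir(small_fixture_dir):
    config = PipelineConfig.from_yaml(
        small_fixture_dir / "config.yaml", out_dir=small_fixture_dir / "out"
    )
    return run_pipeline(config)
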