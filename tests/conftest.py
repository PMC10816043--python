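import pytest
from hypothesis import HealthCheck, settings

from modscreen import (
    RunConfig,
    adrenal_style_config,
    load_packaged_designs,
    load_packaged_table1,
    run_analysis,
    simulate,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_cohort():
    return load_packaged_table1()


@pytest.fixture(scope="session")
def packaged_designs(table1_cohort):
    return {d.analysis_name: d for d in load_packaged_designs(table1_cohort)}


@pytest.fixture(scope="session")
def adrenal_sim(tmp_path_factory):
    """Seed-1 adrenal-style synthetic cohort (the study's default condition)."""
    outdir = tmp_path_factory.mktemp("adrenal_sim")
    return simulate(adrenal_style_config(seed=1), outdir)


@pytest.fixture(scope="session")
def adrenal_run(adrenal_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("adrenal_run")
    config = RunConfig.from_yaml(adrenal_sim.run_config_path)
    return run_analysis(config, outdir / "out")
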