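import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kongsfjorden_run():
    """Ready-made summer-scenario run: (config, records, truth, run_cfg, tables)."""
    from fjordnem.pipeline import RunConfig, run_sources_sinks
    from fjordnem.synthetic import generate_transect, scenario_kongsfjorden_summer

    cfg = scenario_kongsfjorden_summer()
    records, truth = generate_transect(cfg)
    run_cfg = RunConfig(endmembers=cfg.endmember_config())
    tables = run_sources_sinks(records, run_cfg)
    return cfg, records, truth, run_cfg, tables
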