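import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """One simulated fixture set and one full pipeline run, shared."""
    from netpharm.pipeline import config_for_fixture_dir, run, simulate_fixtures

    root = tmp_path_factory.mktemp("pipeline")
    manifest = simulate_fixtures(root / "fx", seed=1)
    cfg = config_for_fixture_dir(root / "fx", seed=1)
    report = run(cfg, root / "out")
    return {
        "root": root,
        "fixtures": root / "fx",
        "out": root / "out",
        "manifest": manifest,
        "config": cfg,
        "report": report,
    }
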