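import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    from fhconcord import load_default_panel

    return load_default_panel()


@pytest.fixture(scope="session")
def ruleset():
    from fhconcord import load_ruleset

    return load_ruleset()


@pytest.fixture(scope="session")
def golden_run(tmp_path_factory, panel):
    """The golden synthetic cohort written to disk and analysed through the
    file-based pipeline — shared across tests that check cohort-level
    numbers."""
    from pathlib import Path

    from fhconcord import RunConfig, golden_config, run_pipeline, simulate_cohort
    from fhconcord.panel import default_panel_path

    tmp = tmp_path_factory.mktemp("golden")
    cohort = simulate_cohort(golden_config(), out_dir=tmp, panel=panel)
    config = RunConfig(
        panel_path=default_panel_path(),
        vcf_path=Path(tmp) / "cohort.vcf",
        annotation_path=Path(tmp) / "annotations.tsv",
        pedigree_path=Path(tmp) / "pedigrees",
        participants_path=Path(tmp) / "participants.tsv",
        out_dir=Path(tmp) / "out",
    )
    result = run_pipeline(config)
    return cohort, result
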