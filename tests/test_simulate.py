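import json

import pytest

from fhconcord import (
    SimulationConfig,
    golden_config,
    run_pipeline_memory,
    simulate_cohort,
)
from fhconcord.errors import ConfigurationError
from fhconcord.report import carrier_counts, cohort_counts
from fhconcord.simulate import GOLDEN_INCREASED_TEMPLATES


def small_config(**kw):
    defaults = dict(
        mode="designed_counts",
        n_participants=120,
        n_fh_available=70,
        n_increased=10,
        carriers_increased=3,
        carriers_average=3,
        carriers_unavailable=2,
        decoy_pool_size=120,
        decoy_rate=1.5,
        seed=42,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfig:
    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(mode="designed_rates", p_carrier_average=1.5)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_participants=100, n_fh_available=200)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(mode="oracle")

    def test_designed_rr_closed_form(self):
        cfg = SimulationConfig(
            mode="designed_rates", p_carrier_increased=0.32, p_carrier_average=0.05
        )
        assert cfg.designed_rr == pytest.approx(6.4)


class TestDeterminism:
    def test_same_seed_same_files(self, tmp_path, panel):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(small_config(), out_dir=d1, panel=panel)
        simulate_cohort(small_config(), out_dir=d2, panel=panel)
        for name in ("cohort.vcf", "annotations.tsv", "participants.tsv", "ground_truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seed_different_data(self, tmp_path, panel):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(small_config(seed=1), out_dir=d1, panel=panel)
        simulate_cohort(small_config(seed=2), out_dir=d2, panel=panel)
        assert (d1 / "cohort.vcf").read_bytes() != (d2 / "cohort.vcf").read_bytes()


class TestNullModel:
    def test_no_familial_variants_and_no_pathogenic_decoys_means_no_carriers(self, panel):
        cfg = SimulationConfig(
            mode="penetrance",
            n_participants=80,
            n_fh_available=80,
            familial_variant_prob=0.0,
            decoy_pool_size=150,
            decoy_rate=2.0,
            seed=5,
        )
        cohort = simulate_cohort(cfg, panel=panel)
        result = run_pipeline_memory(
            cohort.variants, cohort.pedigrees, panel,
            cohort.participants["participant_id"].tolist(),
        )
        assert sum(carrier_counts(result.assessments).values()) == 0
        # with zero carriers every FH-available participant is concordant
        t = result.report.concordance
        assert t.discordant == t.carrier_average + t.noncarrier_increased
        assert t.carrier_increased + t.carrier_average == 0


class TestGroundTruthRecovery:
    def test_triage_recovers_designed_carriers_exactly(self, panel):
        cohort = simulate_cohort(small_config(), panel=panel)
        result = run_pipeline_memory(
            cohort.variants, cohort.pedigrees, panel,
            cohort.participants["participant_id"].tolist(),
        )
        detected = {a.participant_id for a in result.assessments if a.is_carrier}
        truth = {p for p, t in cohort.ground_truth.items() if t["carrier"]}
        assert detected == truth  # sensitivity and specificity both 1.0

    def test_fh_intent_recovered_exactly(self, panel, ruleset):
        from fhconcord import assess_fh_risk

        cohort = simulate_cohort(small_config(), panel=panel)
        for ped in cohort.pedigrees:
            intent = cohort.ground_truth[ped.participant_id]["fh_intent"]
            got = assess_fh_risk(ped, ruleset).cohort
            assert got == intent

    def test_ground_truth_never_read_by_pipeline(self, tmp_path, panel):
        from pathlib import Path

        from fhconcord import RunConfig, run_pipeline
        from fhconcord.panel import default_panel_path

        out = tmp_path / "sim"
        simulate_cohort(small_config(), out_dir=out, panel=panel)
        (out / "ground_truth.json").unlink()  # pipeline must not need it
        result = run_pipeline(
            RunConfig(
                panel_path=default_panel_path(),
                vcf_path=out / "cohort.vcf",
                annotation_path=out / "annotations.tsv",
                pedigree_path=out / "pedigrees",
                participants_path=out / "participants.tsv",
                out_dir=tmp_path / "out",
            )
        )
        assert result.report.baseline["n_total"] == 120


class TestFileMemoryEquivalence:
    def test_both_routes_agree(self, tmp_path, panel):
        from pathlib import Path

        from fhconcord import RunConfig, run_pipeline
        from fhconcord.panel import default_panel_path

        out = tmp_path / "sim"
        cohort = simulate_cohort(small_config(), out_dir=out, panel=panel)
        mem = run_pipeline_memory(
            cohort.variants, cohort.pedigrees, panel,
            cohort.participants["participant_id"].tolist(), cohort.participants,
        )
        file = run_pipeline(
            RunConfig(
                panel_path=default_panel_path(),
                vcf_path=out / "cohort.vcf",
                annotation_path=out / "annotations.tsv",
                pedigree_path=out / "pedigrees",
                participants_path=out / "participants.tsv",
                out_dir=tmp_path / "out",
            )
        )
        assert cohort_counts(mem.assessments) == cohort_counts(file.assessments)
        assert carrier_counts(mem.assessments) == carrier_counts(file.assessments)
        assert mem.triage.funnel == file.triage.funnel


class TestGoldenComposition:
    def test_template_mix_totals(self):
        # 73 families; 42 with more than one distinct cancer type
        assert len(GOLDEN_INCREASED_TEMPLATES) == 73
        multi = [
            t for t in GOLDEN_INCREASED_TEMPLATES
            if t[0] in ("breast_ovarian", "breast_plus", "colorectal_plus")
        ]
        assert len(multi) == 42

    def test_golden_config_counts(self):
        cfg = golden_config()
        assert cfg.n_participants == 1750
        assert cfg.n_fh_available == 866
        assert cfg.n_increased == 73
        assert (cfg.carriers_increased, cfg.carriers_average, cfg.carriers_unavailable) == (10, 17, 17)


class TestManifest:
    def test_rerun_with_same_inputs_gives_identical_report(self, tmp_path, panel):
        from pathlib import Path

        from fhconcord import RunConfig, run_pipeline
        from fhconcord.panel import default_panel_path

        out = tmp_path / "sim"
        simulate_cohort(small_config(), out_dir=out, panel=panel)

        def run_once(dirname):
            run_pipeline(
                RunConfig(
                    panel_path=default_panel_path(),
                    vcf_path=out / "cohort.vcf",
                    annotation_path=out / "annotations.tsv",
                    pedigree_path=out / "pedigrees",
                    participants_path=out / "participants.tsv",
                    out_dir=tmp_path / dirname,
                )
            )
            return (tmp_path / dirname / "cohort_report.json").read_bytes()

        assert run_once("r1") == run_once("r2")

    def test_manifest_records_inputs_and_thresholds(self, tmp_path, panel):
        from pathlib import Path

        from fhconcord import RunConfig, run_pipeline
        from fhconcord.panel import default_panel_path

        out = tmp_path / "sim"
        simulate_cohort(small_config(), out_dir=out, panel=panel)
        run_pipeline(
            RunConfig(
                panel_path=default_panel_path(),
                vcf_path=out / "cohort.vcf",
                annotation_path=out / "annotations.tsv",
                pedigree_path=out / "pedigrees",
                participants_path=out / "participants.tsv",
                out_dir=tmp_path / "out",
            )
        )
        manifest = json.loads((tmp_path / "out" / "run_manifest.json").read_text())
        assert manifest["maf_threshold"] == 0.01
        assert "sha256" in manifest["inputs"]["vcf"]
        assert manifest["funnel"]["carriers"] == 8
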