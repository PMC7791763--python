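import pytest
from hypothesis import given, strategies as st

from fhconcord import Pedigree, RelativeRecord, assess_fh_risk, summarize_family_cancers
from fhconcord.errors import ConfigurationError
from fhconcord.fhrisk import FHRule, Ruleset, load_validation_families
from fhconcord.pedigree import make_diagnosis, pedigree_from_dict


def ped(*relatives, pid="T1"):
    return Pedigree(participant_id=pid, relatives=list(relatives))


def rel(relation, *conds, sex="unknown"):
    diagnoses = [make_diagnosis(c, a) for c, a in conds]
    return RelativeRecord(relation=relation, sex=sex, diagnoses=diagnoses)


class TestRuleFiring:
    def test_empty_history_is_average(self, ruleset):
        r = assess_fh_risk(ped(), ruleset)
        assert r.cohort == "average" and not r.triggered_rules

    def test_no_history_collected_is_not_available(self, ruleset):
        r = assess_fh_risk(Pedigree("T0", fh_available=False), ruleset)
        assert r.cohort == "not_available"

    def test_early_breast_fires(self, ruleset):
        r = assess_fh_risk(ped(rel("mother", ("breast", 42))), ruleset)
        assert r.cohort == "increased" and "breast_early_onset" in r.triggered_rules

    def test_late_single_breast_does_not_fire(self, ruleset):
        r = assess_fh_risk(ped(rel("maternal_grandmother", ("breast", "60s"))), ruleset)
        assert r.cohort == "average"

    def test_ovarian_fires_at_any_age(self, ruleset):
        r = assess_fh_risk(ped(rel("maternal_aunt", ("ovarian", 78))), ruleset)
        assert r.cohort == "increased"

    def test_male_breast_fires(self, ruleset):
        r = assess_fh_risk(ped(rel("father", ("breast", 66))), ruleset)
        assert "male_breast" in r.triggered_rules

    def test_colorectal_cluster_same_lineage_fires(self, ruleset):
        r = assess_fh_risk(
            ped(
                rel("maternal_grandmother", ("colorectal", "50s")),
                rel("maternal_aunt", ("colorectal", "60s")),
            ),
            ruleset,
        )
        assert "colorectal_pair_same_side" in r.triggered_rules

    def test_colorectal_split_across_lineages_does_not_fire(self, ruleset):
        r = assess_fh_risk(
            ped(
                rel("maternal_grandmother", ("colorectal", "50s")),
                rel("paternal_aunt", ("colorectal", "60s")),
            ),
            ruleset,
        )
        assert r.cohort == "average"

    def test_late_lynch_spectrum_pair_does_not_fire(self, ruleset):
        # urothelial 65 + colorectal 76 on one side: no early diagnosis
        r = assess_fh_risk(
            ped(
                rel("father", ("bladder", 65)),
                rel("brother", ("colorectal", 76)),
            ),
            ruleset,
        )
        assert r.cohort == "average"

    def test_sibling_counts_towards_both_lineages(self, ruleset):
        r = assess_fh_risk(
            ped(
                rel("sister", ("colorectal", 60)),
                rel("maternal_aunt", ("colorectal", 62)),
            ),
            ruleset,
        )
        assert "colorectal_pair_same_side" in r.triggered_rules

    def test_cousins_excluded_from_rule_counts(self, ruleset):
        r = assess_fh_risk(
            ped(
                rel("maternal_cousin", ("colorectal", 44)),
                rel("maternal_cousin", ("ovarian", 40)),
            ),
            ruleset,
        )
        assert r.cohort == "average"

    def test_two_early_unknown_cancers_same_side_fire(self, ruleset):
        r = assess_fh_risk(
            ped(
                rel("maternal_uncle", ("unknown cancer", "30s")),
                rel("maternal_aunt", ("unknown cancer", "40s")),
            ),
            ruleset,
        )
        assert "unknown_cancer_pair_early" in r.triggered_rules

    def test_unknown_age_sets_ambiguous_not_increased(self, ruleset):
        r = assess_fh_risk(ped(rel("sister", ("breast", None), sex="F")), ruleset)
        assert r.cohort == "average" and r.ambiguous

    def test_noncancer_conditions_ignored(self, ruleset):
        r = assess_fh_risk(
            ped(rel("mother", ("hypertension", "40s"), ("diabetes", 44))), ruleset
        )
        assert r.cohort == "average" and not r.ambiguous


class TestGoldenHistories:
    def test_published_average_risk_carrier_histories_all_average(self, ruleset):
        fams = load_validation_families()
        results = {
            p.participant_id: assess_fh_risk(p, ruleset) for p in fams["average_risk"]
        }
        assert len(results) == 17
        assert all(r.cohort == "average" for r in results.values())

    def test_colorectal_cluster_family_is_increased(self, ruleset):
        fams = load_validation_families()
        (family,) = fams["increased_risk"]
        r = assess_fh_risk(family, ruleset)
        assert r.cohort == "increased"


class TestProperties:
    def test_rule_firing_is_order_independent(self, ruleset):
        fams = load_validation_families()
        for family in fams["average_risk"] + fams["increased_risk"]:
            reversed_ped = Pedigree(
                family.participant_id, relatives=list(reversed(family.relatives))
            )
            a = assess_fh_risk(family, ruleset)
            b = assess_fh_risk(reversed_ped, ruleset)
            assert (a.cohort, sorted(a.triggered_rules), a.ambiguous) == (
                b.cohort, sorted(b.triggered_rules), b.ambiguous,
            )

    def test_adding_affected_relative_is_monotone(self, ruleset):
        # average -> increased is possible; increased -> average never
        fams = load_validation_families()
        extra = rel("maternal_aunt", ("ovarian", 50))
        for family in fams["average_risk"] + fams["increased_risk"]:
            before = assess_fh_risk(family, ruleset)
            grown = Pedigree(
                family.participant_id, relatives=family.relatives + [extra]
            )
            after = assess_fh_risk(grown, ruleset)
            assert after.cohort == "increased"
            assert set(before.triggered_rules) <= set(after.triggered_rules)

    @given(age=st.integers(min_value=20, max_value=90))
    def test_breast_rule_age_threshold_is_sharp(self, age):
        from fhconcord import load_ruleset

        r = assess_fh_risk(ped(rel("mother", ("breast", age))), load_ruleset())
        assert ("breast_early_onset" in r.triggered_rules) == (age <= 45)


class TestRulesetConfig:
    def test_unknown_cancer_term_rejected(self):
        with pytest.raises(ConfigurationError):
            FHRule(id="bad", cancers=frozenset({"elbow"}))

    def test_duplicate_rule_ids_rejected(self):
        r = FHRule(id="r1", cancers=frozenset({"breast"}))
        with pytest.raises(ConfigurationError):
            Ruleset([r, r])

    def test_custom_ruleset_from_yaml(self, tmp_path):
        import yaml

        doc = {"rules": [{"id": "any_breast", "cancers": ["breast"], "min_count": 1}]}
        path = tmp_path / "rules.yaml"
        path.write_text(yaml.safe_dump(doc))
        from fhconcord import load_ruleset

        rs = load_ruleset(path)
        r = assess_fh_risk(ped(rel("maternal_grandmother", ("breast", "60s"))), rs)
        assert r.cohort == "increased"


class TestSummaries:
    def test_single_family_single_breast(self):
        s = summarize_family_cancers([ped(rel("mother", ("breast", 44)))])
        assert s.percentages == {"breast": 100.0}
        assert s.multi_cancer_fraction == 0.0

    def test_two_families_both_multi_type(self):
        fam = lambda pid: pedigree_from_dict(
            {
                "participant_id": pid,
                "relatives": [
                    {"relation": "mother", "diagnoses": [{"condition": "breast", "age": 50}]},
                    {"relation": "maternal_aunt", "diagnoses": [{"condition": "ovarian", "age": 60}]},
                ],
            }
        )
        s = summarize_family_cancers([fam("A"), fam("B")])
        assert s.multi_cancer_fraction == 1.0
        assert s.percentages == {"breast": 50.0, "ovarian": 50.0}

    def test_empty_subset_gives_empty_summary(self):
        s = summarize_family_cancers([])
        assert s.n_families == 0 and s.n_reports == 0 and s.counts == {}

    def test_unknown_category_retained(self):
        s = summarize_family_cancers(
            [ped(rel("maternal_uncle", ("unknown cancer", "30s")))]
        )
        assert s.counts == {"unknown_primary": 1}
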