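import json

import pytest

from fhconcord import Pedigree, RelativeRecord, parse_pedigree, write_pedigree
from fhconcord.errors import StructureError, VocabularyError
from fhconcord.pedigree import (
    make_diagnosis,
    parse_age,
    parse_ped_file,
    pedigree_from_dict,
    write_ped_file,
)


class TestAges:
    def test_decade_band_maps_to_midpoint(self):
        assert parse_age("50s") == (55, True)
        assert parse_age("40s") == (45, True)

    def test_exact_and_unknown(self):
        assert parse_age(44) == (44, False)
        assert parse_age(None) == (None, False)
        assert parse_age("63y") == (63, False)

    def test_garbage_rejected(self):
        with pytest.raises(VocabularyError):
            parse_age("fifty")


class TestDiagnosis:
    def test_cancer_inferred_from_vocabulary(self):
        d = make_diagnosis("breast", 44)
        assert d.is_cancer and d.cancer_term == "breast"

    def test_alias_normalised(self):
        assert make_diagnosis("bladder", 65).cancer_term == "urothelial"
        assert make_diagnosis("unknown cancer", "30s").cancer_term == "unknown_primary"

    def test_free_text_defaults_to_noncancer(self):
        d = make_diagnosis("hypertension", "60s")
        assert not d.is_cancer and d.cancer_term is None

    def test_explicit_cancer_flag_with_unmapped_site(self):
        d = make_diagnosis("mystery tumour", 50, is_cancer=True)
        assert d.is_cancer and d.cancer_term == "unknown_primary"
        assert not d.primary_site_known


class TestStructure:
    def test_degrees_and_lineage_from_relation(self):
        ped = pedigree_from_dict(
            {
                "participant_id": "X1",
                "relatives": [
                    {"relation": "mother", "diagnoses": [{"condition": "breast", "age": 44}]},
                    {"relation": "maternal_aunt", "diagnoses": [{"condition": "ovarian", "age": "50s"}]},
                ],
            }
        )
        mother, aunt = ped.relatives
        assert (mother.degree, mother.lineage, mother.sex) == (1, "maternal", "F")
        assert (aunt.degree, aunt.lineage) == (2, "maternal")
        assert aunt.diagnoses[0].age == 55

    def test_empty_history_with_fh_unavailable_is_valid(self):
        ped = Pedigree(participant_id="X2", fh_available=False, relatives=[])
        assert ped.relatives == []

    def test_relatives_with_fh_unavailable_rejected(self):
        with pytest.raises(StructureError):
            Pedigree("X3", fh_available=False, relatives=[RelativeRecord("mother")])

    def test_two_fathers_rejected(self):
        with pytest.raises(StructureError, match="father"):
            Pedigree("X4", relatives=[RelativeRecord("father"), RelativeRecord("father")])

    def test_repeated_nonunique_relations_allowed(self):
        ped = Pedigree("X5", relatives=[RelativeRecord("sister"), RelativeRecord("sister")])
        assert len(ped.relatives) == 2

    def test_unknown_relation_is_vocabulary_error(self):
        with pytest.raises(VocabularyError, match="stepcousin"):
            RelativeRecord("stepcousin")


class TestJsonRoundTrip:
    def test_parse_write_parse_identical(self, tmp_path):
        ped = pedigree_from_dict(
            {
                "participant_id": "R1",
                "proband": {"sex": "F", "age": 45},
                "relatives": [
                    {"relation": "mother", "deceased": True,
                     "diagnoses": [{"condition": "breast", "age": "40s"}]},
                    {"relation": "paternal_uncle",
                     "diagnoses": [{"condition": "colorectal", "age": 62}]},
                ],
            }
        )
        path = tmp_path / "r1.json"
        write_pedigree(ped, path)
        again = parse_pedigree(path)
        assert again == ped


PED = """\
FAM1\tPGF\t0\t0\t1\t0\t-
FAM1\tPGM\t0\t0\t2\t0\t-
FAM1\tMGF\t0\t0\t1\t0\t-
FAM1\tMGM\t0\t0\t2\t0\tcolorectal@50s
FAM1\tFA\tPGF\tPGM\t1\t0\thypertension@60s
FAM1\tMO\tMGF\tMGM\t2\t0\tbreast@44
FAM1\tAU1\tMGF\tMGM\t2\t0\tovarian@58
FAM1\tFAM1\tFA\tMO\t2\t0\t-
FAM1\tSIB1\tFA\tMO\t1\t0\thypertension@-
"""


class TestPedDialect:
    def test_relations_inferred_from_links(self, tmp_path):
        path = tmp_path / "fam.ped"
        path.write_text(PED)
        (ped,) = parse_ped_file(path)
        relations = {r.relation for r in ped.relatives}
        assert {"father", "mother", "maternal_aunt", "brother",
                "maternal_grandmother"} <= relations
        mo = next(r for r in ped.relatives if r.relation == "mother")
        assert mo.diagnoses[0].cancer_term == "breast" and mo.diagnoses[0].age == 44
        mgm = next(r for r in ped.relatives if r.relation == "maternal_grandmother")
        assert mgm.diagnoses[0].age == 55

    def test_round_trip_preserves_relations_and_diagnoses(self, tmp_path):
        path = tmp_path / "fam.ped"
        path.write_text(PED)
        (ped,) = parse_ped_file(path)
        out = tmp_path / "out.ped"
        write_ped_file([ped], out)
        (again,) = parse_ped_file(out)

        def summary(p):
            return sorted(
                (r.relation, tuple((d.condition, d.age) for d in r.diagnoses))
                for r in p.relatives
            )

        assert summary(again) == summary(ped)

    def test_missing_proband_rejected(self, tmp_path):
        path = tmp_path / "fam.ped"
        path.write_text("FAM2\tFA\t0\t0\t1\t0\t-\n")
        with pytest.raises(StructureError, match="proband"):
            parse_ped_file(path)


def test_pedigree_json_with_bad_structure_rejected(tmp_path):
    doc = {
        "participant_id": "B1",
        "relatives": [
            {"relation": "mother"},
            {"relation": "mother"},
        ],
    }
    path = tmp_path / "b1.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(StructureError):
        parse_pedigree(path)
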