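"""Four-generation family health histories.

A pedigree here is proband-centric: each relative is stored with a relation
term (children up to grandparents and cousins), from which the degree of
relationship (1st: parent/sibling/child; 2nd: grandparent/aunt/uncle;
3rd: cousin) and lineage (maternal/paternal; siblings and children belong to
both) are derived. Diagnoses carry a condition term and an age at diagnosis
that may be exact years, a decade band ("50s" — self-reported histories
frequently only know the decade), or unknown.

Two on-disk forms are supported: a JSON document per family, and an
extended PED dialect (the standard six columns plus a semicolon-separated
``condition@age`` phenotype column) where relations are inferred from the
parent links.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import StructureError, VocabularyError
from .vocab import canonical_cancer_term

# relation -> (degree, lineage, implied sex)
RELATIONS: dict[str, tuple[int, str, str | None]] = {
    "self": (0, "both", None),
    "father": (1, "paternal", "M"),
    "mother": (1, "maternal", "F"),
    "brother": (1, "both", "M"),
    "sister": (1, "both", "F"),
    "sibling": (1, "both", None),
    "son": (1, "both", "M"),
    "daughter": (1, "both", "F"),
    "child": (1, "both", None),
    "maternal_grandmother": (2, "maternal", "F"),
    "maternal_grandfather": (2, "maternal", "M"),
    "paternal_grandmother": (2, "paternal", "F"),
    "paternal_grandfather": (2, "paternal", "M"),
    "maternal_aunt": (2, "maternal", "F"),
    "maternal_uncle": (2, "maternal", "M"),
    "paternal_aunt": (2, "paternal", "F"),
    "paternal_uncle": (2, "paternal", "M"),
    "maternal_cousin": (3, "maternal", None),
    "paternal_cousin": (3, "paternal", None),
}

_UNIQUE_RELATIONS = (
    "father",
    "mother",
    "maternal_grandmother",
    "maternal_grandfather",
    "paternal_grandmother",
    "paternal_grandfather",
)

_DECADE_RE = re.compile(r"^(\d{1,2}0)s$")


def parse_age(value) -> tuple[int | None, bool]:
    """Normalise an age entry to (representative years, was_decade_band).

    Decade bands map to the band midpoint ("50s" -> 55). Unknown ages
    (None/"") stay None.
    """
    if value is None or value == "" or value == "unknown":
        return None, False
    if isinstance(value, (int, float)):
        return int(value), False
    m = _DECADE_RE.match(str(value).strip())
    if m:
        return int(m.group(1)) + 5, True
    try:
        return int(str(value).rstrip("y")), False
    except ValueError as exc:
        raise VocabularyError(f"unparseable age {value!r}") from exc


@dataclass(frozen=True)
class Diagnosis:
    """One reported condition of one relative."""

    condition: str
    age: int | None = None  # representative years at diagnosis
    is_cancer: bool = False
    age_is_band: bool = False
    primary_site_known: bool = True

    @property
    def cancer_term(self) -> str | None:
        """Canonical cancer term, or None for non-cancer conditions."""
        if not self.is_cancer:
            return None
        return canonical_cancer_term(self.condition) or "unknown_primary"


def make_diagnosis(condition: str, age=None, is_cancer: bool | None = None) -> Diagnosis:
    """Build a Diagnosis, inferring cancer status from the vocabulary when
    not given explicitly. Unrecognised free text defaults to non-cancer."""
    term = canonical_cancer_term(condition)
    if is_cancer is None:
        is_cancer = term is not None
    years, band = parse_age(age)
    return Diagnosis(
        condition=condition,
        age=years,
        is_cancer=is_cancer,
        age_is_band=band,
        primary_site_known=not (is_cancer and (term is None or term == "unknown_primary")),
    )


@dataclass
class RelativeRecord:
    """One relative with their reported diagnoses."""

    relation: str
    sex: str = "unknown"  # M | F | unknown
    deceased: bool = False
    age: int | None = None  # current age or age at death, when reported
    diagnoses: list[Diagnosis] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise VocabularyError(f"unknown relation term {self.relation!r}")
        implied = RELATIONS[self.relation][2]
        if self.sex == "unknown" and implied:
            self.sex = implied

    @property
    def degree(self) -> int:
        return RELATIONS[self.relation][0]

    @property
    def lineage(self) -> str:
        return RELATIONS[self.relation][1]

    @property
    def cancer_diagnoses(self) -> list[Diagnosis]:
        return [d for d in self.diagnoses if d.is_cancer]


@dataclass
class Pedigree:
    """A proband-centric family history."""

    participant_id: str
    fh_available: bool = True
    relatives: list[RelativeRecord] = field(default_factory=list)
    proband_sex: str = "unknown"
    proband_age: int | None = None

    def __post_init__(self) -> None:
        if not self.fh_available and self.relatives:
            raise StructureError(
                f"{self.participant_id}: relatives present but fh_available=false"
            )
        seen: set[str] = set()
        for r in self.relatives:
            if r.relation in _UNIQUE_RELATIONS:
                if r.relation in seen:
                    raise StructureError(
                        f"{self.participant_id}: more than one {r.relation}"
                    )
                seen.add(r.relation)


# ---------------------------------------------------------------------------
# JSON form


def pedigree_from_dict(doc: dict) -> Pedigree:
    relatives = []
    for rd in doc.get("relatives", []):
        diagnoses = [
            make_diagnosis(
                d["condition"], d.get("age"), d.get("is_cancer")
            )
            for d in rd.get("diagnoses", [])
        ]
        relatives.append(
            RelativeRecord(
                relation=rd["relation"],
                sex=rd.get("sex", "unknown"),
                deceased=bool(rd.get("deceased", False)),
                age=parse_age(rd.get("age"))[0],
                diagnoses=diagnoses,
            )
        )
    proband = doc.get("proband", {})
    return Pedigree(
        participant_id=doc["participant_id"],
        fh_available=bool(doc.get("fh_available", True)),
        relatives=relatives,
        proband_sex=proband.get("sex", "unknown"),
        proband_age=parse_age(proband.get("age"))[0],
    )


def pedigree_to_dict(ped: Pedigree) -> dict:
    return {
        "participant_id": ped.participant_id,
        "fh_available": ped.fh_available,
        "proband": {"sex": ped.proband_sex, "age": ped.proband_age},
        "relatives": [
            {
                "relation": r.relation,
                "sex": r.sex,
                "deceased": r.deceased,
                "age": r.age,
                "diagnoses": [
                    {
                        "condition": d.condition,
                        "age": f"{d.age - 5}s" if d.age_is_band else d.age,
                        "is_cancer": d.is_cancer,
                    }
                    for d in r.diagnoses
                ],
            }
            for r in ped.relatives
        ],
    }


def parse_pedigree(path: str | Path) -> Pedigree:
    """Parse one pedigree file (JSON document or extended PED)."""
    path = Path(path)
    if path.suffix.lower() == ".ped":
        peds = parse_ped_file(path)
        if len(peds) != 1:
            raise StructureError(f"{path}: expected one family, found {len(peds)}")
        return peds[0]
    return pedigree_from_dict(json.loads(path.read_text()))


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(pedigree_to_dict(ped), indent=1))


def load_pedigrees(path: str | Path) -> list[Pedigree]:
    """Load pedigrees from a directory of JSON files, one combined JSON list,
    or a single .ped file."""
    path = Path(path)
    if path.is_dir():
        return [parse_pedigree(p) for p in sorted(path.glob("*.json"))] + [
            ped for p in sorted(path.glob("*.ped")) for ped in parse_ped_file(p)
        ]
    if path.suffix.lower() == ".ped":
        return parse_ped_file(path)
    doc = json.loads(path.read_text())
    if isinstance(doc, list):
        return [pedigree_from_dict(d) for d in doc]
    return [pedigree_from_dict(doc)]


# ---------------------------------------------------------------------------
# Extended PED dialect
#
# Columns: FID IID PAT MAT SEX PHENO CONDITIONS
# SEX: 1=male 2=female 0=unknown. PHENO: 0/-9 unused here.
# CONDITIONS: semicolon-separated condition@age items ("breast@44",
# "colorectal@50s", "hypertension@-"), or "-" for none.
# The proband is the individual whose IID equals the family ID (FID).


def _relation_of(iid, proband, individuals) -> str | None:
    """Infer the relation of individual ``iid`` to the proband from links."""
    pat, mat = individuals[proband][0], individuals[proband][1]
    if iid == proband:
        return "self"
    if iid == pat:
        return "father"
    if iid == mat:
        return "mother"
    p_pat, p_mat = individuals[iid][0], individuals[iid][1]
    # sibling: shares a declared parent with proband
    if (pat != "0" and p_pat == pat) or (mat != "0" and p_mat == mat):
        return {"1": "brother", "2": "sister"}.get(individuals[iid][2], "sibling")
    # child
    if proband in (p_pat, p_mat):
        return {"1": "son", "2": "daughter"}.get(individuals[iid][2], "child")
    # grandparents
    for parent, side in ((pat, "paternal"), (mat, "maternal")):
        if parent != "0" and parent in individuals:
            g_pat, g_mat = individuals[parent][0], individuals[parent][1]
            if iid == g_pat:
                return f"{side}_grandfather"
            if iid == g_mat:
                return f"{side}_grandmother"
    # aunts/uncles: share a parent with the proband's parent
    for parent, side in ((pat, "paternal"), (mat, "maternal")):
        if parent == "0" or parent not in individuals:
            continue
        g_pat, g_mat = individuals[parent][0], individuals[parent][1]
        i_pat, i_mat = individuals[iid][0], individuals[iid][1]
        if (g_pat != "0" and i_pat == g_pat) or (g_mat != "0" and i_mat == g_mat):
            sex = individuals[iid][2]
            return f"{side}_uncle" if sex == "1" else f"{side}_aunt"
    # cousins: child of an aunt/uncle
    for parent, side in ((pat, "paternal"), (mat, "maternal")):
        if parent == "0" or parent not in individuals:
            continue
        g_pat, g_mat = individuals[parent][0], individuals[parent][1]
        i_pat, i_mat = individuals[iid][0], individuals[iid][1]
        for cand in (i_pat, i_mat):
            if cand in individuals and cand != parent:
                c_pat, c_mat = individuals[cand][0], individuals[cand][1]
                if (g_pat != "0" and c_pat == g_pat) or (g_mat != "0" and c_mat == g_mat):
                    return f"{side}_cousin"
    return None  # unrelated (e.g. spouse of an aunt) — stored nowhere


def parse_ped_file(path: str | Path) -> list[Pedigree]:
    path = Path(path)
    families: dict[str, dict[str, tuple]] = {}
    conditions: dict[tuple[str, str], str] = {}
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise StructureError(f"{path}:{ln}: expected >= 6 columns")
        fid, iid, pat, mat, sex = parts[:5]
        cond = parts[6] if len(parts) > 6 else "-"
        families.setdefault(fid, {})[iid] = (pat, mat, sex)
        conditions[(fid, iid)] = cond
    out = []
    for fid, individuals in families.items():
        if fid not in individuals:
            raise StructureError(
                f"{path}: family {fid}: no proband (individual with IID == FID)"
            )
        relatives = []
        for iid, (pat, mat, sex) in individuals.items():
            rel = _relation_of(iid, fid, individuals)
            if rel in (None, "self"):
                continue
            diags = []
            cond = conditions[(fid, iid)]
            if cond and cond != "-":
                for item in cond.split(";"):
                    name, _, age = item.partition("@")
                    diags.append(make_diagnosis(name, None if age in ("", "-") else age))
            relatives.append(
                RelativeRecord(
                    relation=rel,
                    sex={"1": "M", "2": "F"}.get(sex, "unknown"),
                    diagnoses=diags,
                )
            )
        out.append(Pedigree(participant_id=fid, relatives=relatives))
    return out


def write_ped_file(peds: list[Pedigree], path: str | Path) -> None:
    """Serialise pedigrees to the extended PED dialect (inverse of
    :func:`parse_ped_file` for the relations that dialect can express)."""
    lines = []
    for ped in peds:
        fid = ped.participant_id
        sex_code = {"M": "1", "F": "2"}.get(ped.proband_sex, "0")
        ids = {
            "father": "FA", "mother": "MO",
            "paternal_grandfather": "PGF", "paternal_grandmother": "PGM",
            "maternal_grandfather": "MGF", "maternal_grandmother": "MGM",
        }
        rows = {}

        def _row(iid, pat, mat, sex, conds="-"):
            rows[iid] = [fid, iid, pat, mat, sex, "0", conds]

        def _conds(rel: RelativeRecord) -> str:
            if not rel.diagnoses:
                return "-"
            items = []
            for d in rel.diagnoses:
                if d.age is None:
                    items.append(f"{d.condition}@-")
                elif d.age_is_band:
                    items.append(f"{d.condition}@{d.age - 5}s")
                else:
                    items.append(f"{d.condition}@{d.age}")
            return ";".join(items)

        _row("PGF", "0", "0", "1")
        _row("PGM", "0", "0", "2")
        _row("MGF", "0", "0", "1")
        _row("MGM", "0", "0", "2")
        _row("FA", "PGF", "PGM", "1")
        _row("MO", "MGF", "MGM", "2")
        _row(fid, "FA", "MO", sex_code)
        counters: dict[str, int] = {}
        for rel in ped.relatives:
            if rel.relation in ids:
                iid = ids[rel.relation]
                rows[iid][6] = _conds(rel)
                continue
            counters[rel.relation] = counters.get(rel.relation, 0) + 1
            iid = f"{rel.relation[:3].upper()}{counters[rel.relation]}"
            sex = {"M": "1", "F": "2"}.get(rel.sex, "0")
            if rel.relation in ("brother", "sister", "sibling"):
                _row(iid, "FA", "MO", sex, _conds(rel))
            elif rel.relation in ("son", "daughter", "child"):
                spouse = "SP"
                if spouse not in rows:
                    _row(spouse, "0", "0", "0")
                pat, mat = (fid, spouse) if sex_code == "1" else (spouse, fid)
                _row(iid, pat, mat, sex, _conds(rel))
            elif rel.relation.endswith(("_aunt", "_uncle")):
                side = "P" if rel.relation.startswith("paternal") else "M"
                _row(iid, f"{side}GF", f"{side}GM", sex, _conds(rel))
            elif rel.relation.endswith("_cousin"):
                side = "paternal" if rel.relation.startswith("paternal") else "maternal"
                # attach to (or create) an aunt on the right side
                anchor = f"{side}_aunt_anchor"
                if anchor not in rows:
                    g = "P" if side == "paternal" else "M"
                    rows[anchor] = [fid, anchor, f"{g}GF", f"{g}GM", "2", "0", "-"]
                    rows[anchor + "_sp"] = [fid, anchor + "_sp", "0", "0", "1", "0", "-"]
                _row(iid, anchor + "_sp", anchor, sex, _conds(rel))
        lines.extend("\t".join(r) for r in rows.values())
    Path(path).write_text("\n".join(lines) + "\n")
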