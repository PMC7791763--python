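"""Family-history cancer-risk stratification and family-cancer summaries.

The rules engine classifies a pedigree into one of three cohorts:

* ``increased`` — the history satisfies at least one rule of the active
  ruleset (rule identifiers are recorded);
* ``average`` — history available but no rule fires;
* ``not_available`` — no family history was collected.

Rules count *distinct affected relatives* per cancer-term set, optionally
within one lineage, with age limits evaluated on the representative
diagnosis age (decade bands use the band midpoint). A diagnosis of unknown
age never satisfies an age limit on its own; when treating unknown ages as
passing would make an otherwise-silent rule fire, the result carries
``ambiguous=True`` — the deterministic rendering of "borderline pedigree,
reviewed by the clinical team".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .pedigree import Pedigree, RelativeRecord
from .vocab import CANCER_TERMS

COHORTS = ("increased", "average", "not_available")


@dataclass(frozen=True)
class FHRule:
    id: str
    cancers: frozenset[str]
    degrees: frozenset[int] = frozenset({1, 2})
    same_lineage: bool = False
    min_count: int = 1
    max_age: int | None = None
    min_early: int = 0
    early_age: int | None = None
    sex: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        unknown = self.cancers - CANCER_TERMS
        if unknown:
            raise ConfigurationError(
                f"rule {self.id}: unknown cancer term(s) {sorted(unknown)}"
            )
        if self.min_early and self.early_age is None:
            raise ConfigurationError(f"rule {self.id}: min_early without early_age")


@dataclass
class FHRiskResult:
    participant_id: str
    cohort: str
    triggered_rules: list[str] = field(default_factory=list)
    ambiguous: bool = False


class Ruleset:
    def __init__(self, rules: list[FHRule], name: str = "custom"):
        if not rules:
            raise ConfigurationError("ruleset is empty")
        ids = [r.id for r in rules]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate rule ids in ruleset")
        self.rules = list(rules)
        self.name = name

    def __iter__(self):
        return iter(self.rules)

    def __len__(self):
        return len(self.rules)


def load_ruleset(path: str | Path | None = None) -> Ruleset:
    """Load a ruleset YAML; with no path, the bundled default."""
    if path is None:
        path = Path(resources.files("fhconcord").joinpath("data/default_ruleset.yaml"))
        name = "default"
    else:
        path = Path(path)
        name = path.stem
    if not path.exists():
        raise ConfigurationError(f"ruleset file not found: {path}")
    doc = yaml.safe_load(path.read_text())
    if not doc or "rules" not in doc:
        raise ConfigurationError(f"{path}: no rules found")
    rules = [
        FHRule(
            id=r["id"],
            cancers=frozenset(r["cancers"]),
            degrees=frozenset(r.get("degrees", [1, 2])),
            same_lineage=bool(r.get("same_lineage", False)),
            min_count=int(r.get("min_count", 1)),
            max_age=r.get("max_age"),
            min_early=int(r.get("min_early", 0)),
            early_age=r.get("early_age"),
            sex=r.get("sex"),
            description=r.get("description", ""),
        )
        for r in doc["rules"]
    ]
    return Ruleset(rules, name=name)


@dataclass(frozen=True)
class _Event:
    """One (relative, cancer term) pair with rule-relevant attributes."""

    term: str
    age: int | None
    degree: int
    lineage: str  # maternal | paternal | both
    sex: str
    relative_index: int


def _events(pedigree: Pedigree) -> list[_Event]:
    events = []
    for idx, rel in enumerate(pedigree.relatives):
        for diag in rel.cancer_diagnoses:
            events.append(
                _Event(
                    term=diag.cancer_term,
                    age=diag.age,
                    degree=rel.degree,
                    lineage=rel.lineage,
                    sex=rel.sex,
                    relative_index=idx,
                )
            )
    return events


def _rule_fires(rule: FHRule, events: list[_Event], relax_unknown_age: bool) -> bool:
    def age_ok(age, limit):
        if limit is None:
            return True
        if age is None:
            return relax_unknown_age
        return age <= limit

    matching = [
        e
        for e in events
        if e.term in rule.cancers
        and e.degree in rule.degrees
        and (rule.sex is None or e.sex == rule.sex)
        and age_ok(e.age, rule.max_age)
    ]
    lineages = ("maternal", "paternal") if rule.same_lineage else (None,)
    for lineage in lineages:
        if lineage is None:
            pool = matching
        else:
            pool = [e for e in matching if e.lineage in (lineage, "both")]
        # distinct affected relatives, not diagnosis events
        count = len({e.relative_index for e in pool})
        if count < rule.min_count:
            continue
        if rule.min_early:
            early = {
                e.relative_index
                for e in pool
                if age_ok(e.age, rule.early_age) and (e.age is not None or relax_unknown_age)
            }
            if len(early) < rule.min_early:
                continue
        return True
    return False


def assess_fh_risk(pedigree: Pedigree, ruleset: Ruleset | None = None) -> FHRiskResult:
    """Classify one pedigree into increased / average / not_available."""
    ruleset = ruleset or load_ruleset()
    if not pedigree.fh_available:
        return FHRiskResult(pedigree.participant_id, "not_available")
    events = _events(pedigree)
    triggered = [r.id for r in ruleset if _rule_fires(r, events, relax_unknown_age=False)]
    ambiguous = False
    if not triggered:
        # would any rule fire if unknown ages were allowed to pass age limits?
        ambiguous = any(
            _rule_fires(r, events, relax_unknown_age=True) for r in ruleset
        )
    cohort = "increased" if triggered else "average"
    return FHRiskResult(pedigree.participant_id, cohort, triggered, ambiguous)


def assess_cohort(
    pedigrees: list[Pedigree], ruleset: Ruleset | None = None
) -> dict[str, FHRiskResult]:
    ruleset = ruleset or load_ruleset()
    return {p.participant_id: assess_fh_risk(p, ruleset) for p in pedigrees}


def load_validation_families() -> dict[str, list[Pedigree]]:
    """Bundled reference family histories for ruleset validation.

    ``average_risk``: the published histories of actionable-variant carriers
    whose families were assessed at average cancer risk (the default ruleset
    must leave all of them average). ``increased_risk``: a family with
    same-lineage clustered colorectal cancer that must classify increased.
    """
    import json

    from .pedigree import pedigree_from_dict

    path = Path(resources.files("fhconcord").joinpath("data/validation_families.json"))
    doc = json.loads(path.read_text())
    return {
        group: [pedigree_from_dict(d) for d in doc[group]]
        for group in ("average_risk", "increased_risk")
    }


@dataclass
class FamilyCancerSummary:
    """Cancer-type mix across a set of families."""

    n_families: int
    n_reports: int
    counts: dict[str, int]
    percentages: dict[str, float]  # of all cancer reports, 1 decimal
    per_family_percentages: dict[str, float]  # of families reporting the type
    multi_cancer_fraction: float  # families with >1 distinct cancer type


def summarize_family_cancers(
    pedigrees: list[Pedigree], per_family: bool = False
) -> FamilyCancerSummary:
    """Tabulate reported familial cancers over a pedigree subset.

    Percentages are per cancer *report* by default (denominator = all cancer
    diagnoses across the families, unknown-type retained as its own
    category); ``per_family`` switches the denominator to families reporting
    the type at least once.
    """
    if not pedigrees:
        return FamilyCancerSummary(0, 0, {}, {}, {}, 0.0)
    counts: dict[str, int] = {}
    family_types: list[set[str]] = []
    for ped in pedigrees:
        types = set()
        for rel in ped.relatives:
            for diag in rel.cancer_diagnoses:
                counts[diag.cancer_term] = counts.get(diag.cancer_term, 0) + 1
                types.add(diag.cancer_term)
        family_types.append(types)
    n_reports = sum(counts.values())
    n_families = len(pedigrees)
    percentages = {
        t: round(100 * c / n_reports, 1) for t, c in sorted(counts.items())
    }
    per_family_counts = {
        t: sum(1 for types in family_types if t in types) for t in counts
    }
    per_family_percentages = {
        t: round(100 * c / n_families, 1) for t, c in sorted(per_family_counts.items())
    }
    multi = sum(1 for types in family_types if len(types) > 1)
    return FamilyCancerSummary(
        n_families=n_families,
        n_reports=n_reports,
        counts=dict(sorted(counts.items())),
        percentages=percentages,
        per_family_percentages=per_family_percentages,
        multi_cancer_fraction=multi / n_families,
    )
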