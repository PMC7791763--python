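"""ACMG/AMP evidence codes and deterministic class combination.

Variant classification under the ACMG/AMP framework assigns discrete
evidence codes (very-strong to supporting, pathogenic and benign side) and
combines them by fixed rules into five classes: pathogenic (P), likely
pathogenic (LP), uncertain (VUS), likely benign (LB), benign (B).

The combining-rule table ships as editable YAML
(``data/acmg_combining_rules.yaml``); :func:`combine_acmg_evidence` is a pure
function of the evidence set and the table. Conflicting evidence — a
pathogenic-side class and a benign-side class both satisfied — is reported as
VUS, which is how a deterministic pipeline renders "resolve by expert
discussion".

A small automated-evidence deriver (:func:`automated_evidence`) emulates the
subset of codes an InterVar-style engine can assign from annotations alone:

* PVS1 — loss-of-function consequence in a gene with an established
  haploinsufficiency mechanism;
* PM2 — absent or extremely rare in both population-frequency sources;
* PP3 / BP4 — in-silico ensemble score (REVEL) above 0.7 / below 0.3;
* PP5 / BP6 — a concordant pathogenic / benign assertion from the variant
  database;
* BA1 — allele frequency above 5% in either source.

Manually curated codes (functional, segregation, de novo...) are outside
automation scope and can be supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError, VocabularyError
from .vocab import LOF_CONSEQUENCES

PATHOGENIC_CODES = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
)
BENIGN_CODES = frozenset(
    {"BA1"} | {f"BS{i}" for i in range(1, 5)} | {f"BP{i}" for i in range(1, 8)}
)
ALL_CODES = PATHOGENIC_CODES | BENIGN_CODES

# Category of a code is its alphabetic prefix: PVS, PS, PM, PP, BA, BS, BP.
_CATEGORIES = ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")

# Thresholds used by the automated-evidence deriver.
PM2_MAX_AF = 1e-4
PP3_MIN_REVEL = 0.7
BP4_MAX_REVEL = 0.3
BA1_MIN_AF = 0.05


@dataclass(frozen=True)
class EvidenceSet:
    """An immutable set of ACMG/AMP evidence codes from the closed vocabulary."""

    codes: frozenset[str]

    def __init__(self, codes=()):
        codes = frozenset(codes)
        unknown = codes - ALL_CODES
        if unknown:
            raise VocabularyError(
                f"unknown ACMG evidence code(s): {', '.join(sorted(unknown))}"
            )
        object.__setattr__(self, "codes", codes)

    def __iter__(self):
        return iter(sorted(self.codes))

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __len__(self) -> int:
        return len(self.codes)

    def __or__(self, other: "EvidenceSet") -> "EvidenceSet":
        return EvidenceSet(self.codes | other.codes)

    def category_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(_CATEGORIES, 0)
        for code in self.codes:
            for cat in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
                if code.startswith(cat):
                    counts[cat] += 1
                    break
        # PVS1 also starts with "P" only; prefixes above are unambiguous
        # except PS vs PVS ordering, handled by checking PVS first.
        return counts


class CombiningRules:
    """A parsed evidence-combining rule table."""

    def __init__(self, table: dict):
        for cls in ("pathogenic", "likely_pathogenic", "benign", "likely_benign"):
            if cls not in table or not isinstance(table[cls], list):
                raise ConfigurationError(
                    f"combining-rule table missing class {cls!r}"
                )
            for entry in table[cls]:
                bad = set(entry) - set(_CATEGORIES)
                if bad:
                    raise ConfigurationError(
                        f"combining-rule entry for {cls} uses unknown "
                        f"categories: {sorted(bad)}"
                    )
        self.table = table

    @staticmethod
    def _met(entry: dict, counts: dict[str, int]) -> bool:
        return all(counts[cat] >= n for cat, n in entry.items())

    def classify(self, evidence: EvidenceSet) -> str:
        counts = evidence.category_counts()
        path_class = None
        if any(self._met(e, counts) for e in self.table["pathogenic"]):
            path_class = "P"
        elif any(self._met(e, counts) for e in self.table["likely_pathogenic"]):
            path_class = "LP"
        benign_class = None
        if any(self._met(e, counts) for e in self.table["benign"]):
            benign_class = "B"
        elif any(self._met(e, counts) for e in self.table["likely_benign"]):
            benign_class = "LB"
        if path_class and benign_class:
            return "VUS"  # conflicting evidence is flagged, not adjudicated
        return path_class or benign_class or "VUS"


def default_rules_path() -> Path:
    return Path(resources.files("fhconcord").joinpath("data/acmg_combining_rules.yaml"))


def load_combining_rules(path: str | Path | None = None) -> CombiningRules:
    path = Path(path) if path is not None else default_rules_path()
    if not path.exists():
        raise ConfigurationError(f"combining-rule table not found: {path}")
    return CombiningRules(yaml.safe_load(path.read_text()))


_DEFAULT_RULES: CombiningRules | None = None


def _default_rules() -> CombiningRules:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_combining_rules()
    return _DEFAULT_RULES


def combine_acmg_evidence(
    evidence: EvidenceSet | set[str] | frozenset[str],
    rules: CombiningRules | None = None,
) -> str:
    """Combine evidence codes into a final class: P, LP, VUS, LB or B."""
    if not isinstance(evidence, EvidenceSet):
        evidence = EvidenceSet(evidence)
    rules = rules or _default_rules()
    return rules.classify(evidence)


def automated_evidence(variant, panel_entry) -> EvidenceSet:
    """Derive the automatable evidence codes for one variant record.

    ``variant`` is a :class:`~fhconcord.variants.VariantRecord`;
    ``panel_entry`` the matching :class:`~fhconcord.panel.GenePanelEntry`.
    """
    codes: set[str] = set()
    if (
        variant.consequence in LOF_CONSEQUENCES
        and panel_entry is not None
        and panel_entry.haploinsufficient == "yes"
    ):
        codes.add("PVS1")
    afs = [af for af in (variant.af_local, variant.af_gnomad) if af is not None]
    if all(af < PM2_MAX_AF for af in afs):  # vacuously true when both absent
        codes.add("PM2")
    if any(af > BA1_MIN_AF for af in afs):
        codes.add("BA1")
        codes.discard("PM2")
    if variant.revel is not None:
        if variant.revel > PP3_MIN_REVEL:
            codes.add("PP3")
        elif variant.revel < BP4_MAX_REVEL:
            codes.add("BP4")
    if variant.clinvar_assertion in ("pathogenic", "likely_pathogenic"):
        codes.add("PP5")
    elif variant.clinvar_assertion in ("benign", "likely_benign"):
        codes.add("BP6")
    return EvidenceSet(codes)
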