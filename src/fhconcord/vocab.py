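"""Controlled vocabularies: cancer-type terms, variant consequences, enums.

Cancer terms are the currency of the family-history rules engine; free-text
conditions reported by relatives are normalised onto this vocabulary where an
alias is known, and anything else is carried through as a non-cancer (or, for
"unknown cancer" style entries, as ``unknown_primary``).
"""

from __future__ import annotations

# Canonical cancer-type terms used by risk rules and summaries.
CANCER_TERMS = frozenset(
    {
        "breast",
        "ovarian",
        "colorectal",
        "endometrial",
        "gastric",
        "urothelial",
        "small_bowel",
        "prostate",
        "pancreatic",
        "lung",
        "liver",
        "thyroid",
        "cervical",
        "kidney",
        "melanoma",
        "leukemia",
        "lymphoma",
        "brain",
        "sarcoma",
        "head_neck",
        "testicular",
        "esophageal",
        "bone",
        "skin_nonmelanoma",
        "unknown_primary",
    }
)

# Free-text aliases seen in self-reported histories.
CANCER_ALIASES = {
    "bladder": "urothelial",
    "bladder cancer": "urothelial",
    "bowel": "colorectal",
    "bowel cancer": "colorectal",
    "colon": "colorectal",
    "colon cancer": "colorectal",
    "rectal": "colorectal",
    "uterine": "endometrial",
    "uterus": "endometrial",
    "womb": "endometrial",
    "stomach": "gastric",
    "stomach cancer": "gastric",
    "unknown cancer": "unknown_primary",
    "unknown": "unknown_primary",
    "cancer": "unknown_primary",
    "renal": "kidney",
    "hepatic": "liver",
    "liver cancer": "liver",
    "lung cancer": "lung",
    "breast cancer": "breast",
    "ovarian cancer": "ovarian",
    "colorectal cancer": "colorectal",
    "prostate cancer": "prostate",
    "pancreatic cancer": "pancreatic",
    "cervical cancer": "cervical",
    "thyroid cancer": "thyroid",
}

# Cancers aggregated by hereditary colorectal (Lynch-spectrum) risk rules.
LYNCH_SPECTRUM = frozenset(
    {"colorectal", "endometrial", "ovarian", "gastric", "urothelial", "small_bowel"}
)

CONSEQUENCES = frozenset(
    {
        "missense",
        "stopgain",
        "stoploss",
        "frameshift_indel",
        "inframe_indel",
        "essential_splice",
        "synonymous",
        "intronic",
        "other",
    }
)

# Consequences treated as protein-disrupting (loss of function).
LOF_CONSEQUENCES = frozenset(
    {"frameshift_indel", "stopgain", "stoploss", "essential_splice"}
)

CLINVAR_ASSERTIONS = frozenset(
    {
        "pathogenic",
        "likely_pathogenic",
        "vus",
        "likely_benign",
        "benign",
        "conflicting",
        "absent",
    }
)

INHERITANCE_MODES = frozenset({"AD", "AR", "XL"})
ZYGOSITIES = frozenset({"het", "hom", "hemi"})


def canonical_cancer_term(condition: str) -> str | None:
    """Map a condition string to a canonical cancer term, or None if the
    condition is not recognised as a cancer."""
    key = condition.strip().lower().replace("-", " ")
    if key in CANCER_TERMS:
        return key
    if key in CANCER_ALIASES:
        return CANCER_ALIASES[key]
    key_us = key.replace(" ", "_")
    if key_us in CANCER_TERMS:
        return key_us
    return None
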