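"""Joining carrier status with family-history cohorts; report tables.

Produces the cohort-level analyses: a baseline-characteristics table, the
carrier-prevalence and relative-risk comparisons between family-history
cohorts (for the full panel and the secondary-findings subset), the
carrier x history concordance partition, and a gene-exclusion sensitivity
re-computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DataError
from .fhrisk import FHRiskResult
from .panel import GenePanel
from .stats import (
    ConcordanceTable,
    ContingencyResult,
    Z_95,
    concordance_table,
    relative_risk,
    round_pct,
)
from .triage import CarrierStatus, ClassifiedVariant


@dataclass
class ParticipantAssessment:
    """Joined per-participant outcome: history cohort x carrier status."""

    participant_id: str
    fh_cohort: str  # increased | average | not_available
    is_carrier: bool
    acmg_sf_carrier: bool
    variants: list[ClassifiedVariant] = field(default_factory=list)

    @property
    def actionable_genes(self) -> list[str]:
        return [v.variant.gene for v in self.variants if v.clinically_actionable]


def join_assessments(
    carrier_status: dict[str, CarrierStatus],
    fh_results: dict[str, FHRiskResult],
) -> list[ParticipantAssessment]:
    """One assessment per participant in the carrier-status universe.

    Participants without a family-history result are assigned to the
    not-available cohort.
    """
    out = []
    for pid, status in sorted(carrier_status.items()):
        fh = fh_results.get(pid)
        out.append(
            ParticipantAssessment(
                participant_id=pid,
                fh_cohort=fh.cohort if fh is not None else "not_available",
                is_carrier=status.is_carrier,
                acmg_sf_carrier=status.acmg_sf_carrier,
                variants=status.actionable_variants,
            )
        )
    return out


def cohort_counts(assessments: list[ParticipantAssessment]) -> dict[str, int]:
    counts = {"increased": 0, "average": 0, "not_available": 0}
    for a in assessments:
        counts[a.fh_cohort] += 1
    return counts


def carrier_counts(
    assessments: list[ParticipantAssessment], sf_only: bool = False
) -> dict[str, int]:
    counts = {"increased": 0, "average": 0, "not_available": 0}
    for a in assessments:
        hit = a.acmg_sf_carrier if sf_only else a.is_carrier
        if hit:
            counts[a.fh_cohort] += 1
    return counts


def assessments_concordance(
    assessments: list[ParticipantAssessment], sf_only: bool = False
) -> ConcordanceTable:
    """Concordance partition over the FH-available subset; records from the
    not-available cohort are a scoping error here."""
    cells = [0, 0, 0, 0]
    for a in assessments:
        if a.fh_cohort == "not_available":
            raise DataError(
                f"{a.participant_id}: not_available cohort passed to concordance"
            )
        carrier = a.acmg_sf_carrier if sf_only else a.is_carrier
        if carrier and a.fh_cohort == "increased":
            cells[0] += 1
        elif carrier and a.fh_cohort == "average":
            cells[1] += 1
        elif a.fh_cohort == "increased":
            cells[2] += 1
        else:
            cells[3] += 1
    return concordance_table(tuple(cells))


@dataclass
class RRBlock:
    """One RR comparison row (a cohort pair, one gene scope)."""

    scope: str  # panel | acmg_sf
    exposed: str
    unexposed: str
    result: ContingencyResult | None  # None when a cohort is empty

    def as_dict(self) -> dict:
        d = {"scope": self.scope, "exposed": self.exposed, "unexposed": self.unexposed}
        if self.result is None:
            d["suppressed"] = True
            return d
        r = self.result
        d.update(
            a=r.a, n1=r.n1, c=r.c, n2=r.n2,
            rr=r.rr, ci_low=r.ci_low, ci_high=r.ci_high, p_value=r.p_value,
            undefined=r.undefined,
            display_1dp=r.formatted(1), display_2dp=r.formatted(2),
            one_in_exposed=r.one_in_exposed, one_in_unexposed=r.one_in_unexposed,
            pct_exposed=round_pct(r.a, r.n1), pct_unexposed=round_pct(r.c, r.n2),
        )
        return d


@dataclass
class CohortReport:
    baseline: dict
    rr_blocks: list[RRBlock]
    concordance: ConcordanceTable | None
    flags: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        doc = {
            "baseline": self.baseline,
            "relative_risk": [b.as_dict() for b in self.rr_blocks],
            "flags": self.flags,
        }
        if self.concordance is not None:
            t = self.concordance
            doc["concordance"] = {
                "cells": {
                    "carrier_increased": t.carrier_increased,
                    "carrier_average": t.carrier_average,
                    "noncarrier_increased": t.noncarrier_increased,
                    "noncarrier_average": t.noncarrier_average,
                },
                "concordant": t.concordant,
                "discordant": t.discordant,
                "percentages": t.percentages(),
            }
        return json.dumps(doc, indent=1, sort_keys=True)


def _baseline(
    assessments: list[ParticipantAssessment],
    participants: pd.DataFrame | None,
) -> dict:
    cohorts = cohort_counts(assessments)
    carriers = carrier_counts(assessments)
    sf_carriers = carrier_counts(assessments, sf_only=True)
    total = len(assessments)
    fh_available = cohorts["increased"] + cohorts["average"]
    baseline = {
        "n_total": total,
        "n_fh_available": fh_available,
        "n_increased": cohorts["increased"],
        "n_average": cohorts["average"],
        "n_not_available": cohorts["not_available"],
        "pct_fh_available": round_pct(fh_available, total) if total else None,
        "pct_increased_of_available": (
            round_pct(cohorts["increased"], fh_available) if fh_available else None
        ),
        "n_carriers": sum(carriers.values()),
        "pct_carriers": round_pct(sum(carriers.values()), total) if total else None,
        "carriers_by_cohort": carriers,
        "sf_carriers_by_cohort": sf_carriers,
    }
    if participants is not None and len(participants):
        ages = participants["age"]
        baseline["median_age"] = float(ages.median())
        baseline["age_range"] = [int(ages.min()), int(ages.max())]
        if "sex" in participants:
            n_f = int((participants["sex"] == "F").sum())
            baseline["n_female"] = n_f
            baseline["pct_female"] = round_pct(n_f, len(participants))
        if "ethnicity" in participants:
            baseline["ethnicity_counts"] = (
                participants["ethnicity"].value_counts().to_dict()
            )
    return baseline


def cohort_report(
    assessments: list[ParticipantAssessment],
    panel: GenePanel | None = None,
    participants: pd.DataFrame | None = None,
    z: float = Z_95,
    haldane: bool = False,
) -> CohortReport:
    """Assemble the full cohort report: baseline, RR comparisons for the
    panel and the secondary-findings subset (increased vs average and
    increased vs not-available), and the concordance partition.

    Comparisons against an empty cohort are suppressed and flagged.
    """
    cohorts = cohort_counts(assessments)
    flags = [f"empty cohort: {k}" for k, v in cohorts.items() if v == 0]
    blocks: list[RRBlock] = []
    for scope, sf_only in (("panel", False), ("acmg_sf", True)):
        carriers = carrier_counts(assessments, sf_only=sf_only)
        for unexposed in ("average", "not_available"):
            if cohorts["increased"] == 0 or cohorts[unexposed] == 0:
                blocks.append(RRBlock(scope, "increased", unexposed, None))
                continue
            result = relative_risk(
                carriers["increased"], cohorts["increased"],
                carriers[unexposed], cohorts[unexposed],
                z=z, haldane=haldane,
            )
            blocks.append(RRBlock(scope, "increased", unexposed, result))
    available = [a for a in assessments if a.fh_cohort != "not_available"]
    concordance = assessments_concordance(available) if available else None
    return CohortReport(
        baseline=_baseline(assessments, participants),
        rr_blocks=blocks,
        concordance=concordance,
        flags=flags,
    )


def sensitivity_exclude_gene(
    assessments: list[ParticipantAssessment],
    gene: str,
    unexposed: str = "average",
    z: float = Z_95,
) -> ContingencyResult:
    """Re-compute the panel RR after removing increased-cohort carriers of
    one gene from the analysis entirely (both numerator and denominator).

    Used for carriers of genes whose disease association is still emerging:
    dropping the participant asks whether the enrichment survives without
    that gene's contribution.
    """
    excluded = {
        a.participant_id
        for a in assessments
        if a.fh_cohort == "increased" and gene in a.actionable_genes
    }
    kept = [a for a in assessments if a.participant_id not in excluded]
    cohorts = cohort_counts(kept)
    carriers = carrier_counts(kept)
    return relative_risk(
        carriers["increased"], cohorts["increased"],
        carriers[unexposed], cohorts[unexposed], z=z,
    )


def assessments_to_frame(assessments: list[ParticipantAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": a.participant_id,
                "fh_cohort": a.fh_cohort,
                "is_carrier": a.is_carrier,
                "acmg_sf_carrier": a.acmg_sf_carrier,
                "actionable_genes": ";".join(a.actionable_genes),
            }
            for a in assessments
        ]
    )


def write_report(report: CohortReport, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "cohort_report.json"
    json_path.write_text(report.to_json())
    rows = [b.as_dict() for b in report.rr_blocks]
    tsv_path = out_dir / "relative_risk.tsv"
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    return {"json": json_path, "tsv": tsv_path}
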