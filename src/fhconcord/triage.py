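"""Variant triage: candidate routing, classification, carrier status.

The triage funnel mirrors standard germline screening practice for a
panel-scoped cohort:

1. frequency filter — keep variants rarer than 1% in both a local
   population-matched database and a broad reference database (strict ``<``);
2. pathogenic-candidate routing — a variant is reviewed further if it meets
   any one of three ordered criteria:

   * **clinvar** — at least one pathogenic / likely-pathogenic database
     entry (checked in exonic and intronic regions alike, no frequency
     precondition),
   * **lof** — a protein-disrupting consequence (small indel, stopgain,
     stoploss, essential splice) at MAF < 1% in a gene with an established
     haploinsufficiency mechanism,
   * **insilico** — absent from the variant database, MAF < 1% and a high
     in-silico ensemble prediction (REVEL > 0.7);

3. uncertain-significance pool — remaining rare variants whose automated
   classification is uncertain, flagged ``potential_pathogenic`` when REVEL
   exceeds 0.7 and the database is silent or uncertain;
4. classification — automated evidence codes combined by the ACMG/AMP rule
   table (a concordant database P/LP assertion is adopted directly);
5. carrier status — a participant carries a *clinically actionable* variant
   when a P/LP variant sits in an autosomal-dominant or X-linked panel gene,
   or a biallelic P/LP genotype in a recessive gene; heterozygous P/LP hits
   in recessive genes are reported as recessive-carrier-only.

Family history is deliberately not an input anywhere in this module:
classification is blind to the pedigree by construction.

Loss-of-function variants in genes whose haploinsufficiency verdict is
``unknown`` are not auto-candidates; they are surfaced on a manual-review
list. Where the verdict is ``no`` they fall through to the uncertain pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .acmg import CombiningRules, EvidenceSet, automated_evidence, combine_acmg_evidence
from .errors import ScopingError
from .panel import GenePanel
from .variants import (
    DEFAULT_MAF_THRESHOLD,
    VariantRecord,
    frequency_filter,
    passes_frequency,
)
from .vocab import LOF_CONSEQUENCES

INSILICO_MIN_REVEL = 0.7

ROUTES = ("clinvar_lp_p", "lof_candidate", "insilico_candidate", "vus_pool", "excluded")


@dataclass
class ClassifiedVariant:
    """A variant with its triage route, evidence and final class."""

    variant: VariantRecord
    route: str
    evidence: EvidenceSet = field(default_factory=EvidenceSet)
    final_class: str | None = None  # P | LP | VUS | LB | B; None when excluded
    potential_pathogenic: bool = False
    needs_manual_review: bool = False

    @property
    def clinically_actionable(self) -> bool:
        return self.final_class in ("P", "LP")


@dataclass
class CarrierStatus:
    """Per-participant actionability summary."""

    participant_id: str
    is_carrier: bool
    actionable_variants: list[ClassifiedVariant]
    acmg_sf_carrier: bool
    recessive_carrier_genes: list[str] = field(default_factory=list)


def _check_panel_scope(variants: list[VariantRecord], panel: GenePanel) -> None:
    off = sorted({v.gene for v in variants if v.gene not in panel})
    if off:
        raise ScopingError(f"variant gene(s) not in panel: {', '.join(off)}")


def select_lp_candidates(
    variants: list[VariantRecord],
    panel: GenePanel,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> list[ClassifiedVariant]:
    """Route variants meeting any pathogenic-candidate criterion.

    Criteria are checked in fixed order (clinvar > lof > insilico); the first
    match is recorded as the route. Class assignment happens later in
    :func:`classify_candidates`. Loss-of-function variants in genes with an
    *unknown* haploinsufficiency verdict are routed but flagged for manual
    review rather than silently auto-qualified.
    """
    _check_panel_scope(variants, panel)
    out: list[ClassifiedVariant] = []
    for v in variants:
        entry = panel[v.gene]
        rare = passes_frequency(v, maf_threshold)
        if v.has_lp_or_p_entry:
            out.append(ClassifiedVariant(v, "clinvar_lp_p"))
        elif v.consequence in LOF_CONSEQUENCES and rare and entry.haploinsufficient == "yes":
            out.append(ClassifiedVariant(v, "lof_candidate"))
        elif (
            v.consequence in LOF_CONSEQUENCES
            and rare
            and entry.haploinsufficient == "unknown"
        ):
            out.append(
                ClassifiedVariant(v, "lof_candidate", needs_manual_review=True)
            )
        elif (
            v.clinvar_assertion == "absent"
            and rare
            and v.revel is not None
            and v.revel > INSILICO_MIN_REVEL
        ):
            out.append(ClassifiedVariant(v, "insilico_candidate"))
    return out


def select_vus(
    variants: list[VariantRecord],
    panel: GenePanel,
    rules: CombiningRules | None = None,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> list[ClassifiedVariant]:
    """Select the uncertain-significance pool from frequency-filtered variants.

    Emulates an automated (InterVar-style) pre-classification by combining
    only the automatable evidence codes; variants whose automated class is
    uncertain enter the pool. ``potential_pathogenic`` marks pool members
    with REVEL > 0.7 that are absent from, or uncertain in, the variant
    database.
    """
    _check_panel_scope(variants, panel)
    pool: list[ClassifiedVariant] = []
    for v in frequency_filter(variants, maf_threshold):
        evidence = automated_evidence(v, panel[v.gene])
        cls = combine_acmg_evidence(evidence, rules)
        if cls != "VUS":
            continue
        potential = (
            v.revel is not None
            and v.revel > INSILICO_MIN_REVEL
            and v.clinvar_assertion in ("absent", "vus")
        )
        pool.append(
            ClassifiedVariant(
                v, "vus_pool", evidence=evidence, final_class="VUS",
                potential_pathogenic=potential,
            )
        )
    return pool


def classify_candidates(
    candidates: list[ClassifiedVariant],
    panel: GenePanel,
    rules: CombiningRules | None = None,
    adopt_database_assertion: bool = True,
) -> list[ClassifiedVariant]:
    """Assign evidence and a final class to routed candidates.

    Evidence is the automated code set. When ``adopt_database_assertion`` is
    on (default), a candidate on the clinvar route whose assertion is
    pathogenic / likely-pathogenic and which attracts no benign-side evidence
    adopts that class directly — the deterministic stand-in for expert
    concordance review. Everything else goes through the combining rules.
    Candidates flagged for manual review are never auto-classified above VUS.
    """
    out: list[ClassifiedVariant] = []
    for cand in candidates:
        v = cand.variant
        evidence = automated_evidence(v, panel.get(v.gene))
        cls = combine_acmg_evidence(evidence, rules)
        if (
            adopt_database_assertion
            and cand.route == "clinvar_lp_p"
            and v.clinvar_assertion in ("pathogenic", "likely_pathogenic")
            and not any(code.startswith("B") for code in evidence)
        ):
            cls = "P" if v.clinvar_assertion == "pathogenic" else "LP"
        if cand.needs_manual_review and cls in ("P", "LP"):
            cls = "VUS"
        out.append(
            ClassifiedVariant(
                v,
                cand.route,
                evidence=evidence,
                final_class=cls,
                needs_manual_review=cand.needs_manual_review,
            )
        )
    return out


def assign_carrier_status(
    participant_id: str,
    classified: list[ClassifiedVariant],
    panel: GenePanel,
) -> CarrierStatus:
    """Determine actionable carriage for one participant's variants.

    Dominant and X-linked genes are actionable on a single P/LP allele;
    recessive genes require a biallelic genotype (homozygous, or two distinct
    heterozygous P/LP variants in the same gene — phase unknown, assumed in
    trans). Heterozygous P/LP variants in recessive genes are reported as
    recessive-carrier-only and are not actionable.
    """
    for cand in classified:
        if cand.variant.participant_id != participant_id:
            raise ScopingError(
                f"variant for {cand.variant.participant_id} passed to "
                f"carrier assignment of {participant_id}"
            )
    plp = [c for c in classified if c.final_class in ("P", "LP")]
    actionable: list[ClassifiedVariant] = []
    recessive_only: list[str] = []
    by_gene: dict[str, list[ClassifiedVariant]] = {}
    for c in plp:
        by_gene.setdefault(c.variant.gene, []).append(c)
    for gene, hits in by_gene.items():
        mode = panel[gene].inheritance if gene in panel else "AD"
        if mode in ("AD", "XL"):
            actionable.extend(hits)
        else:  # AR
            biallelic = any(h.variant.zygosity == "hom" for h in hits) or len(hits) >= 2
            if biallelic:
                actionable.extend(hits)
            else:
                recessive_only.append(gene)
    sf_actionable = [
        c for c in actionable if c.variant.gene in panel and panel[c.variant.gene].acmg_sf
    ]
    return CarrierStatus(
        participant_id=participant_id,
        is_carrier=bool(actionable),
        actionable_variants=actionable,
        acmg_sf_carrier=bool(sf_actionable),
        recessive_carrier_genes=sorted(recessive_only),
    )


@dataclass
class TriageResult:
    """Cohort-level triage output with per-stage funnel counts."""

    classified: list[ClassifiedVariant]
    vus_pool: list[ClassifiedVariant]
    carrier_status: dict[str, CarrierStatus]
    funnel: dict[str, int]


def triage_cohort(
    variants: list[VariantRecord],
    panel: GenePanel,
    participant_ids: list[str] | None = None,
    rules: CombiningRules | None = None,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> TriageResult:
    """Run the full triage funnel over a cohort's variant records.

    ``participant_ids`` fixes the participant universe (participants with no
    variants still receive a non-carrier status); by default it is inferred
    from the records themselves.
    """
    _check_panel_scope(variants, panel)
    rare = frequency_filter(variants, maf_threshold)
    candidates = select_lp_candidates(variants, panel, maf_threshold)
    classified = classify_candidates(candidates, panel, rules)
    candidate_keys = {(c.variant.participant_id, c.variant.key()) for c in classified}
    vus_input = [v for v in rare if (v.participant_id, v.key()) not in candidate_keys]
    vus_pool = select_vus(vus_input, panel, rules, maf_threshold)

    if participant_ids is None:
        participant_ids = sorted({v.participant_id for v in variants})
    by_participant: dict[str, list[ClassifiedVariant]] = {p: [] for p in participant_ids}
    for c in classified:
        by_participant.setdefault(c.variant.participant_id, []).append(c)
    status = {
        pid: assign_carrier_status(pid, items, panel)
        for pid, items in by_participant.items()
    }
    funnel = {
        "input": len(variants),
        "rare": len(rare),
        "candidates": len(classified),
        "actionable": sum(
            1 for c in classified if c.final_class in ("P", "LP")
        ),
        "vus_pool": len(vus_pool),
        "carriers": sum(1 for s in status.values() if s.is_carrier),
    }
    return TriageResult(classified, vus_pool, status, funnel)


def classified_to_frame(classified: list[ClassifiedVariant]) -> pd.DataFrame:
    """Tabulate classified variants, one row per routed variant."""
    rows = []
    for c in classified:
        v = c.variant
        rows.append(
            {
                "participant_id": v.participant_id,
                "gene": v.gene,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "hgvs_c": v.hgvs_c,
                "hgvs_p": v.hgvs_p,
                "consequence": v.consequence,
                "zygosity": v.zygosity,
                "af_local": v.af_local,
                "af_gnomad": v.af_gnomad,
                "clinvar_assertion": v.clinvar_assertion,
                "has_lp_or_p_entry": v.has_lp_or_p_entry,
                "revel": v.revel,
                "route": c.route,
                "evidence": ";".join(c.evidence),
                "final_class": c.final_class,
                "clinically_actionable": c.clinically_actionable,
                "potential_pathogenic": c.potential_pathogenic,
                "needs_manual_review": c.needs_manual_review,
            }
        )
    return pd.DataFrame(rows)


def write_triage_outputs(result: TriageResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the classified-variants TSV and per-participant carrier JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "classified_variants.tsv"
    classified_to_frame(result.classified + result.vus_pool).to_csv(
        tsv, sep="\t", index=False
    )
    carriers = {
        pid: {
            "is_carrier": s.is_carrier,
            "acmg_sf_carrier": s.acmg_sf_carrier,
            "actionable_genes": [c.variant.gene for c in s.actionable_variants],
            "recessive_carrier_genes": s.recessive_carrier_genes,
        }
        for pid, s in sorted(result.carrier_status.items())
    }
    carrier_json = out_dir / "carrier_status.json"
    carrier_json.write_text(json.dumps(carriers, indent=1, sort_keys=True))
    return {"classified": tsv, "carriers": carrier_json}
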