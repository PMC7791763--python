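"""Variant triage on a handful of annotated records.

Builds a few variant records by hand, routes them through the triage
criteria (database assertion > loss-of-function in a haploinsufficient
gene > high in-silico score), combines automated evidence into a final
class, and assigns carrier status.
"""

from fhconcord import VariantRecord, assign_carrier_status, load_default_panel
from fhconcord.triage import classify_candidates, select_lp_candidates, select_vus

panel = load_default_panel()

variants = [
    # database-asserted pathogenic frameshift in BRCA2
    VariantRecord("P1", "BRCA2", "3", 1_201_000, "CT", "C", "frameshift_indel",
                  af_gnomad=2e-5, clinvar_assertion="pathogenic", has_lp_or_p_entry=True),
    # rare stopgain in ATM (haploinsufficient): loss-of-function candidate
    VariantRecord("P1", "ATM", "5", 2_403_000, "G", "T", "stopgain", af_gnomad=8e-4),
    # rare missense with a high ensemble score, absent from the database
    VariantRecord("P2", "PALB2", "7", 3_604_000, "A", "G", "missense",
                  af_gnomad=1e-4, revel=0.86),
    # rare missense, uncertain assertion, low score: uncertain pool
    VariantRecord("P2", "CHEK2", "9", 4_805_000, "T", "C", "missense",
                  af_local=0.004, clinvar_assertion="vus", revel=0.31),
]

candidates = classify_candidates(select_lp_candidates(variants, panel), panel)
pool = select_vus([v for v in variants
                   if v.key() not in {c.variant.key() for c in candidates}], panel)

print("routed candidates:")
for c in candidates:
    print(f"  {c.variant.participant_id} {c.variant.gene:<6} route={c.route:<18} "
          f"evidence={','.join(c.evidence) or '-':<14} class={c.final_class}")
print("uncertain pool:")
for c in pool:
    flag = " (potentially pathogenic)" if c.potential_pathogenic else ""
    print(f"  {c.variant.participant_id} {c.variant.gene:<6} class={c.final_class}{flag}")

for pid in ("P1", "P2"):
    status = assign_carrier_status(
        pid, [c for c in candidates if c.variant.participant_id == pid], panel
    )
    print(f"{pid}: carrier={status.is_carrier} "
          f"secondary_findings_carrier={status.acmg_sf_carrier}")

# A carrier is someone with a pathogenic / likely-pathogenic variant in a
# dominant or X-linked panel gene (or a biallelic recessive genotype).
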