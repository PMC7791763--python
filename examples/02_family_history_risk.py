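"""Family-history risk stratification with the default ruleset.

Builds two pedigrees — one with a qualifying same-lineage colorectal
cluster, one with only late-onset and non-cancer conditions — and shows
which rules fire. Also runs the bundled reference histories (published
carrier families assessed at average risk) through the ruleset.
"""

from fhconcord import Pedigree, RelativeRecord, assess_fh_risk, load_ruleset
from fhconcord.fhrisk import load_validation_families
from fhconcord.pedigree import make_diagnosis

ruleset = load_ruleset()

cluster = Pedigree(
    "FAM_A",
    relatives=[
        RelativeRecord("maternal_grandmother",
                       diagnoses=[make_diagnosis("colorectal", "50s")]),
        RelativeRecord("maternal_aunt",
                       diagnoses=[make_diagnosis("colorectal", "60s")]),
    ],
)
quiet = Pedigree(
    "FAM_B",
    relatives=[
        RelativeRecord("father", diagnoses=[make_diagnosis("hypertension", "60s")]),
        RelativeRecord("paternal_grandfather",
                       diagnoses=[make_diagnosis("lung", "70s")]),
    ],
)

for ped in (cluster, quiet):
    r = assess_fh_risk(ped, ruleset)
    print(f"{ped.participant_id}: {r.cohort:<9} rules={r.triggered_rules} "
          f"ambiguous={r.ambiguous}")

fams = load_validation_families()
calls = [assess_fh_risk(p, ruleset).cohort for p in fams["average_risk"]]
print(f"reference average-risk histories: {calls.count('average')}/{len(calls)} "
      "classified average")
# Increased risk requires a qualifying pattern (early onset, qualifying
# site, or same-lineage clustering) — a lone late-onset cancer is average.
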