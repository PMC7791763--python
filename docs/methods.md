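# Methods

This note documents the models, defaults and numerical choices behind
`fhconcord`, and what the synthetic cohorts do and do not establish about
behaviour on real data.

## Study design being modelled

An unselected adult screening cohort is assessed twice, independently:

1. **Family history.** About half the cohort provides a structured,
   four-generation family health history (children to grandparents and
   cousins, with per-relative cancer diagnoses and ages, often only known
   to the decade). A clinical ruleset stratifies each proband into
   *increased* or *average* familial cancer risk; participants with no
   collected history form a third cohort.
2. **Genotype.** Whole-genome variant calls restricted to a 95-gene
   cancer-predisposition panel are triaged to *clinically actionable*
   (pathogenic or likely pathogenic) variants. Family history is never an
   input to classification; the two assessments only meet at the
   concordance analysis.

The joint outcome is a carrier-status x history-cohort table, summarised
by relative risks and a concordance partition.

## Variant triage

The funnel, in order:

* **Frequency filter.** Keep variants with allele frequency strictly
  below 1% in *both* sources (local population database, broad reference
  database); an absent frequency passes. Both sources must pass because
  population-matched and global frequencies fail differently.
* **Candidate routing** (first match wins):
  1. *database route* — at least one pathogenic / likely-pathogenic
     database entry, checked without a frequency precondition and in
     exonic and intronic regions alike;
  2. *loss-of-function route* — frameshift/stopgain/stoploss/essential
     splice at MAF < 1% in a gene whose haploinsufficiency mechanism is
     established (`haploinsufficient: yes` in the panel). Genes with an
     `unknown` verdict route to a manual-review flag and are never
     auto-classified above uncertain; a refuted mechanism (`no`) sends
     loss-of-function variants to the uncertain pool.
  3. *in-silico route* — absent from the database, MAF < 1% and
     REVEL > 0.7 (strict).
* **Classification.** Automated evidence codes: PVS1 (LoF +
  haploinsufficiency), PM2 (frequency below 1e-4 or absent in both
  sources), PP3/BP4 (REVEL > 0.7 / < 0.3), PP5/BP6 (concordant database
  assertion), BA1 (frequency > 5%). Codes combine through the standard
  combining-rule table shipped as YAML; any pathogenic-side class meeting
  a benign-side class is *conflicting* and reported as uncertain — the
  deterministic rendering of "resolved by expert discussion". A candidate
  on the database route with a pathogenic/likely-pathogenic assertion and
  no benign-side evidence adopts that class directly; this replaces the
  manual concordance review a clinical team would perform and is the one
  place the pipeline trusts an external assertion over its own evidence
  arithmetic (switchable off via `classify_candidates`).
* **Carrier status.** Actionable carriage = P/LP in a dominant or
  X-linked panel gene, or a biallelic recessive genotype (homozygous, or
  two distinct heterozygous P/LP variants in one recessive gene, phase
  unknown and assumed in trans). Heterozygous P/LP in recessive genes is
  reported as recessive-carrier-only and is *not* actionable.

The uncertain pool is selected from frequency-filtered variants whose
automated class is uncertain, with a `potential_pathogenic` flag for
REVEL > 0.7 and a silent/uncertain database entry. Pool sizes depend
heavily on live database states and are not treated as reproducible
quantities.

## Family-history rules engine

Relations determine degree (1st: parent/sibling/child; 2nd:
grandparent/aunt/uncle; 3rd: cousin) and lineage (maternal/paternal;
siblings and children count to both sides). Rules count **distinct
affected relatives** matching a cancer-term set, optionally within one
lineage, with optional overall and "at least one early" age limits.
Counting relatives rather than diagnosis events means one relative with
two Lynch-spectrum primaries contributes once to pair rules — a
conservative choice, noted as a limitation.

Default ruleset (a documented approximation of the hereditary
breast/ovarian and hereditary colorectal clinical testing criteria; every
threshold editable in YAML):

| rule | fires on |
|---|---|
| breast_early_onset | breast ≤ 45 y, 1st/2nd degree |
| breast_pair_one_under_50 | ≥ 2 breast same lineage, ≥ 1 ≤ 50 y |
| ovarian_any_age | ovarian, any age, 1st/2nd degree |
| male_breast | male breast cancer, any age |
| hboc_cluster | ≥ 3 breast/prostate/pancreatic same lineage |
| colorectal_endometrial_early | colorectal or endometrial ≤ 49 y |
| colorectal_pair_same_side | ≥ 2 colorectal same lineage, any age |
| lynch_spectrum_pair_early | ≥ 2 Lynch-spectrum same lineage, ≥ 1 ≤ 49 y |
| lynch_spectrum_triple | ≥ 3 Lynch-spectrum same lineage, any age |
| unknown_cancer_pair_early | ≥ 2 unknown-type cancers ≤ 49 y same lineage |

Design notes:

* The Lynch-spectrum pair rule carries an early-onset requirement, with a
  colorectal-only pair rule and an any-age triple rule alongside. A pair
  rule without any age component would flag families with two late-onset
  spectrum cancers (e.g. urothelial at 65 plus colorectal at 76), which
  clinical review treats as average risk; the bundled reference histories
  pin this behaviour.
* Decade bands map to the band midpoint ("50s" → 55). An unknown age
  never satisfies an age limit on its own; if relaxing unknown ages would
  make an otherwise-silent rule fire, the result is flagged `ambiguous`
  rather than escalated — marking where a clinical team would have
  reviewed, without pretending to reproduce that review's outcome.
* Cousins are stored but excluded from rule counts by default (guideline
  treatment of 3rd-degree relatives is inconsistent); a custom ruleset
  can include degree 3.
* Non-cancer conditions are stored and ignored by the cancer ruleset.

The engine is monotone (adding an affected relative can only move a
family toward increased risk) and order-independent; both are property
tests.

## Statistics

For a table (a carriers of n1 exposed; c of n2 unexposed):

    RR       = (a/n1) / (c/n2)
    SE(lnRR) = sqrt(1/a − 1/n1 + 1/c − 1/n2)
    95% CI   = exp(ln RR ± 1.959964 · SE)

Zero cells report the estimate as undefined by default; a
Haldane-Anscombe +0.5 correction is available by flag. The significance
test is a two-tailed Fisher exact test by probability summation, computed
with exact integer table weights (`C(n1,k)·C(n2,K−k)`) so that
probability ties are decided exactly — the acceptance suite checks bit
equality against a full fixed-margin enumeration for every table with
total ≤ 60. A Yates-corrected chi-square is available as an option; the
choice of test changes small p-values' digits, so only significance calls
are treated as stable.

**Display conventions.** Ratios (RR and CI bounds) are *truncated toward
zero* at the displayed precision, so a displayed bound never overstates
the estimate; reports render both 1- and 2-decimal forms. Percentages are
rounded half away from zero to one decimal. "1 in N" strings (N = total /
carriers rounded half away from zero) are display-only.

## Synthetic cohorts

The generator produces exactly the pipeline's input surface — a
multi-sample VCF (genotypes in GT), the annotation TSV, per-family
pedigree JSON, a participant table — plus a ground-truth JSON that the
pipeline never reads (a test deletes it and re-runs the pipeline to pin
that).

* **Golden preset** (`designed_counts`): 1750 participants (median age
  45, range 16–88; 52.1% female; ethnicity mix matching the modelled
  population), 866 with family history (73 increased-risk, 793 average),
  884 without; 44 actionable carriers split 10/17/17 across the cohorts,
  5/3/4 of them in secondary-findings genes, every carrier gene
  autosomal-dominant with an established haploinsufficiency mechanism and
  at most one actionable variant per participant. Increased-risk
  histories come from a fixed 73-family template mix (122 familial cancer
  reports: breast 38.5%, ovarian 18.0%, colorectal 10.7%, unknown type
  10.7%, other sites 22.1%; 42 families with more than one cancer type),
  every template provably firing at least one default rule;
  average-intent families draw only patterns that provably cannot fire
  (single late-onset diagnoses from a safe menu, placed on
  lineage-specific relatives, at most one per lineage). Around a thousand
  decoy variant sites (rare low-score missense, high-score missense
  absent from the database, synonymous/intronic, common filtered
  variants, loss-of-function in genes without a haploinsufficiency
  mechanism) exercise every filter without ever classifying pathogenic.
  Recovery of the design is therefore exact, which is the point: the
  preset tests the pipeline's bookkeeping end to end, not its robustness
  to noise.
* **Designed rates** (`designed_rates`): fixed cohort sizes, Bernoulli
  carrier draws at per-cohort rates; the generative RR is the rate ratio
  in closed form. Used by the recovery harness (default per-replicate
  n = 600 with 72 increased — sizes chosen to keep zero cells rare while
  preserving the asymptotics the interval relies on).
* **Penetrance mode** (`penetrance`): a latent familial variant enters
  with probability θ through one grandparent, segregates with Mendelian
  probability 0.5 to parents/aunts/uncles, the proband and siblings; each
  relative's diagnosis is drawn from lifetime risk × a normal onset-age
  CDF truncated at current age (defaults: carrier lifetime risk 0.65,
  background 0.05, onset 52 ± 10 y). Family-history risk *emerges* from
  the rules engine. Used for the monotonicity sweep (higher carrier
  penetrance ⇒ higher estimated enrichment) and null calibration.

A single seed drives one generator stream; identical configs give
byte-identical outputs (tested).

**What passing on synthetic data does not show.** The golden preset
plants annotation profiles that the triage rules recognise by
construction; it cannot detect miscalibration against real annotation
noise (discordant database assertions, frequency-source disagreement,
consequence misannotation), self-reported-history error, or pedigree
structures outside the four-generation template. The penetrance model has
no de-novo mutation, no haplotype structure, and single-gene penetrance
only.

## Recovery harness results (recomputed by `scripts/acceptance.py`)

200 replicates at designed RR 6.4: interval coverage lands in the
0.93–0.97 band (binomial noise for 200 draws at 0.95 is ±0.015 SD);
the geometric-mean estimate sits on the design. The arithmetic mean of an
RR estimator is biased upward by ≈ exp(SE²/2), so the null scenario is
asserted as mean ≈ 1 with that allowance.

## Known limitations

* The default panel is a documented reconstruction of a plausible
  95-gene cancer panel, not a clinically validated list; the
  haploinsufficiency verdicts carry the triage weight and must be curated
  for real use.
* The default ruleset approximates clinical testing criteria; it is
  pinned by reference histories but is not the guideline text, and
  borderline pedigrees that a clinical team escalated on judgement will
  be flagged ambiguous rather than escalated.
* The database-assertion adoption step inherits database
  misclassifications; turning it off demotes assertion-only candidates to
  the evidence arithmetic.
* Uncertain-pool totals and VUS rates depend on live database snapshots
  and are not reproducible quantities; they are reported but not
  asserted.
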