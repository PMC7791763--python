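"""Synthetic study cohorts: participants, pedigrees, annotated variants.

Every pipeline stage can be exercised with no external data. The generator
emits exactly what the pipeline consumes — a multi-sample VCF, an
annotation table, per-family pedigree JSON, a participant table — plus a
ground-truth record that the pipeline never reads.

Three generation modes:

``designed_counts``
    Plants an exact cohort composition (group sizes, carriers per group,
    secondary-findings carriers per group). The bundled ``golden_cohort``
    preset reproduces the designed study composition: 1750 participants,
    866 with family history (73 increased-risk, 793 average), 884 without;
    44 clinically actionable carriers split 10/17/17 across the cohorts
    (5/3/4 of them in secondary-findings genes); increased-risk family
    histories drawn from a fixed 73-family template mix (122 familial
    cancer reports: 38.5% breast, 18.0% ovarian, 10.7% colorectal, 10.7%
    unknown type; 42 families with more than one cancer type).

``designed_rates``
    Fixed group sizes with Bernoulli carrier draws at per-group rates, so
    the generative relative risk is known in closed form — the
    parameter-recovery harness uses this.

``penetrance``
    A generative family model: a latent familial variant (probability
    theta) enters through one grandparent couple, segregates by Mendelian
    transmission, and each relative's cancer status is drawn from a
    lifetime-risk x onset-age penetrance model given their latent genotype.
    Family-history risk then *emerges* from the rules engine rather than
    being planted.

Family-history intent in the designed modes is realised with history
templates that provably fire (or provably cannot fire) the default
ruleset, so pipeline recovery of the design is exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .panel import GenePanel, load_default_panel
from .pedigree import Pedigree, RelativeRecord, make_diagnosis, pedigree_to_dict
from .variants import VariantRecord

NONCANCER_CONDITIONS = [
    "hypertension",
    "diabetes",
    "high cholesterol",
    "heart disease",
    "stroke",
    "asthma",
    "arthritis",
]

# cancers safe to report in average-risk families: single reports at >= 55y
# on lineage-specific relatives cannot fire any default rule
SAFE_LATE_CANCERS = [
    ("lung", None),
    ("liver", None),
    ("prostate", "M"),
    ("gastric", None),
    ("colorectal", None),
    ("breast", "F"),
    ("thyroid", None),
    ("kidney", None),
    ("cervical", "F"),
]

_FEMALE_SLOTS = [
    "mother",
    "maternal_aunt",
    "paternal_aunt",
    "maternal_grandmother",
    "paternal_grandmother",
]
_MALE_SLOTS = [
    "father",
    "maternal_uncle",
    "paternal_uncle",
    "maternal_grandfather",
    "paternal_grandfather",
]
_LINEAGE_SLOTS = {
    "maternal": [
        "mother",
        "maternal_aunt",
        "maternal_uncle",
        "maternal_grandmother",
        "maternal_grandfather",
    ],
    "paternal": [
        "father",
        "paternal_aunt",
        "paternal_uncle",
        "paternal_grandmother",
        "paternal_grandfather",
    ],
}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PenetranceModel:
    """Lifetime risk and onset-age model for one associated cancer."""

    carrier_lifetime_risk: float = 0.65
    background_lifetime_risk: float = 0.05
    onset_mean: float = 52.0
    onset_sd: float = 10.0


@dataclass
class SimulationConfig:
    mode: str = "designed_counts"  # designed_counts | designed_rates | penetrance
    n_participants: int = 1750
    seed: int = 0
    # designed_counts
    n_fh_available: int = 866
    n_increased: int = 73
    carriers_increased: int = 10
    carriers_average: int = 17
    carriers_unavailable: int = 17
    sf_carriers: tuple[int, int, int] = (5, 3, 4)  # increased, average, unavailable
    # designed_rates
    p_carrier_increased: float = 0.32
    p_carrier_average: float = 0.05
    # penetrance
    familial_variant_prob: float = 0.25
    transmission_prob: float = 0.5  # Mendelian
    penetrance: PenetranceModel = field(default_factory=PenetranceModel)
    # decoys
    decoy_pool_size: int = 1000
    decoy_rate: float = 2.2  # Poisson mean per participant
    off_panel_fraction: float = 0.02
    # demographics
    female_fraction: float = 0.521
    ethnicity_weights: dict = field(
        default_factory=lambda: {
            "Chinese": 0.893,
            "Indian": 0.042,
            "Malay": 0.039,
            "Other": 0.026,
        }
    )

    def __post_init__(self) -> None:
        probs = [
            self.p_carrier_increased,
            self.p_carrier_average,
            self.familial_variant_prob,
            self.transmission_prob,
            self.female_fraction,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("simulation probabilities must lie in [0, 1]")
        if self.mode not in ("designed_counts", "designed_rates", "penetrance"):
            raise ConfigurationError(f"unknown simulation mode {self.mode!r}")
        if self.mode == "designed_counts":
            if self.n_fh_available > self.n_participants:
                raise ConfigurationError("n_fh_available exceeds n_participants")
            if self.n_increased > self.n_fh_available:
                raise ConfigurationError("n_increased exceeds n_fh_available")

    @property
    def designed_rr(self) -> float | None:
        """Closed-form generative RR for the designed_rates mode."""
        if self.mode != "designed_rates":
            return None
        return self.p_carrier_increased / self.p_carrier_average


def golden_config(seed: int = 20210107) -> SimulationConfig:
    """The golden preset: the designed study composition, fully determined
    by the seed."""
    return SimulationConfig(mode="designed_counts", seed=seed)


def load_sim_config(path: str | Path) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if "penetrance" in doc and isinstance(doc["penetrance"], dict):
        doc["penetrance"] = PenetranceModel(**doc["penetrance"])
    if "sf_carriers" in doc:
        doc["sf_carriers"] = tuple(doc["sf_carriers"])
    try:
        return SimulationConfig(**doc)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# golden family-history template mix
#
# 73 increased-risk families, 122 familial cancer reports:
# breast 47 (38.5%), ovarian 22 (18.0%), colorectal 13 (10.7%),
# unknown type 13 (10.7%), other sites 27 (22.1%); 42/73 families report
# more than one cancer type.

GOLDEN_INCREASED_TEMPLATES: list[tuple[str, str | None]] = (
    [("breast_single", None)] * 15
    + [("ovarian_single", None)] * 7
    + [("colorectal_early_single", None)] * 3
    + [("unknown_pair", None)] * 5
    + [("unknown_triple", None)] * 1
    + [("breast_ovarian", None)] * 15
    + [("breast_plus", "prostate")] * 6
    + [("breast_plus", "pancreatic")] * 4
    + [("breast_plus", "lung")] * 4
    + [("breast_plus", "cervical")] * 2
    + [("breast_plus", "thyroid")] * 1
    + [("colorectal_plus", "gastric")] * 3
    + [("colorectal_plus", "liver")] * 3
    + [("colorectal_plus", "endometrial")] * 4
)

# carrier gene plans for the golden preset (all autosomal dominant with an
# established haploinsufficiency mechanism in the default panel)
GOLDEN_CARRIER_GENES = {
    "increased": ["BRCA1", "BRCA1", "BRCA2", "BRCA2", "MSH2",
                  "ATM", "PALB2", "RAD51C", "SUFU", "AXIN2"],
    "average": ["BRCA2", "BRCA2", "BRCA2",
                "ATM", "ATM", "BRIP1", "DICER1", "LZTR1", "LZTR1", "RAD50",
                "RAD51C", "RAD51D", "RAD51D", "RAD51D", "CHEK2", "PALB2", "BARD1"],
    "unavailable": ["BRCA2", "BRCA2", "BRCA1", "MSH6",
                    "ATM", "ATM", "CHEK2", "CHEK2", "PALB2", "RAD51C", "RAD51D",
                    "BRIP1", "DICER1", "LZTR1", "RAD50", "BARD1", "SUFU"],
}


def _pick(rng: np.random.Generator, items: list):
    return items[int(rng.integers(len(items)))]


def _template_diagnoses(
    rng: np.random.Generator, template: str, extra: str | None
) -> list[tuple[str, str, object]]:
    """Realise one increased-risk template as (relation, condition, age)."""
    lineage = _pick(rng, ["maternal", "paternal"])
    other = "paternal" if lineage == "maternal" else "maternal"
    fem = [s for s in _LINEAGE_SLOTS[lineage] if s in _FEMALE_SLOTS]
    male = [s for s in _LINEAGE_SLOTS[lineage] if s in _MALE_SLOTS]
    fem_other = [s for s in _LINEAGE_SLOTS[other] if s in _FEMALE_SLOTS]
    male_other = [s for s in _LINEAGE_SLOTS[other] if s in _MALE_SLOTS]

    def early_breast_age():
        return int(rng.integers(36, 46))  # <= 45 fires the early-onset rule

    if template == "breast_single":
        return [(_pick(rng, fem + ["sister"]), "breast", early_breast_age())]
    if template == "ovarian_single":
        return [(_pick(rng, fem + ["sister"]), "ovarian", int(rng.integers(42, 72)))]
    if template == "colorectal_early_single":
        slot = _pick(rng, fem + male + ["sister", "brother"])
        return [(slot, "colorectal", int(rng.integers(38, 49)))]
    if template == "unknown_pair":
        a, b = f"{lineage}_uncle", f"{lineage}_aunt"
        return [(a, "unknown cancer", "30s"), (b, "unknown cancer", "40s")]
    if template == "unknown_triple":
        return [
            (f"{lineage}_uncle", "unknown cancer", "30s"),
            (f"{lineage}_aunt", "unknown cancer", "40s"),
            (f"{lineage}_grandmother", "unknown cancer", "40s"),
        ]
    if template == "breast_ovarian":
        return [
            (_pick(rng, fem), "breast", _pick(rng, ["50s", "60s"])),
            (_pick(rng, fem_other + ["sister"]), "ovarian", int(rng.integers(45, 70))),
        ]
    if template == "breast_plus":
        if extra == "prostate":
            slot = _pick(rng, male_other)
        elif extra in ("cervical",):
            slot = _pick(rng, fem_other)
        else:
            slot = _pick(rng, fem_other + male_other)
        return [
            (_pick(rng, fem), "breast", early_breast_age()),
            (slot, extra, _pick(rng, ["50s", "60s", "70s"])),
        ]
    if template == "colorectal_plus":
        if extra == "endometrial":
            slot = _pick(rng, fem_other)
        else:
            slot = _pick(rng, fem_other + male_other)
        return [
            (_pick(rng, fem + male), "colorectal", int(rng.integers(40, 48))),
            (slot, extra, _pick(rng, ["60s", "70s"])),
        ]
    raise ConfigurationError(f"unknown template {template!r}")


def _safe_average_diagnoses(rng: np.random.Generator) -> list[tuple[str, str, object]]:
    """Cancer reports that provably cannot fire the default ruleset:
    single late-onset diagnoses from the safe menu, at most one per
    lineage, never on siblings/children (which count to both lineages)."""
    k = int(rng.choice([0, 1, 2], p=[0.45, 0.35, 0.20]))
    if k == 0:
        return []
    lineages = ["maternal", "paternal"]
    rng.shuffle(lineages)
    out = []
    picks = rng.choice(len(SAFE_LATE_CANCERS), size=k, replace=False)
    for lineage, pick in zip(lineages, picks):
        condition, sex = SAFE_LATE_CANCERS[int(pick)]
        slots = _LINEAGE_SLOTS[lineage]
        if sex == "F":
            slots = [s for s in slots if s in _FEMALE_SLOTS]
        elif sex == "M":
            slots = [s for s in slots if s in _MALE_SLOTS]
        out.append((_pick(rng, slots), condition, _pick(rng, ["60s", "70s", "80s"])))
    return out


def _base_pedigree(
    rng: np.random.Generator,
    participant_id: str,
    proband_sex: str,
    proband_age: int,
) -> Pedigree:
    """Fixed four-generation scaffold with stochastic extras and noise."""
    relatives = []

    def add(relation, sex="unknown", age=None):
        rel = RelativeRecord(relation=relation, sex=sex, age=age)
        relatives.append(rel)
        return rel

    parent_age = proband_age + int(rng.integers(24, 33))
    grand_age = parent_age + int(rng.integers(24, 33))
    add("father", "M", parent_age)
    add("mother", "F", parent_age - int(rng.integers(0, 4)))
    for side in ("maternal", "paternal"):
        add(f"{side}_grandfather", "M", grand_age)
        add(f"{side}_grandmother", "F", grand_age - int(rng.integers(0, 5)))
        add(f"{side}_aunt", "F", parent_age + int(rng.integers(-6, 7)))
        add(f"{side}_uncle", "M", parent_age + int(rng.integers(-6, 7)))
        for _ in range(int(rng.integers(0, 3))):
            add(f"{side}_cousin", _pick(rng, ["M", "F"]), proband_age + int(rng.integers(-8, 9)))
    add("sister", "F", proband_age + int(rng.integers(-6, 7)))
    add("brother", "M", proband_age + int(rng.integers(-6, 7)))
    if proband_age >= 40 and rng.random() < 0.5:
        add(_pick(rng, ["son", "daughter"]), "unknown", proband_age - int(rng.integers(20, 28)))
    # non-cancer background noise
    for rel in relatives:
        if rel.age is not None and rel.age >= 50 and rng.random() < 0.35:
            cond = _pick(rng, NONCANCER_CONDITIONS)
            rel.diagnoses.append(
                make_diagnosis(cond, f"{min(8, max(3, rel.age // 10 - 1)) * 10}s")
            )
        if rel.age is not None and rel.age >= 75 and rng.random() < 0.4:
            rel.deceased = True
    return Pedigree(
        participant_id=participant_id,
        fh_available=True,
        relatives=relatives,
        proband_sex=proband_sex,
        proband_age=proband_age,
    )


def _attach(pedigree: Pedigree, placements: list[tuple[str, str, object]]) -> None:
    by_relation: dict[str, list[RelativeRecord]] = {}
    for rel in pedigree.relatives:
        by_relation.setdefault(rel.relation, []).append(rel)
    for relation, condition, age in placements:
        targets = by_relation.get(relation)
        if not targets:
            rel = RelativeRecord(relation=relation)
            pedigree.relatives.append(rel)
            by_relation.setdefault(relation, []).append(rel)
            targets = by_relation[relation]
        targets[0].diagnoses.append(make_diagnosis(condition, age))


# ---------------------------------------------------------------------------
# variants


@dataclass
class _Locus:
    gene: str
    chrom: str
    base: int


def _gene_loci(panel: GenePanel, off_panel: list[str]) -> dict[str, _Locus]:
    loci = {}
    symbols = panel.symbols + off_panel
    for i, sym in enumerate(symbols):
        chrom = "X" if (sym in panel and panel[sym].inheritance == "XL") else str(i % 22 + 1)
        loci[sym] = _Locus(sym, chrom, 1_000_000 + i * 1_000_000)
    return loci


_OFF_PANEL_GENES = ["TTN", "OBSCN", "MUC16"]

_BASES = ["A", "C", "G", "T"]


@dataclass
class _SimVariant:
    """A unique site in the synthetic cohort's VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    af_local: float | None
    af_gnomad: float | None
    clinvar_assertion: str
    has_lp_or_p_entry: bool
    revel: float | None
    hgvs_c: str
    hgvs_p: str


def _planted_variant(
    rng: np.random.Generator, loci: dict[str, _Locus], gene: str, serial: int
) -> _SimVariant:
    locus = loci[gene]
    pos = locus.base + 1000 + serial * 13
    ref = _pick(rng, _BASES)
    return _SimVariant(
        chrom=locus.chrom,
        pos=pos,
        ref=ref + "TG",
        alt=ref,
        gene=gene,
        consequence="frameshift_indel",
        af_local=None,
        af_gnomad=2e-5,
        clinvar_assertion="pathogenic",
        has_lp_or_p_entry=True,
        revel=None,
        hgvs_c=f"c.{serial + 101}del",
        hgvs_p=f"p.X{serial + 34}fs",
    )


def _decoy_pool(
    rng: np.random.Generator,
    panel: GenePanel,
    loci: dict[str, _Locus],
    size: int,
    off_panel_fraction: float,
) -> list[_SimVariant]:
    """Benign/uncertain decoys that exercise the filters but can never be
    classified pathogenic by the automated pipeline."""
    pool = []
    lof_safe = [e.symbol for e in panel if e.haploinsufficient == "no"]
    panel_syms = panel.symbols
    for i in range(size):
        if rng.random() < off_panel_fraction:
            gene = _pick(rng, _OFF_PANEL_GENES)
        else:
            gene = _pick(rng, panel_syms)
        locus = loci[gene]
        pos = locus.base + 200_000 + i * 7
        ref = _pick(rng, _BASES)
        alt = _pick(rng, [b for b in _BASES if b != ref])
        kind = rng.random()
        revel = None
        clinvar = "absent"
        has_lp = False
        if kind < 0.40:  # rare missense, unremarkable in-silico score
            consequence = "missense"
            revel = round(float(rng.beta(2, 5)) * 0.69, 3)
            af = float(rng.uniform(1e-5, 8e-3))
            clinvar = _pick(rng, ["absent", "vus", "vus", "likely_benign"])
        elif kind < 0.50:  # rare missense, high in-silico score
            consequence = "missense"
            revel = round(float(rng.uniform(0.71, 0.98)), 3)
            af = float(rng.uniform(1e-5, 5e-3))
            clinvar = _pick(rng, ["absent", "vus"])
        elif kind < 0.65:  # synonymous / intronic
            consequence = _pick(rng, ["synonymous", "intronic", "inframe_indel"])
            af = float(rng.uniform(1e-5, 9e-3))
        elif kind < 0.80:  # common, removed by the frequency filter
            consequence = _pick(rng, ["missense", "synonymous"])
            af = float(rng.uniform(0.015, 0.08))
            clinvar = _pick(rng, ["benign", "likely_benign", "absent"])
            if consequence == "missense":
                revel = round(float(rng.beta(2, 6)), 3)
        else:  # loss of function in a gene without a haploinsufficiency mechanism
            consequence = _pick(rng, ["stopgain", "frameshift_indel"])
            gene = _pick(rng, lof_safe)
            locus = loci[gene]
            pos = locus.base + 200_000 + i * 7
            af = float(rng.uniform(1e-5, 6e-3))
        af_gnomad = round(af, 6)
        af_local = round(af * float(rng.uniform(0.4, 1.8)), 6) if rng.random() < 0.8 else None
        if af_local is not None and af_local > 1.0:
            af_local = 1.0
        pool.append(
            _SimVariant(
                chrom=locus.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                consequence=consequence,
                af_local=af_local,
                af_gnomad=af_gnomad,
                clinvar_assertion=clinvar,
                has_lp_or_p_entry=has_lp,
                revel=revel,
                hgvs_c=f"c.{i + 7}{ref}>{alt}",
                hgvs_p="",
            )
        )
    return pool


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort plus (optionally) its on-disk form."""

    config: SimulationConfig
    participants: pd.DataFrame  # participant_id, age, sex, ethnicity
    pedigrees: list[Pedigree]  # FH-available participants only
    variants: list[VariantRecord]  # per-participant observed records
    sites: list[_SimVariant]  # unique sites (VCF rows)
    genotypes: dict[tuple[str, int, str, str], dict[str, str]]  # site -> {pid: GT}
    ground_truth: dict[str, dict]
    paths: dict[str, Path] = field(default_factory=dict)


def _participant_frame(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    n = config.n_participants
    ids = [f"P{i + 1:05d}" for i in range(n)]
    # symmetric age quantiles around 45 give an exact median of 45 and the
    # designed 16-88 range at cohort scale
    from scipy.stats import norm

    q = (np.arange(n) + 0.5) / n
    ages = np.clip(np.round(45 + 13 * norm.ppf(q)), 16, 88).astype(int)
    if n >= 2:
        ages[0], ages[-1] = 16, 88
    rng.shuffle(ages)
    n_female = int(round(config.female_fraction * n))
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sexes)
    eth_names = list(config.ethnicity_weights)
    weights = np.array([config.ethnicity_weights[e] for e in eth_names], dtype=float)
    counts = np.floor(weights / weights.sum() * n).astype(int)
    counts[0] += n - counts.sum()
    ethnicity = np.repeat(eth_names, counts)
    rng.shuffle(ethnicity)
    return pd.DataFrame(
        {"participant_id": ids, "age": ages, "sex": sexes, "ethnicity": ethnicity}
    )


def _assign_groups_designed_counts(rng, config, ids):
    ids = list(ids)
    rng.shuffle(ids)
    fh_ids = ids[: config.n_fh_available]
    unavailable = ids[config.n_fh_available:]
    increased = fh_ids[: config.n_increased]
    average = fh_ids[config.n_increased:]
    plan = {}
    for group, members, n_carriers in (
        ("increased", increased, config.carriers_increased),
        ("average", average, config.carriers_average),
        ("unavailable", unavailable, config.carriers_unavailable),
    ):
        genes = list(GOLDEN_CARRIER_GENES[group][:n_carriers])
        if len(genes) < n_carriers:
            genes += [
                GOLDEN_CARRIER_GENES[group][i % len(GOLDEN_CARRIER_GENES[group])]
                for i in range(n_carriers - len(genes))
            ]
        carriers = members[:n_carriers]
        for pid, gene in zip(carriers, genes):
            plan[pid] = gene
    return increased, average, unavailable, plan


def _assign_groups_designed_rates(rng, config, ids, panel):
    ids = list(ids)
    rng.shuffle(ids)
    n_inc = int(round(config.n_increased))
    increased = ids[:n_inc]
    average = ids[n_inc: config.n_fh_available]
    unavailable = ids[config.n_fh_available:]
    ad_genes = [
        e.symbol
        for e in panel
        if e.inheritance == "AD" and e.haploinsufficient == "yes"
    ]
    plan = {}
    for members, p in ((increased, config.p_carrier_increased),
                       (average, config.p_carrier_average),
                       (unavailable, config.p_carrier_average)):
        draws = rng.random(len(members)) < p
        for pid, hit in zip(members, draws):
            if hit:
                plan[pid] = _pick(rng, ad_genes)
    return increased, average, unavailable, plan


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    panel: GenePanel | None = None,
) -> SimulatedCohort:
    """Generate a synthetic cohort; optionally write its on-disk form.

    The seed in ``config`` fully determines the output: two runs with the
    same config are identical record for record.
    """
    if config.mode == "penetrance":
        cohort = _simulate_penetrance(config, panel)
    else:
        cohort = _simulate_designed(config, panel)
    if out_dir is not None:
        cohort.paths = write_cohort(cohort, out_dir)
    return cohort


def _simulate_designed(config: SimulationConfig, panel: GenePanel | None) -> SimulatedCohort:
    panel = panel or load_default_panel()
    rng = np.random.default_rng(config.seed)
    participants = _participant_frame(rng, config)
    ids = participants["participant_id"].tolist()
    if config.mode == "designed_counts":
        increased, average, unavailable, carrier_plan = _assign_groups_designed_counts(
            rng, config, ids
        )
        templates = list(GOLDEN_INCREASED_TEMPLATES)
        if len(increased) != len(templates):
            templates = [
                templates[i % len(templates)] for i in range(len(increased))
            ]
        rng.shuffle(templates)
    else:
        increased, average, unavailable, carrier_plan = _assign_groups_designed_rates(
            rng, config, ids, panel
        )
        templates = [
            GOLDEN_INCREASED_TEMPLATES[int(rng.integers(len(GOLDEN_INCREASED_TEMPLATES)))]
            for _ in increased
        ]

    demo = participants.set_index("participant_id")
    pedigrees = []
    for pid, template in zip(increased, templates):
        ped = _base_pedigree(rng, pid, demo.at[pid, "sex"], int(demo.at[pid, "age"]))
        _attach(ped, _template_diagnoses(rng, template[0], template[1]))
        pedigrees.append(ped)
    for pid in average:
        ped = _base_pedigree(rng, pid, demo.at[pid, "sex"], int(demo.at[pid, "age"]))
        _attach(ped, _safe_average_diagnoses(rng))
        pedigrees.append(ped)

    sites, genotypes, variants = _make_variants(rng, config, panel, ids, carrier_plan)
    ground_truth = {
        pid: {
            "carrier": pid in carrier_plan,
            "gene": carrier_plan.get(pid),
            "acmg_sf": bool(carrier_plan.get(pid) and panel[carrier_plan[pid]].acmg_sf),
            "fh_intent": (
                "increased" if pid in set(increased)
                else "average" if pid in set(average)
                else "none"
            ),
        }
        for pid in ids
    }
    return SimulatedCohort(
        config=config,
        participants=participants,
        pedigrees=pedigrees,
        variants=variants,
        sites=sites,
        genotypes=genotypes,
        ground_truth=ground_truth,
    )


def _make_variants(rng, config, panel, ids, carrier_plan):
    loci = _gene_loci(panel, _OFF_PANEL_GENES)
    sites: list[_SimVariant] = []
    genotypes: dict[tuple, dict[str, str]] = {}
    variants: list[VariantRecord] = []

    for serial, (pid, gene) in enumerate(sorted(carrier_plan.items())):
        site = _planted_variant(rng, loci, gene, serial)
        key = (site.chrom, site.pos, site.ref, site.alt)
        sites.append(site)
        genotypes[key] = {pid: "0/1"}
        variants.append(_record_from_site(site, pid, "het"))

    pool = _decoy_pool(
        rng, panel, loci, config.decoy_pool_size, config.off_panel_fraction
    )
    pool_used = [False] * len(pool)
    counts = rng.poisson(config.decoy_rate, size=len(ids))
    for pid, k in zip(ids, counts):
        if k == 0:
            continue
        picks = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        for j in picks:
            site = pool[int(j)]
            key = (site.chrom, site.pos, site.ref, site.alt)
            common = site.af_gnomad is not None and site.af_gnomad > 0.04
            gt = "1/1" if (common and rng.random() < 0.1) else "0/1"
            genotypes.setdefault(key, {})[pid] = gt
            pool_used[int(j)] = True
            if site.gene in panel:
                variants.append(
                    _record_from_site(site, pid, "hom" if gt == "1/1" else "het")
                )
    for used, site in zip(pool_used, pool):
        if used:
            sites.append(site)
    sites.sort(key=lambda s: (_chrom_order(s.chrom), s.pos))
    return sites, genotypes, variants


def _chrom_order(chrom: str) -> int:
    return 23 if chrom == "X" else int(chrom)


def _record_from_site(site: _SimVariant, pid: str, zygosity: str) -> VariantRecord:
    return VariantRecord(
        participant_id=pid,
        gene=site.gene,
        chrom=site.chrom,
        pos=site.pos,
        ref=site.ref,
        alt=site.alt,
        consequence=site.consequence,
        zygosity=zygosity,
        hgvs_c=site.hgvs_c or None,
        hgvs_p=site.hgvs_p or None,
        af_local=site.af_local,
        af_gnomad=site.af_gnomad,
        clinvar_assertion=site.clinvar_assertion,
        has_lp_or_p_entry=site.has_lp_or_p_entry,
        revel=site.revel,
    )


# ---------------------------------------------------------------------------
# penetrance mode


def _simulate_penetrance(config: SimulationConfig, panel: GenePanel | None) -> SimulatedCohort:
    """Latent familial variant + Mendelian segregation + penetrance draws."""
    panel = panel or load_default_panel()
    rng = np.random.default_rng(config.seed)
    participants = _participant_frame(rng, config)
    ids = participants["participant_id"].tolist()
    demo = participants.set_index("participant_id")
    ad_genes = [
        e for e in panel if e.inheritance == "AD" and e.haploinsufficient == "yes"
    ]
    pen = config.penetrance
    pedigrees = []
    carrier_plan: dict[str, str] = {}
    fh_mask = rng.random(len(ids)) < (config.n_fh_available / config.n_participants)

    for pid, has_fh in zip(ids, fh_mask):
        ped = _base_pedigree(rng, pid, demo.at[pid, "sex"], int(demo.at[pid, "age"]))
        familial = rng.random() < config.familial_variant_prob
        gene_entry = ad_genes[int(rng.integers(len(ad_genes)))]
        cancer = next(
            (c for c in gene_entry.cancer_types if c in
             {"breast", "ovarian", "colorectal", "endometrial", "gastric",
              "pancreatic", "prostate", "thyroid", "kidney", "melanoma"}),
            "breast",
        )
        origin = _pick(rng, ["maternal", "paternal"]) if familial else None
        genotype: dict[str, bool] = {}
        if familial:
            genotype[f"{origin}_grandmother"] = True  # founder carrier
            parent = "mother" if origin == "maternal" else "father"
            t = config.transmission_prob
            genotype[parent] = rng.random() < t
            for slot in (f"{origin}_aunt", f"{origin}_uncle"):
                genotype[slot] = rng.random() < t
            if genotype[parent]:
                for slot in ("sister", "brother"):
                    genotype[slot] = rng.random() < t
            proband_carrier = genotype[parent] and rng.random() < t
        else:
            proband_carrier = False
        if proband_carrier:
            carrier_plan[pid] = gene_entry.symbol
        for rel in ped.relatives:
            if rel.age is None:
                continue
            carrier = genotype.get(rel.relation, False)
            lifetime = pen.carrier_lifetime_risk if carrier else pen.background_lifetime_risk
            if cancer in ("breast", "ovarian", "cervical", "endometrial") and rel.sex != "F":
                continue
            if cancer == "prostate" and rel.sex != "M":
                continue
            p_by_now = lifetime * _norm_cdf((rel.age - pen.onset_mean) / pen.onset_sd)
            if rng.random() < p_by_now:
                onset = pen.onset_mean + pen.onset_sd * float(rng.standard_normal())
                onset = int(np.clip(onset, 25, rel.age))
                rel.diagnoses.append(make_diagnosis(cancer, onset))
        if has_fh:
            pedigrees.append(ped)

    sites, genotypes, variants = _make_variants(rng, config, panel, ids, carrier_plan)
    fh_ids = {p.participant_id for p in pedigrees}
    ground_truth = {
        pid: {
            "carrier": pid in carrier_plan,
            "gene": carrier_plan.get(pid),
            "acmg_sf": bool(carrier_plan.get(pid) and panel[carrier_plan[pid]].acmg_sf),
            "fh_intent": "emergent" if pid in fh_ids else "none",
        }
        for pid in ids
    }
    return SimulatedCohort(
        config=config,
        participants=participants,
        pedigrees=pedigrees,
        variants=variants,
        sites=sites,
        genotypes=genotypes,
        ground_truth=ground_truth,
    )


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# on-disk form


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the VCF, annotation TSV, pedigree JSONs, participant table and
    ground truth. The pipeline consumes everything except the ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = cohort.participants["participant_id"].tolist()
    idx = {pid: i for i, pid in enumerate(ids)}

    vcf_path = out_dir / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fhconcord-simulate\n")
        for c in [str(i) for i in range(1, 23)] + ["X"]:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids)
            + "\n"
        )
        for site in cohort.sites:
            key = (site.chrom, site.pos, site.ref, site.alt)
            row = ["0/0"] * len(ids)
            for pid, gt in cohort.genotypes.get(key, {}).items():
                row[idx[pid]] = gt
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(row)
                + "\n"
            )

    ann_path = out_dir / "annotations.tsv"
    pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "gene": s.gene,
                "hgvs_c": s.hgvs_c,
                "hgvs_p": s.hgvs_p,
                "consequence": s.consequence,
                "af_local": s.af_local,
                "af_gnomad": s.af_gnomad,
                "clinvar_assertion": s.clinvar_assertion,
                "has_lp_or_p_entry": s.has_lp_or_p_entry,
                "revel": s.revel,
            }
            for s in cohort.sites
        ]
    ).to_csv(ann_path, sep="\t", index=False)

    ped_dir = out_dir / "pedigrees"
    ped_dir.mkdir(exist_ok=True)
    for ped in cohort.pedigrees:
        (ped_dir / f"{ped.participant_id}.json").write_text(
            json.dumps(pedigree_to_dict(ped))
        )

    part_path = out_dir / "participants.tsv"
    cohort.participants.to_csv(part_path, sep="\t", index=False)

    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(cohort.ground_truth, indent=0, sort_keys=True))

    return {
        "vcf": vcf_path,
        "annotations": ann_path,
        "pedigrees": ped_dir,
        "participants": part_path,
        "ground_truth": truth_path,
    }
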