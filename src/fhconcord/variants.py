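"""Annotated variant records and their file plumbing.

The pipeline starts from *called, annotated* variants: a VCF (v4.2,
single- or multi-sample, genotypes read from GT) joined one-to-one on
(chrom, pos, ref, alt) with an annotation table carrying the gene symbol,
consequence, two allele-frequency sources (a local population-matched
database and a broad reference database), the variant-database assertion,
and the REVEL in-silico score. Alignment and variant calling are upstream
and out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .errors import DataError, JoinError
from .panel import GenePanel
from .vocab import CLINVAR_ASSERTIONS, CONSEQUENCES, ZYGOSITIES

logger = logging.getLogger(__name__)

DEFAULT_MAF_THRESHOLD = 0.01

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "af_local",
    "af_gnomad",
    "clinvar_assertion",
    "has_lp_or_p_entry",
    "revel",
]


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant observed in one participant."""

    participant_id: str
    gene: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    consequence: str
    zygosity: str = "het"
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    af_local: float | None = None
    af_gnomad: float | None = None
    clinvar_assertion: str = "absent"
    has_lp_or_p_entry: bool = False
    revel: float | None = None
    confirmed: bool | None = None  # optional QC/orthogonal confirmation flag

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"{self.key()}: position must be >= 1")
        if self.ref == self.alt:
            raise DataError(f"{self.key()}: ref and alt are identical")
        if self.consequence not in CONSEQUENCES:
            raise DataError(
                f"{self.key()}: unknown consequence {self.consequence!r}"
            )
        if self.clinvar_assertion not in CLINVAR_ASSERTIONS:
            raise DataError(
                f"{self.key()}: unknown assertion {self.clinvar_assertion!r}"
            )
        if self.zygosity not in ZYGOSITIES:
            raise DataError(f"{self.key()}: unknown zygosity {self.zygosity!r}")
        for name, af in (("af_local", self.af_local), ("af_gnomad", self.af_gnomad)):
            if af is not None and not 0.0 <= af <= 1.0:
                raise DataError(f"{self.key()}: {name}={af} outside [0, 1]")
        if self.revel is not None and not 0.0 <= self.revel <= 1.0:
            raise DataError(f"{self.key()}: revel={self.revel} outside [0, 1]")

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def max_af(self) -> float | None:
        afs = [af for af in (self.af_local, self.af_gnomad) if af is not None]
        return max(afs) if afs else None


def _opt_float(value) -> float | None:
    if value is None or value == "" or pd.isna(value):
        return None
    return float(value)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate the annotation TSV; key columns must be unique."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing annotation column(s): {missing}")
    dupes = df.duplicated(subset=["chrom", "pos", "ref", "alt"], keep=False)
    if dupes.any():
        first = df.loc[dupes, ["chrom", "pos", "ref", "alt"]].iloc[0]
        raise JoinError(
            "duplicated annotation key "
            f"({first.chrom}, {first.pos}, {first.ref}, {first.alt})"
        )
    return df


def read_variants(
    vcf_path: str | Path,
    annotation_path: str | Path,
    panel: GenePanel,
) -> list[VariantRecord]:
    """Join a VCF with its annotation table into per-participant records.

    Only records whose gene resolves in ``panel`` are returned; off-panel
    records are counted and logged. Every annotation row must match a VCF
    record and vice versa (one-to-one on chrom/pos/ref/alt).
    """
    vcf_path, annotation_path = Path(vcf_path), Path(annotation_path)
    if not vcf_path.exists():
        raise DataError(f"VCF file not found: {vcf_path}")
    ann = read_annotations(annotation_path)
    ann_by_key = {
        (str(r.chrom), int(r.pos), r.ref, r.alt): r for r in ann.itertuples()
    }

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    off_panel = 0
    seen_keys: set[tuple] = set()
    for v in vcf:
        if len(v.ALT) != 1:
            raise DataError(
                f"{vcf_path}: multi-allelic record at {v.CHROM}:{v.POS}; "
                "normalise to bi-allelic sites first"
            )
        key = (str(v.CHROM), int(v.POS), v.REF, v.ALT[0])
        row = ann_by_key.get(key)
        if row is None:
            raise JoinError(f"VCF record with no annotation row: {key}")
        seen_keys.add(key)
        if row.gene not in panel:
            off_panel += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt_types = v.gt_types
        for idx, gt in enumerate(gt_types):
            if gt == 0 or gt == 2:
                continue
            zygosity = "het" if gt == 1 else "hom"
            records.append(
                VariantRecord(
                    participant_id=samples[idx] if samples else "sample_0",
                    gene=row.gene,
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    consequence=row.consequence,
                    zygosity=zygosity,
                    hgvs_c=None if pd.isna(row.hgvs_c) else row.hgvs_c,
                    hgvs_p=None if pd.isna(row.hgvs_p) else row.hgvs_p,
                    af_local=_opt_float(row.af_local),
                    af_gnomad=_opt_float(row.af_gnomad),
                    clinvar_assertion=row.clinvar_assertion,
                    has_lp_or_p_entry=bool(row.has_lp_or_p_entry),
                    revel=_opt_float(row.revel),
                )
            )
    unmatched = set(ann_by_key) - seen_keys
    if unmatched:
        key = sorted(unmatched)[0]
        raise JoinError(f"annotation row with no matching VCF record: {key}")
    if off_panel:
        logger.info("read_variants: %d off-panel record(s) skipped", off_panel)
    return records


def frequency_filter(
    variants: list[VariantRecord],
    threshold: float = DEFAULT_MAF_THRESHOLD,
) -> list[VariantRecord]:
    """Retain variants strictly below ``threshold`` in *both* frequency
    sources; an absent frequency counts as a pass. Comparison is strict
    (a frequency exactly at the threshold is excluded)."""
    if not 0.0 < threshold <= 1.0:
        raise DataError(f"MAF threshold {threshold} outside (0, 1]")
    return [v for v in variants if passes_frequency(v, threshold)]


def passes_frequency(v: VariantRecord, threshold: float = DEFAULT_MAF_THRESHOLD) -> bool:
    for af in (v.af_local, v.af_gnomad):
        if af is not None and af >= threshold:
            return False
    return True


def hemizygous_on_x(record: VariantRecord, sex: str | None) -> VariantRecord:
    """Re-mark a het X-chromosome call in a male as hemizygous."""
    if record.chrom in ("X", "chrX") and sex == "M" and record.zygosity == "het":
        return replace(record, zygosity="hemi")
    return record
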