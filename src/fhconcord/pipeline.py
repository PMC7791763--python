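"""End-to-end orchestration: triage -> history assessment -> concordance.

`run_pipeline` is the file-based route (what the CLI drives): it reads the
panel, VCF + annotations, pedigrees and optional participant table, runs
every stage, writes the classified-variant table, per-participant
assessments, the cohort report and a run manifest (input checksums,
thresholds, ruleset name) sufficient to reproduce the run bit-identically.

`run_pipeline_memory` is the same computation on in-memory objects; the
simulation/recovery harness uses it to avoid serialisation when running
hundreds of replicates. One of the tests pins the two routes to identical
results on a simulated cohort.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .fhrisk import Ruleset, assess_cohort, load_ruleset
from .panel import GenePanel, load_panel
from .pedigree import Pedigree, load_pedigrees
from .report import (
    CohortReport,
    ParticipantAssessment,
    assessments_to_frame,
    cohort_report,
    join_assessments,
    write_report,
)
from .stats import Z_95
from .triage import TriageResult, triage_cohort, write_triage_outputs
from .variants import DEFAULT_MAF_THRESHOLD, VariantRecord, read_variants


@dataclass
class RunConfig:
    panel_path: Path
    vcf_path: Path
    annotation_path: Path
    pedigree_path: Path
    out_dir: Path
    participants_path: Path | None = None
    ruleset_path: Path | None = None
    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    z: float = Z_95
    haldane: bool = False

    def __post_init__(self) -> None:
        for name in ("panel_path", "vcf_path", "annotation_path", "pedigree_path"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise ConfigurationError(f"{name.replace('_path', '')} not found: {p}")
        self.out_dir = Path(self.out_dir)
        if not 0.0 < self.maf_threshold <= 1.0:
            raise ConfigurationError("maf threshold outside (0, 1]")


@dataclass
class PipelineResult:
    triage: TriageResult
    fh_results: dict
    assessments: list[ParticipantAssessment]
    report: CohortReport
    outputs: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline_memory(
    variants: list[VariantRecord],
    pedigrees: list[Pedigree],
    panel: GenePanel,
    participant_ids: list[str],
    participants: pd.DataFrame | None = None,
    ruleset: Ruleset | None = None,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    z: float = Z_95,
    haldane: bool = False,
) -> PipelineResult:
    """The pipeline on in-memory objects; no files touched."""
    triage = triage_cohort(variants, panel, participant_ids, maf_threshold=maf_threshold)
    fh_results = assess_cohort(pedigrees, ruleset)
    assessments = join_assessments(triage.carrier_status, fh_results)
    report = cohort_report(assessments, panel, participants, z=z, haldane=haldane)
    return PipelineResult(triage, fh_results, assessments, report)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based pipeline run with provenance manifest."""
    panel = load_panel(config.panel_path)
    ruleset = load_ruleset(config.ruleset_path)
    variants = read_variants(config.vcf_path, config.annotation_path, panel)
    pedigrees = load_pedigrees(config.pedigree_path)
    participants = None
    participant_ids = sorted({v.participant_id for v in variants})
    if config.participants_path is not None:
        participants = pd.read_csv(config.participants_path, sep="\t")
        participant_ids = participants["participant_id"].tolist()

    result = run_pipeline_memory(
        variants,
        pedigrees,
        panel,
        participant_ids,
        participants,
        ruleset,
        config.maf_threshold,
        config.z,
        config.haldane,
    )

    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = write_triage_outputs(result.triage, out_dir)
    assess_path = out_dir / "assessments.tsv"
    assessments_to_frame(result.assessments).to_csv(assess_path, sep="\t", index=False)
    outputs["assessments"] = assess_path
    outputs.update(write_report(result.report, out_dir))

    inputs = {
        "panel": config.panel_path,
        "vcf": config.vcf_path,
        "annotations": config.annotation_path,
    }
    if config.participants_path is not None:
        inputs["participants"] = config.participants_path
    ped_path = Path(config.pedigree_path)
    ped_files = sorted(ped_path.glob("*.json")) if ped_path.is_dir() else [ped_path]
    manifest = {
        "package_version": __version__,
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "pedigree_files": len(ped_files),
        "pedigree_sha256": hashlib.sha256(
            b"".join(_sha256(p).encode() for p in ped_files)
        ).hexdigest(),
        "ruleset": ruleset.name,
        "maf_threshold": config.maf_threshold,
        "z": config.z,
        "haldane": config.haldane,
        "funnel": result.triage.funnel,
    }
    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    outputs["manifest"] = manifest_path
    result.outputs = outputs
    return result
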