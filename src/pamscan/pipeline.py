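"""End-to-end orchestration: discover -> annotate -> design -> spectrum.

A run is fully determined by its config (plus the input files), so two
runs with the same config produce byte-identical outputs.  Any stage
failure removes partial outputs and re-raises with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

from . import __version__
from .io_formats import (
    load_genome,
    read_gene_model,
    read_somatic_vcf,
    write_report,
)
from .pam_discovery import (
    PAM_REPORT_COLUMNS,
    DiscoveryParams,
    discover,
    pam_record_row,
)
from .sgrna_design import (
    CANDIDATE_REPORT_COLUMNS,
    DesignCriteria,
    apply_criteria,
    candidate_row,
)
from .spectrum_annotation import CONTEXTS_96, mutational_profile
from .io_formats import GeneModel

__all__ = ["RunConfig", "PipelineError", "run_all"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs; mirrors the CLI flags."""

    ref: str
    vcf: str
    tumor: str
    normal: str
    outdir: str
    genes: str | None = None
    purity: float = 1.0
    min_depth: int = 18
    vaf_factor: float = 0.30
    pass_only: bool = True
    sample_id: str = "sample"
    design: DesignCriteria = field(default_factory=DesignCriteria)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        design = d.pop("design", {}) or {}
        if "allow_nag" in design:
            if design.pop("allow_nag"):
                design["allowed_pams"] = ("NGG", "NAG")
        return cls(design=DesignCriteria(**design), **d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Run the whole workflow; returns the summary dict written to disk."""
    for label, path in (("ref", config.ref), ("vcf", config.vcf)):
        if not os.path.exists(path):
            raise PipelineError("validate", FileNotFoundError(f"{label}: {path}"))
    if config.genes and not os.path.exists(config.genes):
        raise PipelineError("validate", FileNotFoundError(f"genes: {config.genes}"))

    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    written: list[str] = []
    log_lines: list[str] = []

    def emit(name: str, writer) -> None:
        path = out(name)
        writer(path)
        written.append(path)
        log_lines.append(f"wrote {name}")

    try:
        stage = "discover"
        genome = load_genome(config.ref)
        result = read_somatic_vcf(
            config.vcf,
            config.tumor,
            config.normal,
            pass_only=config.pass_only,
            genome=genome,
        )
        params = DiscoveryParams(
            purity=config.purity,
            min_depth=config.min_depth,
            vaf_factor=config.vaf_factor,
        )
        records, summary = discover(
            result.variants, genome, params, sample_id=config.sample_id
        )
        log_lines.append(
            f"discover: {len(result.variants)} SNVs read "
            f"({result.n_skipped} records skipped), {summary.n_sbs} eligible, "
            f"{summary.n_pam_variants} PAM-creating"
        )
        emit(
            "pams.tsv",
            lambda p: write_report(
                (pam_record_row(r) for r in records), PAM_REPORT_COLUMNS, p
            ),
        )

        stage = "design"
        gene_model = read_gene_model(config.genes) if config.genes else GeneModel()
        candidates = apply_criteria(records, genome, gene_model, config.design)
        emit(
            "candidates.tsv",
            lambda p: write_report(
                (candidate_row(c) for c in candidates), CANDIDATE_REPORT_COLUMNS, p
            ),
        )

        stage = "spectrum"
        profile = mutational_profile(result.variants, genome)
        emit(
            "profile.tsv",
            lambda p: write_report(
                (
                    {"context": k, "count": int(n)}
                    for k, n in zip(CONTEXTS_96, profile.counts)
                ),
                ["context", "count"],
                p,
            ),
        )

        stage = "summarize"
        n_accepted = sum(1 for c in candidates if c.accepted)
        summary_dict = {
            "version": __version__,
            "sample_id": config.sample_id,
            "purity": config.purity,
            "effective_vaf_cutoff": params.effective_vaf_cutoff,
            "n_vcf_records": result.n_records,
            "n_snvs": len(result.variants),
            "n_skipped_records": result.n_skipped,
            "n_sbs": summary.n_sbs,
            "n_pam_variants": summary.n_pam_variants,
            "n_pam_records": summary.n_pam_records,
            "pct_novel_pam": summary.pct_novel_pam,
            "n_candidates": len(candidates),
            "n_accepted_candidates": n_accepted,
        }
        emit(
            "summary.json",
            lambda p: open(p, "w").write(
                json.dumps(summary_dict, indent=2, sort_keys=True) + "\n"
            ),
        )
        emit("run.log", lambda p: open(p, "w").write("\n".join(log_lines) + "\n"))
        return summary_dict
    except PipelineError:
        raise
    except BaseException as exc:
        for path in written:
            try:
                os.remove(path)
            except OSError:
                pass
        raise PipelineError(stage, exc) from exc
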