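"""Selection filters for sgRNAs targeting somatic PAM sites.

A candidate guide passes when the underlying mutation is clonal enough
(tumor VAF above a near-fixation threshold), its target is non-exonic,
the 12-bp PAM-proximal seed has fewer than a budgeted number of exact
genomic matches next to an allowed PAM, and no one-mismatch full-spacer
sites exist.  Risk observations that do not reject (a pre-existing NAG
at the locus, normal-sample support) are carried as warnings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._seq import revcomp
from .io_formats import GeneModel, GenomeSequence, write_report
from .offtarget_audit import enumerate_offtargets, pam_matches
from .pam_discovery import NovelPamRecord
from .spectrum_annotation import RegionClass, classify_region

__all__ = [
    "DesignCriteria",
    "SgRnaCandidate",
    "count_seed_sites",
    "apply_criteria",
    "CANDIDATE_REPORT_COLUMNS",
    "candidate_row",
]


@dataclass
class DesignCriteria:
    """Thresholds for sgRNA acceptance.

    ``max_seed_sites`` is an exclusive bound on the number of exact
    seed+PAM matches in the genome (a count of 10 is rejected).  Seed
    counting includes the on-target site whenever the scanned genome
    contains it; against the unmutated reference a somatic-PAM guide has
    no on-target PAM, so every counted site is an off-target.
    """

    min_tumor_vaf: float = 0.95
    seed_length: int = 12
    max_seed_sites: int = 10
    allowed_pams: tuple[str, ...] = ("NGG",)
    require_non_exonic: bool = True
    max_one_mismatch_sites: int = 0

    def __post_init__(self):
        if not 0 < self.seed_length <= 20:
            raise ValueError("seed_length must be in 1..20")
        if self.max_seed_sites < 0 or self.max_one_mismatch_sites < 0:
            raise ValueError("site budgets must be non-negative")


@dataclass
class SgRnaCandidate:
    record: NovelPamRecord
    seed: str
    seed_sites: int
    one_mismatch_sites: int
    region: RegionClass
    accepted: bool
    reject_reasons: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def count_seed_sites(
    spacer: str,
    genome: GenomeSequence,
    criteria: DesignCriteria | None = None,
) -> int:
    """Number of genomic loci (both strands) where the PAM-proximal seed
    matches exactly with an allowed PAM immediately 3'."""
    criteria = criteria or DesignCriteria()
    spacer = spacer.upper()
    if not set(spacer) <= set("ACGT"):
        raise ValueError(f"spacer contains non-ACGT characters: {spacer!r}")
    seed = spacer[-criteria.seed_length :]
    k = len(seed)
    n = 0
    for contig in genome.contigs:
        for text in (genome.sequence(contig),):
            for oriented in (text, revcomp(text)):
                start = oriented.find(seed)
                while start != -1:
                    pam = oriented[start + k : start + k + 3]
                    if len(pam) == 3 and any(
                        pam_matches(pam, p) for p in criteria.allowed_pams
                    ):
                        n += 1
                    start = oriented.find(seed, start + 1)
    return n


def _count_one_mismatch_sites(
    spacer: str, genome: GenomeSequence, criteria: DesignCriteria
) -> int:
    hits = enumerate_offtargets(
        spacer, genome, max_mismatches=1, allowed_pams=criteria.allowed_pams
    )
    return sum(1 for h in hits if h.mismatches == 1)


def apply_criteria(
    records: Sequence[NovelPamRecord],
    genome: GenomeSequence,
    gene_model: GeneModel,
    criteria: DesignCriteria | None = None,
) -> list[SgRnaCandidate]:
    """Evaluate every record against the full criterion set.

    All enabled criteria are checked so the reject-reason list is
    complete, not short-circuited.  Records without a full-length spacer
    (truncated contig flank) are rejected outright.
    """
    criteria = criteria or DesignCriteria()
    out: list[SgRnaCandidate] = []
    for rec in records:
        reasons: list[str] = []
        warnings: list[str] = []
        region = classify_region(rec.variant.contig, rec.variant.position, gene_model)

        vaf = rec.variant.tumor_vaf
        if vaf is None or vaf < criteria.min_tumor_vaf:
            reasons.append("low_vaf")
        if criteria.require_non_exonic and region.major == "coding_exon":
            reasons.append("exonic")

        if rec.spacer and "n_in_spacer" not in rec.flags:
            seed = rec.spacer[-criteria.seed_length :]
            seed_sites = count_seed_sites(rec.spacer, genome, criteria)
            if seed_sites >= criteria.max_seed_sites:
                reasons.append("seed_budget")
            one_mm = _count_one_mismatch_sites(rec.spacer, genome, criteria)
            if one_mm > criteria.max_one_mismatch_sites:
                reasons.append("one_mismatch_sites")
        else:
            seed, seed_sites, one_mm = "", 0, 0
            reasons.append("truncated_flank")

        if rec.normal_nag_risk:
            warnings.append("normal_nag_risk")
        if "normal_support" in rec.flags:
            warnings.append("normal_support")
        if any(f.startswith("spacer_contamination") for f in rec.flags):
            warnings.append("spacer_contamination")

        out.append(
            SgRnaCandidate(
                record=rec,
                seed=seed,
                seed_sites=seed_sites,
                one_mismatch_sites=one_mm,
                region=region,
                accepted=not reasons,
                reject_reasons=reasons,
                warnings=warnings,
            )
        )
    return out


CANDIDATE_REPORT_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "strand",
    "pam_class",
    "spacer",
    "pam_after",
    "tumor_vaf",
    "region",
    "seed",
    "seed_sites",
    "one_mismatch_sites",
    "verdict",
    "reject_reasons",
    "warnings",
]


def candidate_row(c: SgRnaCandidate) -> dict[str, object]:
    v = c.record.variant
    return {
        "contig": v.contig,
        "pos": v.position,
        "ref": v.ref,
        "alt": v.alt,
        "strand": c.record.strand,
        "pam_class": c.record.pam_class,
        "spacer": c.record.spacer or None,
        "pam_after": c.record.pam_after,
        "tumor_vaf": v.tumor_vaf,
        "region": str(c.region),
        "seed": c.seed or None,
        "seed_sites": c.seed_sites,
        "one_mismatch_sites": c.one_mismatch_sites,
        "verdict": "accepted" if c.accepted else "rejected",
        "reject_reasons": c.reject_reasons,
        "warnings": c.warnings,
    }
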