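"""Detection of somatic single-base substitutions that create novel NGG PAMs.

A somatic SBS creates a new SpCas9 PAM when the alternate allele is a G
adjacent to an existing reference G (plus strand, 5'-NGG-3'), or a C
adjacent to an existing reference C (the same event on the minus strand,
read 5'-CCN-3' on the plus strand).  Two classes are distinguished by
which G of the GG dinucleotide is novel:

* PAM1 — the novel G is the 5' G of the GG pair;
* PAM2 — the novel G is the 3' G.

A single substitution can create up to two PAM windows per strand
orientation (e.g. G-A-G with A>G yields both classes).  The 20-nt spacer
is taken from the reference immediately 5' of the PAM on the PAM's
strand; the mutated base always sits inside the PAM window, never in the
spacer, which is what makes the guide tumor-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from ._seq import revcomp
from .io_formats import GenomeSequence, SomaticVariant

__all__ = [
    "DiscoveryParams",
    "NovelPamRecord",
    "SampleSummary",
    "vaf_cutoff",
    "find_novel_pams",
    "discover",
    "expected_pam_fraction_uniform",
    "pam_record_row",
    "pam_record_from_row",
    "PAM_REPORT_COLUMNS",
]

SPACER_LEN = 20


@dataclass
class DiscoveryParams:
    """Depth/VAF filters applied before PAM inspection.

    The VAF cutoff scales with tumor purity: ``purity * vaf_factor``
    (30% at full purity by default), filtering out subclonal or
    culture-acquired mutations.  The depth floor (18 reads by default)
    applies to both tumor and normal unless ``tumor_depth_only``.
    """

    purity: float = 1.0
    min_depth: int = 18
    vaf_factor: float = 0.30
    design_vaf: float = 0.95
    tumor_depth_only: bool = False
    normal_vaf_ceiling: float = 0.02

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if not 0 < self.vaf_factor <= 1:
            raise ValueError("vaf_factor must be in (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")

    @property
    def effective_vaf_cutoff(self) -> float:
        return vaf_cutoff(self.purity, self.vaf_factor)


def vaf_cutoff(purity: float, base_factor: float = 0.30) -> float:
    """Purity-scaled VAF cutoff: purity x base factor (e.g. 0.5 -> 0.15)."""
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not 0 < base_factor <= 1:
        raise ValueError(f"base_factor must be in (0, 1], got {base_factor}")
    return purity * base_factor


@dataclass
class NovelPamRecord:
    """One novel PAM window created by a somatic SBS."""

    variant: SomaticVariant
    strand: str  # '+' or '-'
    pam_class: str  # 'PAM1' or 'PAM2'
    pam_start: int  # 0-based half-open window on the plus strand
    pam_end: int
    pam_before: str  # reference 3-mer, read on the record's strand
    pam_after: str  # tumor 3-mer, read on the record's strand
    spacer: str  # 20 nt on the PAM's strand; '' when flank is truncated
    normal_nag_risk: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def locus(self) -> str:
        return f"{self.variant.contig}:{self.variant.position}"


@dataclass
class SampleSummary:
    """Per-sample burden of PAM-creating substitutions.

    ``n_sbs`` counts substitutions passing the depth/VAF filters;
    ``n_pam_variants`` counts those creating at least one novel PAM
    (so the percentage is a per-variant ratio and cannot exceed 100),
    while ``n_pam_records`` counts every PAM window enumerated.
    """

    sample_id: str
    n_sbs: int
    n_pam_variants: int
    n_pam_records: int

    @property
    def pct_novel_pam(self) -> float | None:
        if self.n_sbs == 0:
            return None
        return 100.0 * self.n_pam_variants / self.n_sbs


def _window(genome: GenomeSequence, contig: str, start: int, end: int) -> str | None:
    if start < 0 or end > genome.length(contig):
        return None
    return genome.fetch(contig, start, end)


def _mutate(window: str, offset: int, alt: str) -> str:
    return window[:offset] + alt + window[offset + 1 :]


def find_novel_pams(
    variant: SomaticVariant,
    genome: GenomeSequence,
    other_positions: Iterable[int] | None = None,
) -> list[NovelPamRecord]:
    """Enumerate the 0-2 novel PAM windows a single SBS creates.

    ``other_positions`` is an optional set of 1-based positions of other
    somatic variants in the same sample; any falling inside a reported
    PAM window or spacer sets a contamination flag on that record (the
    spacer itself is always read from the unphased reference).
    """
    contig, p = variant.contig, variant.pos0
    ref_base = genome.fetch(contig, p, p + 1)
    if ref_base != variant.ref:
        raise ValueError(
            f"REF {variant.ref} at {contig}:{variant.position} disagrees "
            f"with genome base {ref_base}"
        )
    others = set(other_positions or ()) - {variant.position}
    records: list[NovelPamRecord] = []

    # (strand, class, window start, plus-strand offset of the required
    #  existing base, spacer interval relative to the window)
    layouts: list[tuple[str, str, int, int]] = []
    if variant.alt == "G":
        # plus strand: window reads N-G-G left to right
        if _window(genome, contig, p + 1, p + 2) == "G":
            layouts.append(("+", "PAM1", p - 1, p + 1))
        if _window(genome, contig, p - 1, p) == "G":
            layouts.append(("+", "PAM2", p - 2, p - 1))
    elif variant.alt == "C":
        # minus strand: plus-strand window reads C-C-N
        if _window(genome, contig, p - 1, p) == "C":
            layouts.append(("-", "PAM1", p - 1, p - 1))
        if _window(genome, contig, p + 1, p + 2) == "C":
            layouts.append(("-", "PAM2", p, p + 1))
    else:
        return []

    for strand, pam_class, start, _existing in layouts:
        end = start + 3
        window_ref = _window(genome, contig, start, end)
        if window_ref is None or "N" in window_ref:
            # PAM window runs off the contig or contains an uncalled base
            continue
        window_alt = _mutate(window_ref, p - start, variant.alt)
        if strand == "+":
            before, after = window_ref, window_alt
            spacer_iv = (start - SPACER_LEN, start)
        else:
            before, after = revcomp(window_ref), revcomp(window_alt)
            spacer_iv = (end, end + SPACER_LEN)
        assert after[1:] == "GG"

        flags: list[str] = []
        spacer_seq = _window(genome, contig, *spacer_iv)
        if spacer_seq is None:
            spacer = ""
            flags.append("truncated_flank")
        else:
            spacer = revcomp(spacer_seq) if strand == "-" else spacer_seq
            if "N" in spacer:
                flags.append("n_in_spacer")
        contaminating = sorted(
            q
            for q in others
            if start < q <= end or spacer_iv[0] < q <= spacer_iv[1]
        )
        if contaminating:
            flags.append("spacer_contamination:" + ";".join(map(str, contaminating)))
        records.append(
            NovelPamRecord(
                variant=variant,
                strand=strand,
                pam_class=pam_class,
                pam_start=start,
                pam_end=end,
                pam_before=before,
                pam_after=after,
                spacer=spacer,
                normal_nag_risk=(before[1] == "A" and before[2] == "G"),
                flags=flags,
            )
        )
    records.sort(key=lambda r: (r.pam_start, r.strand, r.pam_class))
    return records


_STRAND_ORDER = {"+": 0, "-": 1}


def discover(
    variants: Sequence[SomaticVariant],
    genome: GenomeSequence,
    params: DiscoveryParams,
    sample_id: str = "sample",
) -> tuple[list[NovelPamRecord], SampleSummary]:
    """Run the full discovery filter chain over a sample's SBS set.

    Eligibility: tumor depth (and normal depth unless ``tumor_depth_only``)
    at or above ``min_depth``, and tumor VAF at or above the purity-scaled
    cutoff.  Only eligible substitutions are inspected for PAM creation and
    counted in ``n_sbs``.  Output is deterministically ordered by
    (contig, position, strand, class).
    """
    cutoff = params.effective_vaf_cutoff
    eligible: list[SomaticVariant] = []
    for v in variants:
        if v.tumor_depth < params.min_depth:
            continue
        if not params.tumor_depth_only and v.normal_depth < params.min_depth:
            continue
        if v.tumor_vaf is None or v.tumor_vaf < cutoff:
            continue
        eligible.append(v)

    positions_by_contig: dict[str, set[int]] = {}
    for v in eligible:
        positions_by_contig.setdefault(v.contig, set()).add(v.position)

    records: list[NovelPamRecord] = []
    pam_variants = 0
    for v in eligible:
        recs = find_novel_pams(v, genome, positions_by_contig[v.contig])
        if recs:
            pam_variants += 1
        if v.normal_vaf is not None and v.normal_vaf > params.normal_vaf_ceiling:
            for r in recs:
                r.flags.append("normal_support")
        records.extend(recs)
    records.sort(
        key=lambda r: (
            r.variant.contig,
            r.variant.position,
            _STRAND_ORDER[r.strand],
            r.pam_class,
        )
    )
    summary = SampleSummary(
        sample_id=sample_id,
        n_sbs=len(eligible),
        n_pam_variants=pam_variants,
        n_pam_records=len(records),
    )
    return records, summary


def expected_pam_fraction_uniform() -> Fraction:
    """Probability a random SBS creates a novel PAM on an i.i.d. uniform genome.

    With the reference base uniform over ACGT and the alternate uniform over
    the three non-reference bases, P(alt = G) = 3/4 * 1/3 = 1/4, and a novel
    G yields a PAM iff at least one of the two uniform neighbors is G:
    1 - (3/4)^2 = 7/16.  The C case is symmetric and disjoint, so the total
    is 2 * 1/4 * 7/16 = 7/32.
    """
    return Fraction(2) * Fraction(1, 4) * (1 - Fraction(3, 4) ** 2)


# ---------------------------------------------------------------------------
# Report serialization (1-based coordinates on disk)
# ---------------------------------------------------------------------------

PAM_REPORT_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "tumor_depth",
    "tumor_alt",
    "normal_depth",
    "normal_alt",
    "tumor_vaf",
    "normal_vaf",
    "strand",
    "pam_class",
    "pam_start",
    "pam_end",
    "pam_before",
    "pam_after",
    "spacer",
    "normal_nag_risk",
    "flags",
]


def pam_record_row(rec: NovelPamRecord) -> dict[str, object]:
    v = rec.variant
    return {
        "contig": v.contig,
        "pos": v.position,
        "ref": v.ref,
        "alt": v.alt,
        "tumor_depth": v.tumor_depth,
        "tumor_alt": v.tumor_alt,
        "normal_depth": v.normal_depth,
        "normal_alt": v.normal_alt,
        "tumor_vaf": v.tumor_vaf,
        "normal_vaf": v.normal_vaf,
        "strand": rec.strand,
        "pam_class": rec.pam_class,
        "pam_start": rec.pam_start + 1,  # 1-based inclusive on disk
        "pam_end": rec.pam_end,
        "pam_before": rec.pam_before,
        "pam_after": rec.pam_after,
        "spacer": rec.spacer or None,
        "normal_nag_risk": rec.normal_nag_risk,
        "flags": rec.flags,
    }


def pam_record_from_row(row: dict[str, str]) -> NovelPamRecord:
    def opt_float(x: str) -> float | None:
        return None if x == "." else float(x)

    variant = SomaticVariant(
        contig=row["contig"],
        position=int(row["pos"]),
        ref=row["ref"],
        alt=row["alt"],
        tumor_depth=int(row["tumor_depth"]),
        tumor_alt=int(row["tumor_alt"]),
        normal_depth=int(row["normal_depth"]),
        normal_alt=int(row["normal_alt"]),
        tumor_vaf=opt_float(row["tumor_vaf"]),
        normal_vaf=opt_float(row["normal_vaf"]),
    )
    return NovelPamRecord(
        variant=variant,
        strand=row["strand"],
        pam_class=row["pam_class"],
        pam_start=int(row["pam_start"]) - 1,
        pam_end=int(row["pam_end"]),
        pam_before=row["pam_before"],
        pam_after=row["pam_after"],
        spacer="" if row["spacer"] == "." else row["spacer"],
        normal_nag_risk=row["normal_nag_risk"] == "true",
        flags=[] if row["flags"] == "." else row["flags"].split(","),
    )
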