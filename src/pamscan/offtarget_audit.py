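"""Off-target risk assessment for 20-nt Cas9 spacers.

Two complementary audits:

* :func:`enumerate_offtargets` — mismatch-tolerant genome scanning: every
  site on either strand whose 20-mer is within a Hamming budget of the
  spacer and whose 3'-adjacent trinucleotide matches an allowed PAM
  (NGG, optionally the non-canonical NAG).

* :func:`min_mismatch_gapless` / :func:`homology_table` — flank-homology
  auditing of observed indels: the spacer is slid gaplessly across every
  full-length offset of the +/-50 bp window around each indel (both
  strands) and the minimum mismatch count reported.  PAM presence is not
  required here; it is annotated separately.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._seq import N_CODE, encode, revcomp
from .io_formats import GenomeSequence

__all__ = [
    "OfftargetHit",
    "IndelHomologyRecord",
    "enumerate_offtargets",
    "min_mismatch_gapless",
    "homology_table",
    "pam_matches",
]

SPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = SPACER_LEN + PAM_LEN


@dataclass
class OfftargetHit:
    """A genomic site within the mismatch budget of a spacer."""

    contig: str
    start: int  # 0-based start of the 23-bp site (spacer+PAM) on the plus strand
    end: int
    strand: str
    mismatches: int
    mismatch_positions: tuple[int, ...]  # 1 = PAM-distal end of the spacer
    pam: str  # observed PAM 3-mer on the hit's strand


@dataclass
class IndelHomologyRecord:
    """Best gapless spacer placement in the flank window of one indel."""

    contig: str
    start: int  # 1-based inclusive indel interval
    stop: int
    sgrna_name: str
    sgrna_seq: str
    min_mismatches: int
    best_offset: int  # 0-based offset on the scanned strand of the window
    best_strand: str  # '+' forward window, '-' reverse complement
    pam_present: bool  # NGG immediately 3' of the best placement
    window: str


def pam_matches(pam: str, pattern: str) -> bool:
    """Case-sensitive PAM match where N in the pattern is a wildcard."""
    return len(pam) == len(pattern) and all(
        q == "N" or q == b for q, b in zip(pattern, pam)
    )


def _pam_mask(pam_windows: np.ndarray, patterns: Sequence[str]) -> np.ndarray:
    """Boolean mask of rows whose 3-mer matches any pattern (N = wildcard).

    A literal N in the genome matches nothing.
    """
    mask = np.zeros(len(pam_windows), dtype=bool)
    for pattern in patterns:
        m = np.ones(len(pam_windows), dtype=bool)
        for j, q in enumerate(pattern):
            col = pam_windows[:, j]
            if q == "N":
                m &= col != N_CODE
            else:
                m &= col == encode(q)[0]
        mask |= m
    return mask


def _scan_strand(
    seq_codes: np.ndarray, spacer_codes: np.ndarray, max_mm: int, pams: Sequence[str]
) -> list[tuple[int, int, tuple[int, ...], str]]:
    """Hits on one oriented sequence: (site start, mismatches, positions, pam)."""
    L = len(seq_codes)
    if L < SITE_LEN:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(seq_codes, SITE_LEN)
    spacer_part = windows[:, :SPACER_LEN]
    # N in the genome never matches a spacer base
    diff = (spacer_part != spacer_codes) | (spacer_part == N_CODE)
    mm = diff.sum(axis=1)
    ok = (mm <= max_mm) & _pam_mask(windows[:, SPACER_LEN:], pams)
    decode = np.array(list("ACGTN"))
    hits = []
    for i in np.nonzero(ok)[0]:
        positions = tuple(int(j) + 1 for j in np.nonzero(diff[i])[0])
        pam = "".join(decode[windows[i, SPACER_LEN:]])
        hits.append((int(i), int(mm[i]), positions, pam))
    return hits


def enumerate_offtargets(
    spacer: str,
    genome: GenomeSequence,
    max_mismatches: int = 4,
    allowed_pams: Sequence[str] = ("NGG",),
) -> list[OfftargetHit]:
    """Complete mismatch-budgeted scan of both strands of every contig.

    Returns hits sorted by (mismatches, contig, position).  Mismatch
    positions are numbered from the PAM-distal end of the spacer (1-20).
    """
    spacer = spacer.upper()
    if len(spacer) != SPACER_LEN or not set(spacer) <= set("ACGT"):
        raise ValueError(f"spacer must be 20 nt of ACGT, got {spacer!r}")
    spacer_codes = encode(spacer)
    hits: list[OfftargetHit] = []
    for contig in genome.contigs:
        seq = genome.sequence(contig)
        L = len(seq)
        fwd = encode(seq)
        for i, mm, positions, pam in _scan_strand(
            fwd, spacer_codes, max_mismatches, allowed_pams
        ):
            hits.append(
                OfftargetHit(contig, i, i + SITE_LEN, "+", mm, positions, pam)
            )
        rev = encode(revcomp(seq))
        for i, mm, positions, pam in _scan_strand(
            rev, spacer_codes, max_mismatches, allowed_pams
        ):
            # site [i, i+23) on the reverse strand maps to plus coordinates
            hits.append(
                OfftargetHit(
                    contig, L - i - SITE_LEN, L - i, "-", mm, positions, pam
                )
            )
    hits.sort(key=lambda h: (h.mismatches, h.contig, h.start, h.strand))
    return hits


def min_mismatch_gapless(
    sgrna: str, window: str, *, local_trim: bool = False
) -> tuple[int, int, str]:
    """Minimum Hamming distance over all full-length gapless placements.

    The 20-mer is slid across every offset of the window and of its
    reverse complement; ties break to the smallest offset, forward before
    reverse.  Returns (mismatches, offset, strand) where the offset is on
    the scanned strand.

    With ``local_trim=True`` the count is instead taken over the
    maximal-scoring gapless local alignment (match +1 / mismatch -1),
    which trims terminal mismatches and can undercount relative to the
    full-spacer convention; provided for sensitivity analysis only.
    """
    sgrna, window = sgrna.upper(), window.upper()
    if len(window) < len(sgrna):
        raise ValueError("window shorter than the sgRNA")
    if local_trim:
        return _local_trim_scan(sgrna, window)
    q = encode(sgrna)
    best: tuple[int, int, str] | None = None
    for strand, text in (("+", window), ("-", revcomp(window))):
        codes = encode(text)
        views = np.lib.stride_tricks.sliding_window_view(codes, len(q))
        mm = ((views != q) | (views == N_CODE)).sum(axis=1)
        i = int(np.argmin(mm))  # argmin takes the first (smallest offset)
        cand = (int(mm[i]), i, strand)
        if best is None or cand[0] < best[0]:
            best = cand
    assert best is not None
    return best


def _local_trim_scan(sgrna: str, window: str) -> tuple[int, int, str]:
    """Gapless local alignment variant using Biopython's aligner."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-1e6,
        extend_gap_score=-1e6,
    )
    best: tuple[int, int, str] | None = None
    for strand, text in (("+", window), ("-", revcomp(window))):
        aln = aligner.align(text, sgrna)[0]
        (t0, t1), (q0, q1) = aln.aligned[0][0], aln.aligned[1][0]
        mm = sum(1 for a, b in zip(text[t0:t1], sgrna[q0:q1]) if a != b)
        cand = (mm, int(t0), strand)
        if best is None or cand[0] < best[0]:
            best = cand
    assert best is not None
    return best


def _overlaps(
    contig: str, start0: int, end0: int, exclude: Iterable[tuple[str, int, int]]
) -> bool:
    return any(c == contig and s < end0 and start0 < e for c, s, e in exclude)


def homology_table(
    indels: Sequence[tuple[str, int, int]] | str | os.PathLike,
    genome: GenomeSequence,
    sgrnas: Sequence[tuple[str, str]],
    flank: int = 50,
    exclude: Iterable[tuple[str, int, int]] = (),
) -> list[IndelHomologyRecord]:
    """Minimum gapless mismatches of every sgRNA against every indel flank.

    ``indels`` is a VCF path or (contig, start, stop) triples with 1-based
    inclusive coordinates (for a VCF, start = POS and stop = POS +
    len(REF) - 1).  The window runs from start - ``flank`` to stop +
    ``flank``, clipped at contig bounds.  ``exclude`` intervals (0-based
    half-open) drop on-target loci from the table.
    """
    if isinstance(indels, (str, os.PathLike)):
        loci = _read_indel_loci(indels)
    else:
        loci = list(indels)
    exclude = list(exclude)
    records: list[IndelHomologyRecord] = []
    for contig, start, stop in loci:
        if contig not in genome:
            raise KeyError(f"indel contig {contig!r} absent from genome")
        if _overlaps(contig, start - 1, stop, exclude):
            continue
        w_start = max(0, start - 1 - flank)
        w_end = min(genome.length(contig), stop + flank)
        window = genome.fetch(contig, w_start, w_end)
        for name, seq in sgrnas:
            mm, offset, strand = min_mismatch_gapless(seq, window)
            # NGG immediately 3' of the placement, on the placement strand
            text = window if strand == "+" else revcomp(window)
            pam = text[offset + len(seq) : offset + len(seq) + PAM_LEN]
            records.append(
                IndelHomologyRecord(
                    contig=contig,
                    start=start,
                    stop=stop,
                    sgrna_name=name,
                    sgrna_seq=seq,
                    min_mismatches=mm,
                    best_offset=offset,
                    best_strand=strand,
                    pam_present=pam_matches(pam, "NGG"),
                    window=window,
                )
            )
    return records


def _read_indel_loci(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    from cyvcf2 import VCF

    loci = []
    vcf = VCF(str(path))
    for rec in vcf:
        if any(len(rec.REF) != len(alt) for alt in rec.ALT) or len(rec.REF) > 1:
            loci.append((rec.CHROM, rec.POS, rec.POS + len(rec.REF) - 1))
    vcf.close()
    return loci
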