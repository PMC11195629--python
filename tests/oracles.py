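"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: sets of PAM windows,
off-target hits and seed sites are computed by direct string scanning so
the optimized implementations can be checked against them.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def ngg_windows(seq: str) -> set[tuple[str, int]]:
    """All (strand, 0-based window start) where a 3-mer is an NGG PAM.

    Plus strand: positions i with seq[i+1:i+3] == GG (the N slot must not
    be a literal N).  Minus strand: the window reads CCN on the plus
    strand, i.e. seq[i:i+2] == CC and seq[i+2] != N.
    """
    out = set()
    for i in range(len(seq) - 2):
        tri = seq[i : i + 3]
        if "N" in tri:
            continue
        if tri[1:] == "GG":
            out.add(("+", i))
        if tri[:2] == "CC":
            out.add(("-", i))
    return out


def novel_pam_windows(seq: str, pos0: int, alt: str) -> set[tuple[str, int]]:
    """Set difference of NGG windows (mutated minus reference), both
    strands, restricted to windows containing the variant position."""
    mutated = seq[:pos0] + alt + seq[pos0 + 1 :]
    novel = ngg_windows(mutated) - ngg_windows(seq)
    return {(s, i) for s, i in novel if i <= pos0 <= i + 2}


def exhaustive_offtargets(
    spacer: str, sequences: dict[str, str], max_mm: int, pams: tuple[str, ...]
) -> set[tuple[str, int, str, int]]:
    """All (contig, plus-strand site start, strand, mismatches) where the
    20-mer+PAM site fits, by position-by-position comparison."""

    def pam_ok(tri: str) -> bool:
        return any(
            len(tri) == 3
            and all(q == "N" and b != "N" or q == b for q, b in zip(pat, tri))
            for pat in pams
        )

    hits = set()
    for contig, seq in sequences.items():
        L = len(seq)
        for strand, text in (("+", seq), ("-", rc(seq))):
            for i in range(L - 22):
                mm = sum(
                    1
                    for a, b in zip(spacer, text[i : i + 20])
                    if a != b or b == "N"
                )
                if mm <= max_mm and pam_ok(text[i + 20 : i + 23]):
                    start = i if strand == "+" else L - i - 23
                    hits.add((contig, start, strand, mm))
    return hits


def exhaustive_seed_count(
    seed: str, sequences: dict[str, str], pams: tuple[str, ...] = ("NGG",)
) -> int:
    """Count of exact seed matches with an allowed PAM immediately 3'."""

    def pam_ok(tri: str) -> bool:
        return any(
            len(tri) == 3
            and all(q == "N" and b != "N" or q == b for q, b in zip(pat, tri))
            for pat in pams
        )

    k = len(seed)
    n = 0
    for seq in sequences.values():
        for text in (seq, rc(seq)):
            for i in range(len(text) - k - 2):
                if text[i : i + k] == seed and pam_ok(text[i + k : i + k + 3]):
                    n += 1
    return n


def min_hamming_placements(sgrna: str, window: str) -> int:
    """Minimum mismatches over all full-length offsets, both strands."""
    best = len(sgrna)
    for text in (window, rc(window)):
        for i in range(len(text) - len(sgrna) + 1):
            mm = sum(1 for a, b in zip(sgrna, text[i : i + len(sgrna)]) if a != b)
            best = min(best, mm)
    return best
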