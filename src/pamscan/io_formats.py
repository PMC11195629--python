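"""Readers and writers for the external formats the toolkit touches.

All genomic intervals are held internally as 0-based half-open
``[start, end)`` pairs.  VCF positions (1-based) and GFF3 intervals
(1-based closed) are converted on ingestion; report files are written
back in 1-based coordinates to match conventional locus notation
(``chr8:29032916``).
"""

from __future__ import annotations

import collections
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from ._seq import VALID_BASES, revcomp

__all__ = [
    "GenomeSequence",
    "SomaticVariant",
    "VcfReadResult",
    "GeneModel",
    "Transcript",
    "load_genome",
    "read_somatic_vcf",
    "iter_snvs",
    "read_gene_model",
    "read_spacer_list",
    "write_report",
    "read_report",
]


# ---------------------------------------------------------------------------
# Genome access
# ---------------------------------------------------------------------------

class GenomeSequence:
    """Random-access reference genome over uppercase A/C/G/T/N text.

    ``fetch`` uses 0-based half-open intervals and raises on any request
    outside the contig rather than silently truncating.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seq: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains illegal characters: {sorted(bad)}"
                )
            self._seq[name] = seq
        self.lengths: dict[str, int] = {c: len(s) for c, s in self._seq.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSequence":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        # pyfaidx builds the .fai sidecar if absent and rejects duplicate names
        fa = Fasta(str(path), sequence_always_upper=True, duplicate_action="stop")
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    @property
    def contigs(self) -> list[str]:
        return list(self._seq)

    def __contains__(self, contig: str) -> bool:
        return contig in self._seq

    def length(self, contig: str) -> int:
        if contig not in self._seq:
            raise KeyError(f"unknown contig {contig!r}")
        return self.lengths[contig]

    def fetch(self, contig: str, start: int, end: int) -> str:
        n = self.length(contig)
        if not (0 <= start <= end <= n):
            raise ValueError(
                f"interval [{start}, {end}) out of range for contig "
                f"{contig!r} of length {n}"
            )
        return self._seq[contig][start:end]

    def sequence(self, contig: str) -> str:
        """Whole-contig sequence (used by genome-wide scanners)."""
        return self.fetch(contig, 0, self.length(contig))

    def to_fasta(self, path: str | os.PathLike, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seq.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def load_genome(path: str | os.PathLike) -> GenomeSequence:
    """Load an (indexed) FASTA reference into a :class:`GenomeSequence`."""
    return GenomeSequence.from_fasta(path)


# ---------------------------------------------------------------------------
# Somatic variants
# ---------------------------------------------------------------------------

@dataclass
class SomaticVariant:
    """A single somatic base substitution with tumor/normal read support.

    ``position`` is 1-based as in the source VCF.  VAFs are ``None`` when
    the corresponding sample has zero depth.
    """

    contig: str
    position: int
    ref: str
    alt: str
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    tumor_vaf: float | None = None
    normal_vaf: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.ref == self.alt or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a single-base substitution: {self.ref}>{self.alt}")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"non-ACGT allele in {self.ref}>{self.alt}")
        if self.tumor_alt > self.tumor_depth or self.normal_alt > self.normal_depth:
            raise ValueError("alt read count exceeds depth")
        if self.tumor_vaf is None and self.tumor_depth > 0:
            self.tumor_vaf = self.tumor_alt / self.tumor_depth
        if self.normal_vaf is None and self.normal_depth > 0:
            self.normal_vaf = self.normal_alt / self.normal_depth
        if self.normal_depth == 0 and "no_normal_coverage" not in self.flags:
            self.flags.append("no_normal_coverage")
        if self.tumor_depth == 0 and "no_tumor_coverage" not in self.flags:
            self.flags.append("no_tumor_coverage")

    @property
    def pos0(self) -> int:
        return self.position - 1


@dataclass
class VcfReadResult:
    """SNVs extracted from a VCF plus an exact account of what was skipped."""

    variants: list[SomaticVariant]
    n_records: int
    skipped: collections.Counter = field(default_factory=collections.Counter)

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


def _snv_alleles(ref: str, alts: Sequence[str]) -> str | None:
    """Reason a record is not a biallelic SNV, or None if it is one."""
    if len(alts) != 1:
        return "multiallelic"
    alt = alts[0]
    if len(ref) == 1 and len(alt) == 1:
        if ref in "ACGT" and alt in "ACGT":
            return None
        return "symbolic_allele"
    if len(ref) == len(alt):
        return "mnv"
    return "indel"


def read_somatic_vcf(
    path: str | os.PathLike,
    tumor_sample: str,
    normal_sample: str,
    *,
    pass_only: bool = True,
    genome: GenomeSequence | None = None,
    ref_mismatch: str = "error",
) -> VcfReadResult:
    """Extract biallelic SNVs with per-sample depth/allele support.

    Depth is the sum of the FORMAT/AD pair; VAF comes from FORMAT/AF when
    the caller wrote one, else from alt/depth.  Non-SNV and (optionally)
    non-PASS records are counted in ``skipped`` by reason, never silently
    dropped.  With a ``genome``, records whose REF disagrees with the
    reference base are an error (``ref_mismatch="error"``) or skipped.
    """
    from cyvcf2 import VCF

    if ref_mismatch not in ("error", "skip"):
        raise ValueError("ref_mismatch must be 'error' or 'skip'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (tumor_sample, normal_sample):
        if name not in samples:
            raise KeyError(f"sample {name!r} not in VCF (has {samples})")
    it, in_ = samples.index(tumor_sample), samples.index(normal_sample)

    result = VcfReadResult(variants=[], n_records=0)
    for rec in vcf:
        result.n_records += 1
        reason = _snv_alleles(rec.REF, rec.ALT)
        if reason is not None:
            result.skipped[reason] += 1
            continue
        if pass_only and rec.FILTER is not None:  # cyvcf2: None == PASS
            result.skipped["non_pass"] += 1
            continue
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            result.skipped["no_allelic_depth"] += 1
            continue
        ad = np.asarray(ad)
        t_ref, t_alt = int(max(ad[it, 0], 0)), int(max(ad[it, 1], 0))
        n_ref, n_alt = int(max(ad[in_, 0], 0)), int(max(ad[in_, 1], 0))
        try:
            af = rec.format("AF")
        except KeyError:
            af = None
        t_vaf = n_vaf = None
        if af is not None:
            af = np.asarray(af, dtype=float)
            t_vaf = float(af[it].ravel()[0])
            n_vaf = float(af[in_].ravel()[0])
        variant = SomaticVariant(
            contig=rec.CHROM,
            position=rec.POS,
            ref=rec.REF,
            alt=rec.ALT[0],
            tumor_depth=t_ref + t_alt,
            tumor_alt=t_alt,
            normal_depth=n_ref + n_alt,
            normal_alt=n_alt,
            tumor_vaf=t_vaf,
            normal_vaf=n_vaf,
        )
        if genome is not None:
            if variant.contig not in genome:
                if ref_mismatch == "skip":
                    result.skipped["unknown_contig"] += 1
                    continue
                raise ValueError(f"contig {variant.contig!r} absent from genome")
            base = genome.fetch(variant.contig, variant.pos0, variant.pos0 + 1)
            if base != variant.ref:
                if ref_mismatch == "skip":
                    result.skipped["ref_mismatch"] += 1
                    continue
                raise ValueError(
                    f"REF {variant.ref} at {variant.contig}:{variant.position} "
                    f"disagrees with genome base {base}"
                )
        result.variants.append(variant)
    vcf.close()
    return result


def iter_snvs(path: str | os.PathLike) -> Iterator[tuple[str, int, str, str]]:
    """Yield (contig, 1-based position, ref, alt) for each biallelic SNV.

    Sample-free iteration for spectrum computation on arbitrary VCFs.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    for rec in vcf:
        if _snv_alleles(rec.REF, rec.ALT) is None:
            yield rec.CHROM, rec.POS, rec.REF, rec.ALT[0]
    vcf.close()


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

FEATURE_CLASSES = ("coding_exon", "utr", "ncRNA", "intron", "flank1kb")
_SOURCE_CLASSES = ("coding_exon", "utr", "ncRNA")


@dataclass
class Transcript:
    tx_id: str
    contig: str
    strand: str
    # (start0, end0, class) with class in coding_exon/utr/ncRNA
    features: list[tuple[int, int, str]]

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _, _ in self.features), max(e for _, e, _ in self.features)


class GeneModel:
    """Interval sets per contig with derived introns and 1 kb flanks.

    Introns are each transcript's span minus its annotated exonic/UTR/ncRNA
    intervals; flanks are the 1000 bp immediately outside the span on both
    sides, clipped at position 0 and (when contig lengths are known) at the
    contig end.
    """

    FLANK = 1000

    def __init__(
        self,
        transcripts: Iterable[Transcript] = (),
        contig_lengths: Mapping[str, int] | None = None,
    ):
        from intervaltree import IntervalTree

        self.transcripts = list(transcripts)
        self._trees: dict[str, IntervalTree] = {}
        self.intervals: dict[str, list[tuple[int, int, str, str]]] = {}
        lengths = dict(contig_lengths or {})

        for tx in self.transcripts:
            if tx.strand not in "+-":
                raise ValueError(f"unknown strand {tx.strand!r} for {tx.tx_id}")
            if not tx.features:
                continue
            ivs = list(tx.features)
            span_start, span_end = tx.span
            # introns: span minus the union of annotated features
            merged: list[list[int]] = []
            for s, e, _ in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            cursor = span_start
            for s, e in merged:
                if s > cursor:
                    ivs.append((cursor, s, "intron"))
                cursor = max(cursor, e)
            # 1 kb flanks, clipped at contig boundaries
            limit = lengths.get(tx.contig)
            up = (max(0, span_start - self.FLANK), span_start)
            down_end = span_end + self.FLANK
            if limit is not None:
                down_end = min(down_end, limit)
            down = (span_end, down_end)
            for s, e in (up, down):
                if e > s:
                    ivs.append((s, e, "flank1kb"))
            bucket = self.intervals.setdefault(tx.contig, [])
            for s, e, cls in ivs:
                bucket.append((s, e, cls, tx.tx_id))

        for contig, ivs in self.intervals.items():
            ivs.sort()
            tree = IntervalTree()
            for s, e, cls, tx_id in ivs:
                if e > s:
                    tree[s:e] = (cls, tx_id)
            self._trees[contig] = tree

    def classes_at(self, contig: str, pos0: int) -> set[str]:
        """Feature classes of all intervals overlapping a 0-based position."""
        tree = self._trees.get(contig)
        if tree is None:
            return set()
        return {iv.data[0] for iv in tree[pos0]}


def _parse_bed_gene_model(path: str) -> list[Transcript]:
    """BED6 rows are transcript features; the name column is either a bare
    transcript id (class coding_exon) or ``tx_id:class``."""
    groups: dict[str, Transcript] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
            contig, start, end, name, _score, strand = cols[:6]
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            tx_id, _, cls = name.partition(":")
            cls = cls or "coding_exon"
            if cls not in _SOURCE_CLASSES:
                raise ValueError(f"{path}:{lineno}: unknown feature class {cls!r}")
            s, e = int(start), int(end)
            if e < s:
                raise ValueError(f"{path}:{lineno}: end < start")
            tx = groups.setdefault(tx_id, Transcript(tx_id, contig, strand, []))
            if tx.contig != contig or tx.strand != strand:
                raise ValueError(f"{path}:{lineno}: inconsistent transcript {tx_id}")
            tx.features.append((s, e, cls))
    return list(groups.values())


_GFF_CLASS = {
    "CDS": "coding_exon",
    "five_prime_UTR": "utr",
    "three_prime_UTR": "utr",
    "UTR": "utr",
    "ncRNA": "ncRNA",
}


def _parse_gff3_gene_model(path: str) -> list[Transcript]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    groups: dict[str, Transcript] = {}

    def bucket(tx_id: str, feat) -> Transcript:
        strand = feat.strand if feat.strand in "+-" else None
        if strand is None:
            raise ValueError(f"unknown strand for feature {feat.id}")
        tx = groups.setdefault(tx_id, Transcript(tx_id, feat.seqid, strand, []))
        return tx

    has_cds: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype == "CDS":
            has_cds.update(feat.attributes.get("Parent", [feat.id]))
    for feat in db.all_features():
        cls = _GFF_CLASS.get(feat.featuretype)
        parents = feat.attributes.get("Parent", [feat.id])
        if cls is None and feat.featuretype == "exon":
            # bare exons stand in for CDS only when the transcript has none
            if any(p in has_cds for p in parents):
                continue
            cls = "coding_exon"
        if cls is None:
            continue
        for parent in parents:
            tx = bucket(parent, feat)
            tx.features.append((feat.start - 1, feat.end, cls))  # 1-based closed
    return list(groups.values())


def read_gene_model(
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int] | None = None,
) -> GeneModel:
    """Read a BED6 or GFF3 gene model into half-open 0-based intervals."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        transcripts = _parse_gff3_gene_model(path)
    elif path.endswith(".bed"):
        transcripts = _parse_bed_gene_model(path)
    else:
        raise ValueError(f"unrecognized gene-model format: {path}")
    return GeneModel(transcripts, contig_lengths=contig_lengths)


# ---------------------------------------------------------------------------
# Spacer lists
# ---------------------------------------------------------------------------

def read_spacer_list(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read 20-nt spacers, one per line, with an optional tab-separated name.

    Returns (name, sequence) pairs; unnamed spacers get sg1, sg2, ...
    """
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            seq = parts[0].upper()
            name = parts[1] if len(parts) > 1 and parts[1] else f"sg{len(out) + 1}"
            if len(seq) != 20 or not set(seq) <= set("ACGT"):
                raise ValueError(f"{path}:{lineno}: not a 20-nt ACGT spacer: {seq}")
            out.append((name, seq))
    return out


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def _cell(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # repr round-trips exactly
    if isinstance(value, (list, tuple)):
        return ",".join(str(v) for v in value) if value else "."
    return str(value)


def write_report(
    rows: Iterable[Mapping[str, object]],
    columns: Sequence[str],
    path: str | os.PathLike,
) -> None:
    """Write a '#'-headed, tab-delimited report; one row per record."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_cell(row.get(c)) for c in columns) + "\n")


def read_report(path: str | os.PathLike) -> pd.DataFrame:
    """Read a report written by :func:`write_report` as an all-string frame."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '#'-prefixed header")
        columns = header[1:].split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    return pd.DataFrame(rows, columns=columns, dtype=str)
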