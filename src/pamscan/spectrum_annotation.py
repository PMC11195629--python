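"""96-context mutational spectra, genomic region classification, cohort stats.

The trinucleotide spectrum follows the standard pyrimidine-centric
convention: each SBS is keyed by one of the six substitutions C>A, C>G,
C>T, T>A, T>C, T>G together with its 5' and 3' neighbors, with
purine-reference variants mapped through the reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp
from .io_formats import GeneModel, GenomeSequence, SomaticVariant
from .pam_discovery import SampleSummary

__all__ = [
    "CONTEXTS_96",
    "MutationalProfile",
    "RegionClass",
    "trinucleotide_class",
    "mutational_profile",
    "classify_region",
    "region_proportions",
    "cohort_summary",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: canonical ordering: substitution-major, then 5' base, then 3' base
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five, three in product(_BASES, _BASES)
)
_CONTEXT_INDEX = {k: i for i, k in enumerate(CONTEXTS_96)}


def trinucleotide_class(
    contig: str, position: int, ref: str, alt: str, genome: GenomeSequence
) -> str | None:
    """96-context key of an SBS, or None when a neighbor is N or off-contig.

    ``position`` is 1-based.  G>A in a T.G.C context maps to G[C>T]A via
    the reverse complement.
    """
    p = position - 1
    if p - 1 < 0 or p + 2 > genome.length(contig):
        return None
    tri = genome.fetch(contig, p - 1, p + 2)
    if tri[1] != ref:
        raise ValueError(
            f"REF {ref} at {contig}:{position} disagrees with genome base {tri[1]}"
        )
    if "N" in tri:
        return None
    if ref in "GA":  # purine reference: flip to the pyrimidine strand
        tri = revcomp(tri)
        ref, alt = revcomp(ref), revcomp(alt)
    key = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
    return key if key in _CONTEXT_INDEX else None


@dataclass
class MutationalProfile:
    """Counts over the 96 trinucleotide contexts."""

    counts: np.ndarray  # length 96, int
    n_unclassifiable: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros(96)
        return self.counts / self.total

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXTS_96), name="count")


def mutational_profile(
    snvs: Sequence[tuple[str, int, str, str] | SomaticVariant],
    genome: GenomeSequence,
) -> MutationalProfile:
    """Accumulate the 96-context profile of an SBS set.

    Accepts (contig, pos, ref, alt) tuples or :class:`SomaticVariant`s.
    Conservation: total + n_unclassifiable == len(snvs).
    """
    counts = np.zeros(96, dtype=int)
    n_bad = 0
    for snv in snvs:
        if isinstance(snv, SomaticVariant):
            contig, pos, ref, alt = snv.contig, snv.position, snv.ref, snv.alt
        else:
            contig, pos, ref, alt = snv
        key = trinucleotide_class(contig, pos, ref, alt, genome)
        if key is None:
            n_bad += 1
        else:
            counts[_CONTEXT_INDEX[key]] += 1
    return MutationalProfile(counts=counts, n_unclassifiable=n_bad)


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

#: precedence when a locus overlaps several annotations
_PRECEDENCE = ("coding_exon", "utr", "ncRNA", "intron", "flank1kb")
_MAJOR = {
    "coding_exon": "coding_exon",
    "utr": "other",
    "ncRNA": "other",
    "intron": "intron",
    "flank1kb": "other",
}

MAJOR_CLASSES = ("coding_exon", "intron", "intergenic", "other")


@dataclass(frozen=True)
class RegionClass:
    major: str  # coding_exon | intron | intergenic | other
    subclass: str | None = None  # utr | ncRNA | flank1kb when major == other

    def __str__(self) -> str:
        return f"{self.major}({self.subclass})" if self.subclass else self.major


def classify_region(contig: str, position: int, gene_model: GeneModel) -> RegionClass:
    """Classify a 1-based locus; precedence coding_exon > utr > ncRNA >
    intron > flank1kb, falling through to intergenic."""
    classes = gene_model.classes_at(contig, position - 1)
    for cls in _PRECEDENCE:
        if cls in classes:
            major = _MAJOR[cls]
            return RegionClass(major, cls if major == "other" else None)
    return RegionClass("intergenic")


def region_proportions(
    loci: Sequence[tuple[str, int]], gene_model: GeneModel
) -> pd.Series:
    """Percentage of loci per major region class (sums to 100)."""
    counts = {c: 0 for c in MAJOR_CLASSES}
    for contig, pos in loci:
        counts[classify_region(contig, pos, gene_model).major] += 1
    total = max(len(loci), 1)
    return pd.Series({c: 100.0 * n / total for c, n in counts.items()})


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

_METRICS = ("n_sbs", "n_pam_variants", "pct_novel_pam")


def _metric_values(samples: Sequence[SampleSummary], metric: str) -> np.ndarray:
    vals = [getattr(s, metric) for s in samples]
    return np.array([v for v in vals if v is not None], dtype=float)


def cohort_summary(
    cohorts: Mapping[str, Sequence[SampleSummary]],
    metrics: Sequence[str] = _METRICS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median/IQR per cohort and pairwise two-sample KS comparisons.

    Quantiles use linear interpolation, so even-sized cohorts can have
    half-integer medians.  Returns (stats frame, pairwise-test frame).
    """
    if any(len(s) == 0 for s in cohorts.values()):
        raise ValueError("every cohort needs at least one sample")
    rows = []
    for name, samples in cohorts.items():
        for metric in metrics:
            vals = _metric_values(samples, metric)
            q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
            rows.append(
                {
                    "cohort": name,
                    "metric": metric,
                    "n": len(vals),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                }
            )
    stats_df = pd.DataFrame(rows)

    test_rows = []
    names = list(cohorts)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for metric in metrics:
                va = _metric_values(cohorts[a], metric)
                vb = _metric_values(cohorts[b], metric)
                res = stats.ks_2samp(va, vb)
                test_rows.append(
                    {
                        "cohort_a": a,
                        "cohort_b": b,
                        "metric": metric,
                        "ks_statistic": float(res.statistic),
                        "p_value": float(res.pvalue),
                    }
                )
    tests_df = pd.DataFrame(
        test_rows,
        columns=["cohort_a", "cohort_b", "metric", "ks_statistic", "p_value"],
    )
    return stats_df, tests_df
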