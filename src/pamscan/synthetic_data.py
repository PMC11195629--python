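"""Self-contained tumor-normal fixtures with known ground truth.

The simulator emulates the inputs of WGS-based somatic PAM discovery at
desk scale: a random reference genome with a sprinkling of gene models,
and a paired tumor-normal VCF under a diploid, copy-neutral model where
each heterozygous somatic variant's expected tumor VAF is
``purity * CCF / 2`` and read support is binomially sampled at
Poisson-distributed depth.  Normal-sample alt reads arise only from a
flat per-read error rate.  Planted variants come with ground-truth PAM
labels computed by an exhaustive trinucleotide scan of the mutated
sequence, independent of the discovery code.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import GeneModel, GenomeSequence, Transcript, write_report

__all__ = [
    "SimulationConfig",
    "GroundTruthEntry",
    "simulate_genome",
    "simulate_gene_model",
    "simulate_tumor_normal",
    "simulate_to_dir",
    "write_vcf",
    "TRUTH_COLUMNS",
]

_BASES = np.array(list("ACGT"))
_MIN_SEPARATION = 60  # keeps spacers/PAM windows of planted variants disjoint
_EDGE_PAD = 30


@dataclass
class SimulationConfig:
    """All knobs of one simulated tumor-normal experiment.

    Defaults model a clean, fully pure tumor sequenced at 60x with
    clonal heterozygous mutations and a CCF-0.3 subclone, on a uniform
    50 kb genome.
    """

    seed: int = 0
    contig_lengths: dict[str, int] = field(default_factory=lambda: {"sim1": 50_000})
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_clonal: int = 50
    n_subclonal: int = 50
    subclonal_ccf: float = 0.3
    purity: float = 1.0
    mean_depth: int = 60
    n_planted_pam: int = 20
    n_decoy: int = 20
    error_rate: float = 0.001

    def __post_init__(self):
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if min(
            self.n_clonal, self.n_subclonal, self.n_planted_pam, self.n_decoy
        ) < 0:
            raise ValueError("variant counts must be non-negative")
        if any(n <= 0 for n in self.contig_lengths.values()):
            raise ValueError("contig lengths must be positive")


@dataclass
class GroundTruthEntry:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    clonality: str  # planted_pam | decoy | clonal | subclonal
    ccf: float
    expected_vaf: float
    creates_pam: bool
    # (strand, PAM class, 0-based window start) per novel window
    pam_labels: list[tuple[str, str, int]] = field(default_factory=list)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_genome(config: SimulationConfig) -> GenomeSequence:
    """Seeded i.i.d. genome with the configured base composition."""
    rng = _rng(config, 0)
    seqs = {}
    for contig, length in config.contig_lengths.items():
        seqs[contig] = "".join(rng.choice(_BASES, size=length, p=config.composition))
    return GenomeSequence(seqs)


def simulate_gene_model(config: SimulationConfig) -> GeneModel:
    """Deterministic toy transcripts so every region class is reachable.

    Contigs of at least 12 kb get a two-exon coding transcript (with
    UTRs and an intron) and a short ncRNA; smaller contigs stay
    intergenic.
    """
    transcripts = []
    for contig, length in config.contig_lengths.items():
        if length < 12_000:
            continue
        tx = f"{contig}_tx1"
        transcripts.append(
            Transcript(
                tx,
                contig,
                "+",
                [
                    (2000, 2200, "utr"),
                    (2200, 3000, "coding_exon"),
                    (4200, 4800, "coding_exon"),
                    (4800, 5000, "utr"),
                ],
            )
        )
        transcripts.append(
            Transcript(f"{contig}_nc1", contig, "-", [(7000, 7600, "ncRNA")])
        )
    return GeneModel(transcripts, contig_lengths=config.contig_lengths)


def _novel_pam_windows(seq: str, p: int, alt: str) -> list[tuple[str, str, int]]:
    """Ground-truth scan: NGG/CCN windows containing position ``p`` that
    exist in the mutated sequence but not the reference, by direct
    trinucleotide comparison."""
    labels = []
    for start in (p - 2, p - 1, p):
        if start < 0 or start + 3 > len(seq):
            continue
        tri_ref = seq[start : start + 3]
        if "N" in tri_ref:
            continue
        i = p - start
        tri_mut = tri_ref[:i] + alt + tri_ref[i + 1 :]
        if tri_mut[1:] == "GG" and tri_ref[1:] != "GG":
            labels.append(("+", "PAM1" if i == 1 else "PAM2", start))
        if tri_mut[:2] == "CC" and tri_ref[:2] != "CC":
            labels.append(("-", "PAM1" if i == 1 else "PAM2", start))
    return labels


def _place_positions(
    rng: np.random.Generator,
    genome: GenomeSequence,
    used: dict[str, list[int]],
    accept,
    n: int,
    what: str,
    max_tries_per_variant: int = 2000,
) -> list[tuple[str, int, str, str]]:
    """Sample ``n`` variant sites satisfying ``accept`` with pairwise
    separation, searching (not assuming) suitable local context."""
    contigs = genome.contigs
    weights = np.array([genome.length(c) for c in contigs], dtype=float)
    weights /= weights.sum()
    out = []
    for _ in range(n):
        for _try in range(max_tries_per_variant):
            contig = contigs[rng.choice(len(contigs), p=weights)]
            L = genome.length(contig)
            if L < 2 * _EDGE_PAD:
                continue
            p = int(rng.integers(_EDGE_PAD, L - _EDGE_PAD))
            taken = used.setdefault(contig, [])
            if any(abs(p - q) < _MIN_SEPARATION for q in taken):
                continue
            picked = accept(contig, p)
            if picked is None:
                continue
            ref, alt = picked
            taken.append(p)
            out.append((contig, p, ref, alt))
            break
        else:
            raise RuntimeError(
                f"genome too small to place {n} {what} variants without overlap"
            )
    return out


def simulate_tumor_normal(
    config: SimulationConfig, genome: GenomeSequence
) -> tuple[list[dict], list[GroundTruthEntry]]:
    """Plant variants and sample tumor/normal read support.

    Returns VCF-ready row dicts (sorted by locus) and the ground truth.
    Planted PAM creators and decoys are clonal; generic clonal and
    subclonal substitutions mutate uniformly at random and may or may
    not create PAMs (the truth records what the exhaustive scan says).
    """
    rng = _rng(config, 2)
    used: dict[str, list[int]] = {}

    def base(contig: str, p: int) -> str:
        return genome.fetch(contig, p, p + 1)

    def accept_pam(contig: str, p: int):
        ref = base(contig, p)
        if ref == "N":
            return None
        options = []
        if ref != "G":
            if base(contig, p + 1) == "G" or base(contig, p - 1) == "G":
                options.append("G")
        if ref != "C":
            if base(contig, p + 1) == "C" or base(contig, p - 1) == "C":
                options.append("C")
        if not options:
            return None
        return ref, options[int(rng.integers(len(options)))]

    def accept_decoy(contig: str, p: int):
        ref = base(contig, p)
        if ref == "N":
            return None
        left, right = base(contig, p - 1), base(contig, p + 1)
        options = []
        if ref != "G" and left != "G" and right != "G":
            options.append("G")
        if ref != "C" and left != "C" and right != "C":
            options.append("C")
        if not options:
            return None
        return ref, options[int(rng.integers(len(options)))]

    def accept_any(contig: str, p: int):
        ref = base(contig, p)
        if ref == "N":
            return None
        alts = [b for b in "ACGT" if b != ref]
        return ref, alts[int(rng.integers(3))]

    batches = [
        ("planted_pam", 1.0, _place_positions(
            rng, genome, used, accept_pam, config.n_planted_pam, "PAM-creating")),
        ("decoy", 1.0, _place_positions(
            rng, genome, used, accept_decoy, config.n_decoy, "decoy")),
        ("clonal", 1.0, _place_positions(
            rng, genome, used, accept_any, config.n_clonal, "clonal")),
        ("subclonal", config.subclonal_ccf, _place_positions(
            rng, genome, used, accept_any, config.n_subclonal, "subclonal")),
    ]

    rows: list[dict] = []
    truth: list[GroundTruthEntry] = []
    for clonality, ccf, sites in batches:
        for contig, p, ref, alt in sites:
            expected_vaf = config.purity * ccf / 2.0
            t_depth = max(1, int(rng.poisson(config.mean_depth)))
            n_depth = max(1, int(rng.poisson(config.mean_depth)))
            t_alt = int(rng.binomial(t_depth, expected_vaf))
            n_alt = int(rng.binomial(n_depth, config.error_rate))
            labels = _novel_pam_windows(genome.sequence(contig), p, alt)
            truth.append(
                GroundTruthEntry(
                    contig=contig,
                    position=p + 1,
                    ref=ref,
                    alt=alt,
                    clonality=clonality,
                    ccf=ccf,
                    expected_vaf=expected_vaf,
                    creates_pam=bool(labels),
                    pam_labels=labels,
                )
            )
            rows.append(
                {
                    "contig": contig,
                    "position": p + 1,
                    "ref": ref,
                    "alt": alt,
                    "tumor_depth": t_depth,
                    "tumor_alt": t_alt,
                    "normal_depth": n_depth,
                    "normal_alt": n_alt,
                }
            )
    order = sorted(range(len(rows)), key=lambda i: (rows[i]["contig"], rows[i]["position"]))
    return [rows[i] for i in order], [truth[i] for i in order]


def write_vcf(
    rows: Sequence[dict],
    genome: GenomeSequence,
    path: str | os.PathLike,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> None:
    """Write simulated variants as a minimal Mutect2-style VCF (GT:AD:DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pamscan-simulate\n")
        for contig in genome.contigs:
            fh.write(f"##contig=<ID={contig},length={genome.length(contig)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{tumor_sample}\t{normal_sample}\n"
        )
        for r in rows:
            t_ref = r["tumor_depth"] - r["tumor_alt"]
            n_ref = r["normal_depth"] - r["normal_alt"]
            fh.write(
                f"{r['contig']}\t{r['position']}\t.\t{r['ref']}\t{r['alt']}\t.\t"
                f"PASS\t.\tGT:AD:DP\t"
                f"0/1:{t_ref},{r['tumor_alt']}:{r['tumor_depth']}\t"
                f"0/0:{n_ref},{r['normal_alt']}:{r['normal_depth']}\n"
            )


TRUTH_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "clonality",
    "ccf",
    "expected_vaf",
    "creates_pam",
    "pam_labels",
]


def _truth_row(t: GroundTruthEntry) -> dict[str, object]:
    return {
        "contig": t.contig,
        "pos": t.position,
        "ref": t.ref,
        "alt": t.alt,
        "clonality": t.clonality,
        "ccf": t.ccf,
        "expected_vaf": t.expected_vaf,
        "creates_pam": t.creates_pam,
        "pam_labels": [f"{s}|{c}|{w}" for s, c, w in t.pam_labels],
    }


def _gene_model_bed(model: GeneModel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for tx in model.transcripts:
            for s, e, cls in tx.features:
                fh.write(
                    f"{tx.contig}\t{s}\t{e}\t{tx.tx_id}:{cls}\t0\t{tx.strand}\n"
                )


def simulate_to_dir(config: SimulationConfig, outdir: str | os.PathLike) -> dict:
    """Emit ref.fa, genes.bed, somatic.vcf and truth.tsv; byte-reproducible
    for a fixed config."""
    os.makedirs(outdir, exist_ok=True)
    genome = simulate_genome(config)
    model = simulate_gene_model(config)
    rows, truth = simulate_tumor_normal(config, genome)
    paths = {
        "ref": os.path.join(outdir, "ref.fa"),
        "genes": os.path.join(outdir, "genes.bed"),
        "vcf": os.path.join(outdir, "somatic.vcf"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    genome.to_fasta(paths["ref"])
    _gene_model_bed(model, paths["genes"])
    write_vcf(rows, genome, paths["vcf"])
    write_report((_truth_row(t) for t in truth), TRUTH_COLUMNS, paths["truth"])
    return paths
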