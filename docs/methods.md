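# Methods

## Somatic PAM model

SpCas9 requires a 5′-NGG-3′ PAM immediately 3′ of its 20-nt protospacer.
A single-base substitution creates a novel PAM in exactly two ways per
strand orientation:

* the alternate allele is **G** and the reference base immediately 3′
  is G — the novel G is the 5′ G of the GG pair (**PAM1**, window
  `[p−1, p+2)` in 0-based half-open coordinates around the variant
  position `p`);
* the alternate allele is **G** and the base immediately 5′ is G — the
  novel G is the 3′ G (**PAM2**, window `[p−2, p+1)`).

An alternate **C** adjacent to an existing C is the same event on the
minus strand (the plus strand reads C-C-N); windows and classes mirror
accordingly. C>G and G>C substitutions are eligible (any of the three
non-reference bases may be the novel G or C). One SBS can create up to
two windows (e.g. G-A-G with A>G yields PAM2 and PAM1); it can never
create PAMs on both strands at once, since the alternate base is either
G or C. PAM-destroying mutations and GG pairs assembled from two
separate SBSs are out of scope.

Correctness is defined — and property-tested — against an exhaustive
oracle: the set of NGG windows in the singly mutated sequence minus the
set in the reference, on both strands, restricted to windows containing
the variant. On an i.i.d. uniform genome with the alternate allele
uniform over the three non-reference bases, the probability that a
random SBS creates at least one PAM has the closed form
`2 × 1/4 × (1 − (3/4)²) = 7/32`, which the Monte-Carlo tests reproduce.

Flanking bases are always read from the *reference*: phase between
nearby somatic variants is unknown in bulk data, so another variant
falling inside a reported PAM window or spacer sets a
`spacer_contamination` flag rather than editing the sequence.

## Filters and their defaults

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 18 reads | minimum depth, tumor **and** normal (normal requirement flag-removable) |
| `vaf_factor` | 0.30 | base clonality cutoff at 100% purity |
| `purity` | required input | effective cutoff = `purity × vaf_factor` |
| `design_vaf` / `min_tumor_vaf` | 0.95 | near-fixation threshold for guide selection |
| `seed_length` | 12 bp | PAM-proximal seed region |
| `max_seed_sites` | 10 (exclusive) | genomic seed+PAM matches allowed |
| `max_one_mismatch_sites` | 0 | full-spacer 1-mismatch sites tolerated |
| `normal_vaf_ceiling` | 0.02 | above this, records are flagged `normal_support` |

The purity-scaled cutoff exists to remove subclonal or
culture-acquired mutations: a clonal heterozygous variant in a tumor of
purity ρ has expected VAF ρ/2, so a cutoff of 0.3 ρ sits comfortably
below clonal-het support at ≥ 18× depth while excluding CCF ≲ 0.6
subclones in expectation. The depth floor is applied to both samples
because a shallow normal cannot support a confident somatic call; the
published filter names only "18×", so a tumor-only mode is kept behind
`tumor_depth_only`.

Burden summaries count *variants creating ≥ 1 PAM* (so the percentage
of PAM-creating substitutions is bounded by 100%), while the record
list enumerates every window; both counts are reported.

## Region classification and spectra

Gene models (BED6 or GFF3) are reduced to five interval classes —
`coding_exon`, `utr`, `ncRNA`, derived `intron` (transcript span minus
annotated features) and derived `flank1kb` (1000 bp outside each span,
clipped at contig bounds). A locus takes the highest-precedence class
among all overlapping transcripts, precedence
`coding_exon > utr > ncRNA > intron > flank1kb`, falling through to
`intergenic`; UTR, ncRNA and flank fold into the reporting class
`other`. The precedence order is this package's own convention, chosen
so that protein-coding consequence always dominates.

Spectra use the standard pyrimidine-centric 96-context classification
(six substitutions × 16 flanking pairs, purine references mapped through
the reverse complement); the module stops at the raw profile and leaves
signature refitting to dedicated tools. Cohort summaries report median
and IQR with linear (type-7) quantile interpolation — half-integer
medians on even cohorts are intentional — and compare cohorts with the
two-sample Kolmogorov–Smirnov test (`scipy.stats.ks_2samp`).

## Off-target audits

`enumerate_offtargets` is defined by completeness: every site on either
strand whose 20-mer is within the Hamming budget (default ≤ 4) of the
spacer with an allowed PAM (N is a wildcard in patterns; a literal N in
the genome matches nothing and always counts as a mismatch). The
implementation vectorises the comparison over sliding windows with
NumPy; tests assert set equality with a per-position Python scan on
100 kb genomes for every budget 0–4 and both PAM sets.

`min_mismatch_gapless` implements homology scoring as a *fitting*
alignment: the minimum Hamming distance over every full-length gapless
placement of the 20-mer on the window and its reverse complement, ties
broken toward the smallest offset, forward strand first. A
local-alignment variant that trims terminal mismatches (gapless
Smith–Waterman via Biopython's `PairwiseAligner` with prohibitive gap
costs) is available behind `local_trim=True` for sensitivity analysis;
it can only report counts ≤ the fitting count and is not used for
tables, because "mismatches between the guide and the nearest matching
DNA" is a statement about the whole spacer. The indel flank window runs
from `start − 50` to `stop + 50` (1-based inclusive; 101 bp for a 1-bp
locus), clipped at contig ends. PAM presence is *not* required for
homology counts; an NGG immediately 3′ of the best placement is
annotated separately (`pam_present`).

Seed-site counting includes the on-target site whenever the scanned
genome contains it; a somatic-PAM guide screened against the unmutated
reference has no on-target PAM there, so its count is purely
off-target. The exclusive `< 10` budget is interpreted on this
inclusive count. NAG is excluded from seed counting by default — the
canonical NGG is the conservative, reproducible choice — but the
allowed-PAM set is configurable everywhere.

## Synthetic data

The simulator emulates paired tumor–normal WGS calls at desk scale
under a diploid, copy-neutral model: every somatic variant is
heterozygous with expected tumor VAF `purity × CCF / 2`; per-site depth
is Poisson (mean 60 by default, floored at 1 read); tumor alt counts
are Binomial(depth, expected VAF); normal alt counts are
Binomial(depth, 0.001) sequencing error. Four variant classes are
planted with ≥ 60 bp pairwise separation (keeping spacer and PAM
windows disjoint): **planted_pam** (context searched so the chosen alt
G/C sits next to an existing G/C; clonal), **decoy** (alt G/C with no
matching neighbor — provably unable to create a PAM), and generic
**clonal** / **subclonal** (CCF 0.3 by default) substitutions with
uniform random alt. Ground-truth PAM labels are computed by a direct
trinucleotide scan of the mutated sequence that shares no code with the
discovery module, and every simulated dataset must satisfy exact set
equality between the two.

What the simulation does **not** model — and what passing tests
therefore do not demonstrate on real data: copy-number alteration and
LOH (so VAFs near 1, the regime the design filter selects, never occur;
the pipeline demo documents this), mapping artifacts and alignment
error, context-dependent mutation rates (the spectrum of simulated
variants is flat), strand bias, and purity estimation error (purity is
taken as given).

All randomness flows from a single integer seed through independent
`numpy` `default_rng([seed, stream])` streams for genome, gene model
and variants; fixture files are byte-reproducible.

## Problem sizes and numerical choices

Property suites run on seeded random genomes of 0.3–2.5 kb (1000
genomes for the discovery oracle), 100 kb for the off-target oracle and
Monte-Carlo limit (10 000 draws, three-standard-error bound), and
2 × 150 kb with 200 + 200 planted variants for parameter recovery —
sizes at which the brute-force oracles stay exact and the whole suite
runs in seconds. Statistical assertions state their tolerance as
binomial/Gaussian standard-error multiples rather than magic constants.
Output ordering is deterministic everywhere — records sort by (contig,
position, strand, PAM class) — so repeated runs are byte-identical.
Report files carry 1-based coordinates; all internal arithmetic is
0-based half-open, converted once at I/O boundaries.

## Known limitations

* Only SpCas9 NGG (and NAG in audits) is modeled; other nucleases'
  PAMs are out of scope.
* External trained scorers (specificity/efficiency scores) are not
  computed; the seed-count and one-mismatch rules are the built-in
  surrogates, and scorer columns can be carried through reports as
  pass-through data.
* The off-target enumerator is exhaustive rather than index-based; it
  is intended for the fixture-to-chromosome scale, not repeated
  whole-genome screens of large guide libraries.
* Bulge (gapped) off-target sites are not searched.
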