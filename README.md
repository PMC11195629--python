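# pamscan

Somatic PAM discovery and sgRNA design from tumor–normal variant calls.

## The problem

Most somatic mutations in solid tumors are non-coding passengers with no
druggable product, yet every one of them is a perfectly clonal genetic
difference between tumor and normal cells. A subset of single-base
substitutions (SBSs) does something exploitable: it creates a novel
SpCas9 protospacer-adjacent motif (5′-NGG-3′ PAM) that exists only in
the tumor genome. A guide RNA programmed against the 20-nt protospacer
next to such a *somatic PAM* directs Cas9 double-strand breaks to tumor
cells while the patient's normal cells — lacking the PAM — are untouched,
turning functionally inert passenger mutations into cancer-specific
cut sites.

`pamscan` is a toolkit for scientists designing such guides. Given a
reference genome (FASTA), a paired tumor–normal VCF (Mutect2-style, with
per-sample allelic depths) and a tumor-purity estimate, it:

1. **discovers** SBSs that create novel NGG PAMs on either strand
   (`pam_discovery`). An SBS creates a PAM when the alternate allele is
   a G adjacent to an existing reference G (or, on the minus strand, a C
   adjacent to an existing C). Two classes are distinguished: **PAM1**
   (the novel G is the 5′ G of the GG dinucleotide) and **PAM2** (the 3′
   G). Variants are pre-filtered by read depth (≥ 18× in both samples by
   default) and a purity-scaled clonality cutoff
   `VAF ≥ purity × 30%`, so a 50%-pure tumor uses a 15% cutoff;
2. **annotates** loci with genomic region classes
   (exon / intron / intergenic / other) and 96-trinucleotide-context
   mutational spectra (`spectrum_annotation`);
3. **designs and screens sgRNAs** (`sgrna_design`): near-fixation
   tumor VAF (> 95% by default), non-exonic targets, fewer than 10 exact
   matches of the 12-bp PAM-proximal **seed** next to an NGG anywhere in
   the genome, and no one-mismatch full-spacer sites;
4. **audits off-target risk** (`offtarget_audit`): complete
   Cas-OFFinder-style enumeration of genomic sites within a 0–4 mismatch
   budget of a spacer next to NGG (optionally the non-canonical NAG)
   PAMs, and a gapless flank-homology table that slides each guide
   across the ±50 bp windows around observed indels and reports the
   minimum mismatch count over all full-length placements on both
   strands;
5. **simulates** fully self-contained tumor–normal fixtures with known
   ground truth (`synthetic_data`): seeded random genomes, toy gene
   models, and binomially sampled read support under a diploid
   copy-neutral model where the expected tumor VAF is
   `purity × CCF / 2`.

## Worked example

Simulate a 50 kb tumor–normal pair and run the whole pipeline:

```bash
pamscan simulate --seed 7 --outdir fixtures
cat > run.yaml <<EOF
ref: fixtures/ref.fa
vcf: fixtures/somatic.vcf
genes: fixtures/genes.bed
tumor: TUMOR
normal: NORMAL
purity: 1.0
outdir: out
sample_id: sim_tumor
EOF
pamscan run --config run.yaml
```

which prints (and writes to `out/summary.json`):

```json
{
  "effective_vaf_cutoff": 0.3,
  "n_accepted_candidates": 0,
  "n_candidates": 39,
  "n_pam_records": 39,
  "n_pam_variants": 32,
  "n_sbs": 90,
  "pct_novel_pam": 35.55555555555556,
  ...
}
```

Reading: of 140 simulated variants, 90 pass the depth and 30% VAF
filters (the CCF-0.3 subclone is removed); 32 of them create at least
one novel PAM (35.6% — far above the genome-wide random-SBS rate of
7/32 ≈ 21.9% because this fixture deliberately plants PAM creators),
producing 39 PAM windows in `out/pams.tsv`, e.g.

```
#contig pos  ref alt ... strand pam_class pam_before pam_after spacer
sim1    222  A   G   ... +      PAM1      TAG        TGG       TGGAGATTTACCAGTCTTAT
```

No candidate survives the default design screen because a clonal
heterozygous variant in a diploid simulation sits at VAF ≈ 0.5, below
the > 0.95 near-fixation criterion used to pick the most toxic targets
(real tumors reach such VAFs through loss of heterozygosity, which this
simulation does not model). Relaxing that one criterion shows the rest
of the screen at work:

```bash
pamscan design --pams out/pams.tsv --ref fixtures/ref.fa \
    --genes fixtures/genes.bed --min-vaf 0.45 -o candidates.tsv
# 29/39 accepted
```

The audit tools run standalone on any spacer list:

```bash
pamscan offtarget scan --spacer TGGAGATTTACCAGTCTTAT --ref fixtures/ref.fa \
    --max-mm 4 --pam NGG --pam NAG -o hits.tsv
pamscan offtarget homology --indels indels.vcf --ref fixtures/ref.fa \
    --sgrnas guides.txt -o homology.tsv
```

Every command is a thin wrapper over importable functions
(`pamscan.discover`, `pamscan.enumerate_offtargets`,
`pamscan.min_mismatch_gapless`, ...), so the same workflow is available
from Python.

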