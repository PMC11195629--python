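import textwrap

import numpy as np
import pytest

from pamscan.io_formats import GenomeSequence


@pytest.fixture
def write_fasta(tmp_path):
    def _write(sequences: dict[str, str], name: str = "ref.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for contig, seq in sequences.items():
                fh.write(f">{contig}\n{seq}\n")
        return path

    return _write


VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    ##FILTER=<ID=artifact,Description="failed caller filters">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
    """
)


@pytest.fixture
def write_vcf(tmp_path):
    """Write a two-sample (TUMOR, NORMAL) VCF from row tuples:
    (chrom, pos, ref, alt, tumor_ad, normal_ad[, filter])."""

    def _write(rows, name: str = "test.vcf", header: str = VCF_HEADER):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write(header)
            for row in rows:
                chrom, pos, ref, alt, t_ad, n_ad = row[:6]
                filt = row[6] if len(row) > 6 else "PASS"
                fh.write(
                    f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\t"
                    f"GT:AD\t0/1:{t_ad}\t0/0:{n_ad}\n"
                )
        return path

    return _write


def random_genome(rng: np.random.Generator, length: int, contig: str = "chr1"):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeSequence({contig: seq})
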