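from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import novel_pam_windows, rc
from pamscan.io_formats import GenomeSequence, SomaticVariant
from pamscan.pam_discovery import (
    DiscoveryParams,
    discover,
    expected_pam_fraction_uniform,
    find_novel_pams,
    vaf_cutoff,
)


def make_variant(contig, pos, ref, alt, t_vaf=0.5, depth=60):
    return SomaticVariant(
        contig, pos, ref, alt, depth, round(depth * t_vaf), depth, 0
    )


class TestVafCutoff:
    @pytest.mark.parametrize(
        "purity,factor,expected",
        [(1.0, 0.30, 0.30), (0.5, 0.30, 0.15), (1.0, 1.0, 1.0)],
    )
    def test_purity_scaling(self, purity, factor, expected):
        assert vaf_cutoff(purity, factor) == pytest.approx(expected)

    @pytest.mark.parametrize("purity", [0.0, -0.1, 1.5])
    def test_purity_domain(self, purity):
        with pytest.raises(ValueError):
            vaf_cutoff(purity)


SPACER20 = "ACGTACGTACGTACGTACGT"


class TestFindNovelPams:
    def test_plus_strand_pam1(self):
        genome = GenomeSequence({"chrA": SPACER20 + "ATG" + "ACGTACG"})
        (rec,) = find_novel_pams(make_variant("chrA", 22, "T", "G"), genome)
        assert (rec.strand, rec.pam_class) == ("+", "PAM1")
        assert (rec.pam_before, rec.pam_after) == ("ATG", "AGG")
        assert rec.spacer == SPACER20
        assert not rec.normal_nag_risk

    def test_preexisting_nag_is_flagged(self):
        genome = GenomeSequence({"chrA": SPACER20 + "AAG" + "ACGTACG"})
        (rec,) = find_novel_pams(make_variant("chrA", 22, "A", "G"), genome)
        assert rec.pam_before == "AAG"
        assert rec.normal_nag_risk

    def test_one_variant_two_pam_windows(self):
        genome = GenomeSequence({"chrA": SPACER20 + "GAG" + "ACGTACG"})
        recs = find_novel_pams(make_variant("chrA", 22, "A", "G"), genome)
        windows = {(r.pam_class, r.pam_start, r.pam_end) for r in recs}
        assert windows == {("PAM2", 19, 22), ("PAM1", 20, 23)}

    def test_non_g_non_c_alt_never_creates(self):
        genome = GenomeSequence({"chrA": SPACER20 + "GAG" + "ACGTACG"})
        assert find_novel_pams(make_variant("chrA", 22, "A", "T"), genome) == []

    def test_minus_strand_spacer_is_reverse_complement(self):
        seq = "ACGTACGTAC" + "T" + "GTACGTACGTACGTACGTACGTACGTACG"
        genome = GenomeSequence({"chrA": seq})
        (rec,) = find_novel_pams(make_variant("chrA", 11, "T", "C"), genome)
        assert (rec.strand, rec.pam_class) == ("-", "PAM1")
        assert rec.spacer == rc(seq[12:32])
        assert rec.pam_after[1:] == "GG"

    def test_truncated_flank_near_contig_start(self):
        genome = GenomeSequence({"chrA": "ATG" + "ACGTACG" * 4})
        (rec,) = find_novel_pams(make_variant("chrA", 2, "T", "G"), genome)
        assert rec.spacer == ""
        assert "truncated_flank" in rec.flags

    def test_n_in_pam_window_rejected(self):
        genome = GenomeSequence({"chrA": SPACER20 + "NTG" + "ACGTACG"})
        assert find_novel_pams(make_variant("chrA", 22, "T", "G"), genome) == []

    def test_ref_mismatch_raises(self):
        genome = GenomeSequence({"chrA": SPACER20 + "ATG" + "ACGTACG"})
        with pytest.raises(ValueError, match="disagrees"):
            find_novel_pams(make_variant("chrA", 22, "C", "G"), genome)

    def test_contamination_flag_for_nearby_variant(self):
        genome = GenomeSequence({"chrA": SPACER20 + "ATG" + "ACGTACG"})
        (rec,) = find_novel_pams(
            make_variant("chrA", 22, "T", "G"), genome, other_positions=[5, 22]
        )
        assert any(f.startswith("spacer_contamination:5") for f in rec.flags)


@st.composite
def genome_and_variant(draw):
    seq = draw(st.text(alphabet="ACGT", min_size=10, max_size=300))
    pos0 = draw(st.integers(0, len(seq) - 1))
    ref = seq[pos0]
    alt = draw(st.sampled_from([b for b in "ACGT" if b != ref]))
    return seq, pos0, alt


class TestOracleEquivalence:
    @settings(max_examples=300, derandomize=True)
    @given(genome_and_variant())
    def test_matches_exhaustive_set_difference(self, case):
        """Reported PAM windows equal {NGG in mutated} minus {NGG in
        reference}, both strands, restricted to windows over the variant."""
        seq, pos0, alt = case
        genome = GenomeSequence({"c": seq})
        v = make_variant("c", pos0 + 1, seq[pos0], alt)
        got = {(r.strand, r.pam_start) for r in find_novel_pams(v, genome)}
        assert got == novel_pam_windows(seq, pos0, alt)

    @settings(max_examples=50, derandomize=True)
    @given(genome_and_variant())
    def test_spacer_never_contains_the_mutated_base(self, case):
        seq, pos0, alt = case
        genome = GenomeSequence({"c": seq})
        for rec in find_novel_pams(genome=genome, variant=make_variant("c", pos0 + 1, seq[pos0], alt)):
            if not rec.spacer:
                continue
            # the spacer must be reference sequence, untouched by the variant
            if rec.strand == "+":
                iv = (rec.pam_start - 20, rec.pam_start)
                assert rec.spacer == seq[iv[0] : iv[1]]
            else:
                iv = (rec.pam_end, rec.pam_end + 20)
                assert rec.spacer == rc(seq[iv[0] : iv[1]])
            assert not iv[0] <= pos0 < iv[1]


class TestDiscover:
    def _genome_with_pams(self):
        # 5 variant sites, 2 of which create PAMs (plus-strand PAM1)
        chunks, variants = [], []
        layouts = ["ATG", "ATG", "ATT", "ATT", "ATT"]
        for i, ctx in enumerate(layouts):
            chunks.append(SPACER20 + ctx + "ACGTACG")
            variants.append(("chr1", 30 * i + 22, "T", "G"))
        return GenomeSequence({"chr1": "".join(chunks)}), variants

    def test_percentage_is_per_variant(self):
        genome, sites = self._genome_with_pams()
        variants = [make_variant(*s, t_vaf=0.9) for s in sites]
        records, summary = discover(variants, genome, DiscoveryParams())
        assert summary.n_sbs == 5
        assert summary.n_pam_variants == 2
        assert summary.pct_novel_pam == pytest.approx(40.0)

    def test_subclonal_vaf_excluded_before_pam_inspection(self):
        genome, sites = self._genome_with_pams()
        variants = [make_variant(*s, t_vaf=0.25) for s in sites]
        records, summary = discover(variants, genome, DiscoveryParams(purity=1.0))
        assert summary.n_sbs == 0 and records == []

    def test_depth_filter_applies_to_both_samples(self):
        genome, sites = self._genome_with_pams()
        shallow_normal = SomaticVariant("chr1", 22, "T", "G", 60, 55, 10, 0)
        _, summary = discover([shallow_normal], genome, DiscoveryParams())
        assert summary.n_sbs == 0
        _, summary = discover(
            [shallow_normal], genome, DiscoveryParams(tumor_depth_only=True)
        )
        assert summary.n_sbs == 1

    def test_empty_input(self):
        genome, _ = self._genome_with_pams()
        records, summary = discover([], genome, DiscoveryParams())
        assert records == [] and summary.n_sbs == 0
        assert summary.pct_novel_pam is None

    def test_monotone_in_cutoff_and_depth(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        genome = GenomeSequence({"c": seq})
        variants = []
        for pos0 in range(30, 4950, 45):
            ref = seq[pos0]
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
            depth = int(rng.integers(10, 80))
            variants.append(
                SomaticVariant(
                    "c", pos0 + 1, ref, alt, depth,
                    int(rng.binomial(depth, 0.45)), depth, 0,
                )
            )
        prev = None
        for factor in (0.1, 0.3, 0.5, 0.8):
            _, s = discover(variants, genome, DiscoveryParams(vaf_factor=factor))
            if prev is not None:
                assert s.n_pam_variants <= prev
            prev = s.n_pam_variants
        prev = None
        for depth in (5, 18, 40, 70):
            _, s = discover(variants, genome, DiscoveryParams(min_depth=depth))
            if prev is not None:
                assert s.n_pam_variants <= prev
            prev = s.n_pam_variants

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        genome = GenomeSequence({"c": seq})
        genome_rc = GenomeSequence({"c": rc(seq)})
        L = len(seq)
        swap_strand = {"+": "-", "-": "+"}
        for pos0 in range(25, 1975, 31):
            ref = seq[pos0]
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
            fwd = find_novel_pams(make_variant("c", pos0 + 1, ref, alt), genome)
            mirrored = make_variant("c", L - pos0, rc(ref), rc(alt))
            rev = find_novel_pams(mirrored, genome_rc)
            assert len(fwd) == len(rev)
            assert {(swap_strand[r.strand], r.pam_class) for r in fwd} == {
                (r.strand, r.pam_class) for r in rev
            }


class TestUniformFraction:
    def test_closed_form_by_enumeration(self):
        """Enumerate ref x alt x neighbor pairs and count PAM creators."""
        creating = total = 0
        # 5-mers so both PAM window layouts fit around the central base
        for l2, l1, ref, r1, r2 in product("ACGT", repeat=5):
            for alt in "ACGT":
                if alt == ref:
                    continue
                total += 1
                seq = l2 + l1 + ref + r1 + r2
                if novel_pam_windows(seq, 2, alt):
                    creating += 1
        assert Fraction(creating, total) == expected_pam_fraction_uniform()
        assert expected_pam_fraction_uniform() == Fraction(7, 32)

    def test_monte_carlo_converges(self):
        rng = np.random.default_rng(2024)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        genome = GenomeSequence({"c": seq})
        n = 10_000
        hits = 0
        positions = rng.integers(25, len(seq) - 25, size=n)
        for pos0 in positions:
            ref = seq[pos0]
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
            if find_novel_pams(make_variant("c", int(pos0) + 1, ref, alt), genome):
                hits += 1
        p = float(expected_pam_fraction_uniform())
        se = (p * (1 - p) / n) ** 0.5
        assert abs(hits / n - p) < 3 * se

    def test_all_a_genome_has_no_neighbor_g(self):
        genome = GenomeSequence({"c": "A" * 500})
        for pos0 in range(50, 450, 37):
            assert find_novel_pams(make_variant("c", pos0 + 1, "A", "G"), genome) == []
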