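"""Overlap pair counts, z-scores and the overlap -> overhang conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnasurv.alignments import AlignedRead, Locus
from srnasurv.signatures import (
    OverlapSignature,
    argmax_overlap,
    averaged_overhang,
    build_profiles,
    overhang_signature,
    overlap_pair_counts,
    per_locus_signatures,
    signature_matrix,
    zscore,
)
from srnasurv.simulate import simulate_dicer_reads, simulate_pingpong_reads

from conftest import random_genome, sim_to_alignments


def _aln(start, length, strand, copies=1, chrom="chr1"):
    return AlignedRead(
        "r", "A" * length, chrom, start, start + length, strand, copies=copies
    )


def brute_pair_counts(alignments, L1, L2, o_max=30):
    """Enumerate every plus x minus read pair and bin its 5' distance."""
    counts = np.zeros(o_max)
    plus = [a for a in alignments if a.strand == "+" and (L1 == "all" or a.length == L1)]
    minus = [a for a in alignments if a.strand == "-" and (L2 == "all" or a.length == L2)]
    for a in plus:
        for b in minus:
            if a.chrom != b.chrom:
                continue
            o = (b.end - 1) - a.start + 1
            if 1 <= o <= o_max:
                counts[o - 1] += a.copies * b.copies
    return counts


class TestProfiles:
    def test_five_prime_conventions(self):
        prof = build_profiles([_aln(100, 24, "+"), _aln(98, 24, "-"), _aln(50, 20, "+", copies=5)])
        assert prof.stratum("chr1", "+", 24) == {100: 1}
        assert prof.stratum("chr1", "-", 24) == {121: 1}  # end - 1
        assert prof.stratum("chr1", "+", 20) == {50: 5}
        assert prof.stratum("chr1", "+", "all") == {100: 1, 50: 5}

    def test_out_of_range_sizes_excluded(self):
        prof = build_profiles([_aln(0, 17, "+"), _aln(0, 31, "+")])
        assert prof.total() == 0


class TestPairCounts:
    def test_counts_product_example(self):
        """Plus 5' x2 at 100 against minus 5' x3 at 109 -> Z(10) = 6."""
        alns = [_aln(100, 24, "+", copies=2), _aln(109 - 23, 24, "-", copies=3)]
        sig = overlap_pair_counts(build_profiles(alns), 24, 24)
        assert sig.counts[9] == 6
        assert sig.counts.sum() == 6

    def test_single_strand_all_zero(self):
        alns = [_aln(100, 24, "+"), _aln(200, 24, "+")]
        sig = overlap_pair_counts(build_profiles(alns), 24, 24)
        assert (sig.counts == 0).all()

    def test_dicer_duplex_gives_register(self):
        # duplex L=24 at p: minus 5' at p+21, so overlap (p+21) - p + 1 = 22
        p = 500
        alns = [_aln(p, 24, "+"), _aln(p - 2, 24, "-")]
        sig = overlap_pair_counts(build_profiles(alns), 24, 24)
        assert sig.counts[21] == 1 and sig.counts.sum() == 1

    @pytest.mark.parametrize("L1,L2", [(24, 24), (22, 26), ("all", "all")])
    def test_matches_brute_force_enumeration(self, L1, L2):
        rng = np.random.default_rng(17)
        alns = [
            _aln(
                int(rng.integers(0, 500)),
                int(rng.integers(18, 31)),
                "+" if rng.random() < 0.5 else "-",
                copies=int(rng.integers(1, 4)),
            )
            for _ in range(400)
        ]
        sig = overlap_pair_counts(build_profiles(alns), L1, L2)
        np.testing.assert_array_equal(sig.counts, brute_pair_counts(alns, L1, L2))

    def test_window_sum_equals_pairs_in_window(self):
        rng = np.random.default_rng(19)
        alns = [
            _aln(int(rng.integers(0, 100)), 24, "+" if rng.random() < 0.5 else "-")
            for _ in range(200)
        ]
        sig = overlap_pair_counts(build_profiles(alns), 24, 24)
        pairs = sum(
            1
            for a in alns
            if a.strand == "+"
            for b in alns
            if b.strand == "-" and 1 <= (b.end - 1) - a.start + 1 <= 30
        )
        assert sig.counts.sum() == pairs


class TestZScore:
    def test_single_peak_arithmetic(self):
        """Z = 6 at o=10 among 30 zeros: z(10) = 5.8 / sqrt(34.8/30)."""
        counts = np.zeros(30)
        counts[9] = 6
        sig = overlap_pair_counts(build_profiles([]), 24, 24)
        sig.counts = counts
        sig = zscore(sig)
        assert sig.defined
        assert sig.z[9] == pytest.approx(5.385164807134504)

    def test_zero_variance_undefined(self):
        sig = overlap_pair_counts(build_profiles([]), 24, 24)
        sig = zscore(sig)
        assert not sig.defined
        assert np.isnan(sig.z).all()

    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=5, max_size=30).filter(
            lambda c: len(set(c)) > 1
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_standardisation_contract(self, counts):
        sig = overlap_pair_counts(build_profiles([]), 24, 24, o_max=len(counts))
        sig.counts = np.array(counts, dtype=float)
        sig = zscore(sig)
        assert sig.z.mean() == pytest.approx(0.0, abs=1e-9)
        assert sig.z.std() == pytest.approx(1.0, abs=1e-9)


class TestOverhang:
    def test_transposition(self):
        counts = np.zeros(30)
        counts[21] = 10  # o = 22 for L = 24 -> h = 2
        sig = zscore(OverlapSignature(size_pair=(24, 24), overlaps=np.arange(1, 31), counts=counts))
        oh = overhang_signature(sig)
        peak_h = oh.overhangs[np.nanargmax(oh.z)]
        assert peak_h == 2
        assert oh.counts.sum() == sig.counts.sum()

    @pytest.mark.parametrize("L,o,h", [(24, 22, 2), (18, 16, 2), (21, 10, 11)])
    def test_h_equals_L_minus_o(self, L, o, h):
        counts = np.zeros(30)
        counts[o - 1] = 5
        sig = OverlapSignature(size_pair=(L, L), overlaps=np.arange(1, 31), counts=counts)
        oh = overhang_signature(zscore(sig))
        assert oh.overhangs[np.nanargmax(oh.z)] == h

    def test_non_size_matched_rejected(self):
        sig = overlap_pair_counts(build_profiles([]), 22, 26)
        with pytest.raises(ValueError):
            overhang_signature(sig)


class TestSignatureRecovery:
    def test_dicer_register_per_size(self):
        genome = random_genome(51, 30000)
        region = Locus("chr1", 0, 30000, ".", "master", "m")
        size_dist = {L: 1 / 13 for L in range(18, 31)}
        reads = simulate_dicer_reads(genome, region, 1500, size_dist, seed=7)
        matrix = signature_matrix(sim_to_alignments(reads))
        for L in range(18, 31):
            col = matrix[str(L)]
            assert col.idxmax() == L - 2, f"size {L}"

    def test_pingpong_ten_everywhere(self):
        genome = random_genome(52, 30000)
        region = Locus("chr1", 0, 30000, "+", "TE", "t")
        reads = simulate_pingpong_reads(genome, region, 1500, seed=8)
        matrix = signature_matrix(sim_to_alignments(reads))
        assert matrix["all"].idxmax() == 10
        assert matrix["24"].idxmax() == 10

    def test_empty_alignments_all_blank(self):
        matrix = signature_matrix([])
        assert matrix.isna().all().all()

    def test_mixture_monotonicity_of_z10(self):
        """z(10) never decreases as the ping-pong fraction grows."""
        genome0 = random_genome(53, 40000)
        z10 = []
        for frac in [0.0, 0.25, 0.5, 0.75, 1.0]:
            genome = dict(genome0)
            n_pp = int(1000 * frac)
            reads = []
            if 1000 - n_pp:
                reads += simulate_dicer_reads(
                    genome, Locus("chr1", 0, 20000, ".", "master", "m"), 1000 - n_pp, seed=9
                )
            if n_pp:
                reads += simulate_pingpong_reads(
                    genome, Locus("chr1", 20000, 40000, "+", "TE", "t"), n_pp, seed=9
                )
            sig = zscore(
                overlap_pair_counts(build_profiles(sim_to_alignments(reads)), "all", "all")
            )
            z10.append(sig.z[9])
        assert all(b >= a - 1e-9 for a, b in zip(z10, z10[1:])), z10


class TestPerLocus:
    def test_locus_restriction_and_blanks(self):
        genome = random_genome(54, 12000)
        locus_a = Locus("chr1", 0, 6000, ".", "master", "withreads")
        locus_b = Locus("chr1", 6000, 12000, ".", "unknown", "empty")
        reads = simulate_dicer_reads(genome, locus_a, 800, {24: 1.0}, seed=10)
        results = per_locus_signatures(sim_to_alignments(reads), [locus_a, locus_b])
        assert results["withreads"]["matrix"]["24"].idxmax() == 22
        assert results["empty"]["matrix"].isna().all().all()
        counts = results["withreads"]["log2_size_counts"]
        assert counts[24] == pytest.approx(np.log2(1600))
        assert np.isnan(counts[20])


class TestAveragedOverhang:
    def test_dicer_reads_peak_at_two(self):
        genome = random_genome(55, 30000)
        region = Locus("chr1", 0, 30000, ".", "master", "m")
        size_dist = {L: 1 / 9 for L in range(20, 29)}
        reads = simulate_dicer_reads(genome, region, 1200, size_dist, seed=11)
        _, _, h = averaged_overhang(sim_to_alignments(reads))
        assert h == 2

    def test_single_size_equals_its_curve(self):
        genome = random_genome(56, 20000)
        region = Locus("chr1", 0, 20000, ".", "master", "m")
        reads = simulate_dicer_reads(genome, region, 500, {24: 1.0}, seed=12)
        alns = sim_to_alignments(reads)
        hs, curve, h = averaged_overhang(alns, sizes=[24])
        sig = zscore(overlap_pair_counts(build_profiles(alns), 24, 24))
        oh = overhang_signature(sig)
        by_h = dict(zip(oh.overhangs.tolist(), oh.z))
        np.testing.assert_allclose(curve, [by_h[x] for x in hs])
        assert h == 2

    def test_empty_input_raises(self):
        multi = [_aln(0, 24, "+")]
        multi[0].n_hits = 7  # nothing uniquely mapping
        with pytest.raises(ValueError, match="empty input"):
            averaged_overhang(multi)

    def test_argmax_tie_breaks_to_smallest(self):
        counts = np.zeros(30)
        counts[[4, 9]] = 7
        sig = overlap_pair_counts(build_profiles([]), 24, 24)
        sig.counts = counts
        assert argmax_overlap(zscore(sig)) == 5
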