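"""The synthetic genome and read populations carry the structure they claim."""

import numpy as np
import pytest

from srnasurv.alignments import Locus
from srnasurv.sequtils import revcomp
from srnasurv.simulate import (
    CapacityError,
    SimConfig,
    collapse_reads,
    simulate_dataset,
    simulate_degradation_reads,
    simulate_dicer_reads,
    simulate_genome,
    simulate_methyl_calls,
    simulate_pingpong_reads,
)

from conftest import random_genome


def _master_seq(genome, annotation):
    master = next(l for l in annotation if l.feature_class == "master")
    return genome[master.chrom][master.start : master.end]


class TestGenome:
    def test_master_locus_shares_fragment_with_every_family(self):
        cfg = SimConfig(seed=4, te_families=2, master_locus_length=2000)
        genome, annotation, catalog = simulate_genome(cfg)
        master = _master_seq(genome, annotation)
        assert len(catalog) == 2
        for fam_seq in catalog.values():
            windows = (fam_seq[i : i + 25] for i in range(len(fam_seq) - 24))
            assert any(w in master or revcomp(w) in master for w in windows)

    def test_deterministic_under_seed(self):
        a = simulate_genome(SimConfig(seed=7))
        b = simulate_genome(SimConfig(seed=7))
        assert a[0] == b[0]
        assert [(l.start, l.end, l.feature_class, l.strand) for l in a[1]] == [
            (l.start, l.end, l.feature_class, l.strand) for l in b[1]
        ]

    def test_zero_te_families_gives_random_master(self):
        cfg = SimConfig(seed=5, te_families=0, mixture={"dicer": 1.0})
        genome, annotation, catalog = simulate_genome(cfg)
        assert catalog == {}
        assert not [l for l in annotation if l.feature_class == "TE"]
        assert len(_master_seq(genome, annotation)) >= cfg.master_locus_length

    def test_features_do_not_overlap(self):
        _, annotation, _ = simulate_genome(SimConfig(seed=8))
        spans = sorted((l.start, l.end) for l in annotation)
        assert all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            simulate_genome(SimConfig(seed=1, genome_length=5000))

    @pytest.mark.parametrize(
        "field,value",
        [
            ("mixture", {"dicer": 0.5, "pingpong": 0.6}),
            ("size_dist", {24: 0.5}),
            ("guide_5p_bias", 1.5),
            ("methyl_rates", {"CG": -0.1, "CHG": 0, "CHH": 0}),
        ],
    )
    def test_config_validation(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})


class TestDicerReads:
    def test_duplex_geometry(self):
        """A duplex of length L yields mates offset by the 2-nt 3' overhang."""
        genome = random_genome(1, 2000)
        region = Locus("chr1", 0, 2000, ".", "master", "m")
        reads = simulate_dicer_reads(genome, region, 1, {24: 1.0}, seed=2)
        plus, minus = reads
        p = plus.start
        assert (plus.start, plus.end) == (p, p + 24)
        assert (minus.start, minus.end) == (p - 2, p + 22)
        # 5' overlap from the two 5' ends, enumerated brute force
        five_plus, five_minus = plus.start, minus.end - 1
        assert five_minus - five_plus + 1 == 22

    @pytest.mark.parametrize("L,expected_overlap", [(18, 16), (24, 22), (30, 28)])
    def test_overlap_is_length_minus_two(self, L, expected_overlap):
        genome = random_genome(3, 1000)
        region = Locus("chr1", 0, 1000, ".", "master", "m")
        reads = simulate_dicer_reads(genome, region, 5, {L: 1.0}, seed=4)
        for plus, minus in zip(reads[::2], reads[1::2]):
            assert (minus.end - 1) - plus.start + 1 == expected_overlap

    def test_empty(self):
        genome = random_genome(1, 500)
        region = Locus("chr1", 0, 500, ".", "master", "m")
        assert simulate_dicer_reads(genome, region, 0, seed=1) == []

    def test_region_too_small(self):
        genome = random_genome(1, 500)
        with pytest.raises(ValueError):
            simulate_dicer_reads(genome, Locus("chr1", 10, 30, ".", "TE", "t"), 1, {30: 1.0}, seed=1)


class TestPingPongReads:
    def test_responder_five_prime_ten_from_guide(self):
        """Responder 5' sits 9 bp downstream of a plus guide 5': overlap 10."""
        genome = random_genome(6, 3000)
        region = Locus("chr1", 0, 3000, "+", "TE", "t")
        rng = np.random.default_rng(0)
        reads = simulate_pingpong_reads(genome, region, 50, rng=rng)
        for guide, resp in zip(reads[::2], reads[1::2]):
            assert guide.role == "guide" and resp.role == "responder"
            g5 = guide.start if guide.strand == "+" else guide.end - 1
            r5 = resp.start if resp.strand == "+" else resp.end - 1
            # brute 5'-distance: bases between and including the two 5' ends
            assert abs(r5 - g5) + 1 == 10

    def test_forced_bias(self):
        genome = random_genome(7, 3000)
        region = Locus("chr1", 0, 3000, "+", "TE", "t")
        reads = simulate_pingpong_reads(genome, region, 500, None, 1.0, 1.0, seed=3)
        guides = [r for r in reads if r.role == "guide"]
        resp = [r for r in reads if r.role == "responder"]
        assert all(r.sequence[0] == "T" for r in guides)
        assert all(r.sequence[9] == "A" for r in resp)

    def test_bias_recovery_within_binomial_interval(self):
        # large region keeps 5'-site collisions (shared draws) negligible
        genome = random_genome(8, 60000)
        region = Locus("chr1", 0, 60000, "+", "TE", "t")
        n = 1000
        reads = simulate_pingpong_reads(genome, region, n, None, 0.25, 0.25, seed=5)
        frac = np.mean([r.sequence[0] == "T" for r in reads if r.role == "guide"])
        # 99% binomial CI half-width at p=0.25, n=1000
        halfwidth = 2.576 * np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < halfwidth

    def test_reads_consistent_with_edited_genome(self):
        genome = random_genome(9, 4000)
        region = Locus("chr1", 0, 4000, "+", "TE", "t")
        reads = simulate_pingpong_reads(genome, region, 200, seed=6)
        for r in reads:
            s = genome[r.chrom][r.start : r.end]
            assert r.sequence == (s if r.strand == "+" else revcomp(s))


class TestDegradationReads:
    def test_single_strand(self):
        genome = random_genome(10, 3000)
        locus = Locus("chr1", 100, 1600, "+", "mRNA", "m0")
        reads = simulate_degradation_reads(genome, locus, 100, seed=1)
        assert len(reads) == 100
        assert all(r.strand == "+" for r in reads)
        assert all(locus.start <= r.start < r.end <= locus.end for r in reads)

    def test_minus_strand_transcript(self):
        genome = random_genome(10, 3000)
        locus = Locus("chr1", 100, 1600, "-", "mRNA", "m1")
        reads = simulate_degradation_reads(genome, locus, 50, seed=2)
        assert all(r.strand == "-" for r in reads)
        for r in reads:
            assert r.sequence == revcomp(genome["chr1"][r.start : r.end])

    def test_unstranded_locus_rejected(self):
        genome = random_genome(10, 3000)
        with pytest.raises(ValueError):
            simulate_degradation_reads(genome, Locus("chr1", 0, 500, ".", "mRNA", "m"), 1, seed=1)

    def test_deterministic(self):
        genome = random_genome(10, 3000)
        locus = Locus("chr1", 100, 1600, "+", "mRNA", "m0")
        a = simulate_degradation_reads(genome, locus, 20, seed=3)
        b = simulate_degradation_reads(genome, locus, 20, seed=3)
        assert [(r.start, r.end, r.sequence) for r in a] == [
            (r.start, r.end, r.sequence) for r in b
        ]


class TestMethylCalls:
    def test_zero_rates_give_zero_meth(self):
        genome = random_genome(12, 2000)
        calls = simulate_methyl_calls(genome, {"CG": 0, "CHG": 0, "CHH": 0}, 5.0, seed=1)
        assert (calls["n_meth"] == 0).all()

    def test_full_cg_rate_saturates_covered_cg_sites(self):
        genome = random_genome(13, 2000)
        calls = simulate_methyl_calls(genome, {"CG": 1.0, "CHG": 0, "CHH": 0}, 10.0, seed=2)
        cg = calls[(calls["context"] == "CG") & (calls["n_meth"] + calls["n_unmeth"] > 0)]
        assert (cg["n_unmeth"] == 0).all() and len(cg) > 50

    def test_rate_recovery_within_three_se(self):
        genome = random_genome(14, 30000)
        rate = 0.3
        calls = simulate_methyl_calls(genome, {"CG": rate, "CHG": 0, "CHH": 0}, 8.0, seed=3)
        cg = calls[calls["context"] == "CG"]
        cov = (cg["n_meth"] + cg["n_unmeth"]).sum()
        assert (cg["n_meth"] + cg["n_unmeth"] > 0).sum() >= 1000
        est = cg["n_meth"].sum() / cov
        se = np.sqrt(rate * (1 - rate) / cov)
        assert abs(est - rate) < 3 * se


class TestDataset:
    def test_every_read_matches_genome(self, dataset):
        for r in dataset.reads:
            s = dataset.genome[r.chrom][r.start : r.end]
            assert r.sequence == (s if r.strand == "+" else revcomp(s))

    def test_every_read_has_one_mechanism_label(self, dataset):
        assert all(r.mechanism in {"dicer", "pingpong", "degradation"} for r in dataset.reads)

    def test_byte_identical_outputs_under_fixed_seed(self, dataset, tmp_path):
        from srnasurv import io

        other = simulate_dataset(dataset.config)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        io.write_reads_fasta(collapse_reads(dataset.reads), p1)
        io.write_reads_fasta(collapse_reads(other.reads), p2)
        assert p1.read_bytes() == p2.read_bytes()
        io.write_genome_fasta(dataset.genome, p1)
        io.write_genome_fasta(other.genome, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_mixture_allocation(self, dataset):
        from collections import Counter

        mech = Counter(r.mechanism for r in dataset.reads)
        n = len(dataset.reads)
        assert mech["dicer"] / n == pytest.approx(0.7, abs=0.02)
        assert mech.get("pingpong", 0) == 0
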