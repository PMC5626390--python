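import numpy as np
import pytest

import tfsig
from tfsig import GeneModel, GeneModelSet, Peak, PeakSet, ValidationError

from conftest import brute_force_assignment, random_instance


def peakset(*intervals, chrom="chr1"):
    return PeakSet("t", [
        Peak(chrom, s, e, f"p{i}", float(a))
        for i, (s, e, a) in enumerate(intervals)
    ])


@pytest.fixture
def one_gene():
    return GeneModelSet([
        GeneModel("gA", "chr1", "+", 100_000, 110_000),
    ])


class TestAssignment:
    def test_within_window_assigned_with_signed_distance(self, one_gene):
        peaks = peakset((140_000, 140_500, 1))
        a = tfsig.assign_peaks_to_genes(peaks, one_gene)
        (pair,) = a.pairs
        assert pair.relation == "near_tss"
        assert pair.distance == 40_000

    def test_beyond_window_unassigned(self, one_gene):
        peaks = peakset((160_000, 160_400, 1))
        a = tfsig.assign_peaks_to_genes(peaks, one_gene)
        assert a.pairs == []

    def test_body_overlap_takes_priority_over_near_tss(self, one_gene):
        peaks = peakset((105_000, 105_200, 1))
        a = tfsig.assign_peaks_to_genes(peaks, one_gene)
        (pair,) = a.pairs
        assert pair.relation == "in_body"
        assert pair.distance == 5_000

    def test_minus_strand_distance_sign_is_strand_relative(self):
        genes = GeneModelSet([GeneModel("gM", "chr1", "-", 100_000, 110_000)])
        # peak upstream of the minus-strand TSS (genomically to the right)
        a = tfsig.assign_peaks_to_genes(peakset((120_000, 120_100, 1)), genes)
        assert a.pairs[0].distance == -(120_000 - 109_999)

    def test_peaks_on_foreign_chromosomes_counted(self, one_gene):
        peaks = peakset((100, 200, 1), chrom="chrUn")
        a = tfsig.assign_peaks_to_genes(peaks, one_gene)
        assert a.pairs == [] and a.n_unassignable_chrom_peaks == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks, genes = random_instance(rng, n_peaks=120, n_genes=30)
        window = int(rng.choice([10_000, 50_000, 120_000]))
        got = tfsig.assign_peaks_to_genes(peaks, genes, window).pair_set()
        assert got == brute_force_assignment(peaks, genes, window)

    @pytest.mark.parametrize("seed", range(5))
    def test_shrinking_window_never_adds_assignments(self, seed):
        rng = np.random.default_rng(seed + 100)
        peaks, genes = random_instance(rng, n_peaks=80, n_genes=20)
        wide = tfsig.assign_peaks_to_genes(peaks, genes, 80_000).pair_set()
        narrow = tfsig.assign_peaks_to_genes(peaks, genes, 20_000).pair_set()
        assert narrow <= wide


class TestConditionOverlap:
    def test_single_bp_overlap_counts_as_shared(self):
        a = peakset((100, 200, 1))
        b = peakset((150, 250, 1))
        r = tfsig.classify_condition_overlap(a, b)
        assert (r.shared_a, r.unique_a) == (1, 0)

    def test_disjoint_sets_share_nothing(self):
        r = tfsig.classify_condition_overlap(
            peakset((100, 200, 1)), peakset((300, 400, 1))
        )
        assert r.shared_a == 0 and r.frac_shared_a == 0.0

    def test_many_to_one_overlap_is_asymmetric(self):
        a = peakset((100, 200, 1), (210, 300, 1))
        b = peakset((150, 260, 1))
        r = tfsig.classify_condition_overlap(a, b)
        assert (r.shared_a, r.shared_b) == (2, 1)
        assert r.shared_a + r.unique_a == len(a)
        assert r.shared_b + r.unique_b == len(b)

    def test_self_overlap_fraction_is_one(self):
        a = peakset((100, 200, 5), (5_000, 5_500, 2))
        r = tfsig.classify_condition_overlap(a, a)
        assert r.frac_shared_a == 1.0 and r.frac_shared_b == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            tfsig.classify_condition_overlap(peakset(), peakset((1, 2, 1)))


class TestExclusivity:
    def make(self, gene_peaks, genes):
        pairs = [
            tfsig.peaks.AssignedPair(p, g, "near_tss", 0)
            for p, g in gene_peaks
        ]
        peaks = peakset(*[(i * 1000, i * 1000 + 100, 1)
                          for i in range(len(gene_peaks) or 1)])
        return tfsig.peaks.PeakGeneAssignment(
            peaks=peaks, genes=genes, window=50_000, pairs=pairs
        )

    def test_partition_of_union(self):
        genes = GeneModelSet([
            GeneModel(g, "chr1", "+", i * 10_000, i * 10_000 + 100)
            for i, g in enumerate(["g1", "g2", "g3"])
        ])
        a = self.make([("p0", "g1"), ("p1", "g2")], genes)
        b = self.make([("p0", "g2"), ("p1", "g3")], genes)
        r = tfsig.gene_association_exclusivity(a, b)
        assert (r.a_only, r.both, r.b_only) == ({"g1"}, {"g2"}, {"g3"})
        assert sum(r.fractions().values()) == pytest.approx(1.0)

    def test_identical_assignments_have_no_exclusive_genes(self):
        genes = GeneModelSet([GeneModel("g1", "chr1", "+", 0, 100)])
        a = self.make([("p0", "g1")], genes)
        r = tfsig.gene_association_exclusivity(a, a)
        assert r.a_only == set() == r.b_only and r.both == {"g1"}


class TestTssProfile:
    @pytest.fixture
    def assignment(self):
        genes = GeneModelSet([GeneModel("g", "chr1", "+", 1_000_000, 1_010_000)])
        peaks = peakset((1_001_000, 1_001_100, 10), (960_050, 960_150, 30))
        # distances: 1 kb (in body) and ~40 kb upstream
        return tfsig.assign_peaks_to_genes(peaks, genes)

    def test_fractions_and_mean_amplitude(self, assignment):
        prof = tfsig.tss_distance_profile(assignment, [0, 10_000, 50_000])
        assert prof.fractions.tolist() == [0.5, 0.5]
        assert prof.mean_amplitudes.tolist() == [10.0, 30.0]
        assert prof.fractions.sum() == 1.0

    def test_shared_bin_averages_amplitude(self):
        genes = GeneModelSet([GeneModel("g", "chr1", "+", 1_000_000, 1_010_000)])
        peaks = peakset((1_001_000, 1_001_100, 10), (1_002_000, 1_002_100, 30))
        prof = tfsig.tss_distance_profile(
            tfsig.assign_peaks_to_genes(peaks, genes), [0, 10_000]
        )
        assert prof.mean_amplitudes.tolist() == [20.0]

    def test_invariant_to_peak_order(self, assignment):
        reordered = PeakSet("t", list(assignment.peaks)[::-1])
        a2 = tfsig.assign_peaks_to_genes(reordered, assignment.genes)
        p1 = tfsig.tss_distance_profile(assignment, [0, 10_000, 50_000])
        p2 = tfsig.tss_distance_profile(a2, [0, 10_000, 50_000])
        assert p1.fractions.tolist() == p2.fractions.tolist()
        assert p1.mean_amplitudes.tolist() == p2.mean_amplitudes.tolist()

    def test_bad_bin_edges_rejected(self, assignment):
        with pytest.raises(ValidationError):
            tfsig.tss_distance_profile(assignment, [10_000, 0])


class TestAmplitudeQuantile:
    def test_interpolated_threshold_flags_top_quartile(self):
        peaks = peakset((0, 10, 1), (20, 30, 2), (40, 50, 3), (60, 70, 4))
        flags = tfsig.amplitude_quantile_flag(peaks, q=0.75)
        assert flags.threshold == pytest.approx(3.25)  # np.quantile convention
        assert flags.high_peak_ids() == {"p3"}

    def test_all_equal_amplitudes_all_flagged(self):
        peaks = peakset((0, 10, 7), (20, 30, 7), (40, 50, 7))
        flags = tfsig.amplitude_quantile_flag(peaks, q=0.75)
        assert flags.high_peak_ids() == {"p0", "p1", "p2"}

    def test_zero_quantile_flags_everything(self):
        peaks = peakset((0, 10, 1), (20, 30, 9))
        assert len(tfsig.amplitude_quantile_flag(peaks, 0).high_peak_ids()) == 2


class TestCooccupancy:
    def test_identical_sets(self):
        a = peakset((100, 200, 1), (1_000, 1_100, 1))
        r = tfsig.cooccupancy(a, a)
        assert r.fraction == 1.0
        assert all(d == 0 for d in r.midpoint_distances.values())

    def test_disjoint_chromosomes(self):
        a = peakset((100, 200, 1), chrom="chr1")
        b = peakset((100, 200, 1), chrom="chr2")
        r = tfsig.cooccupancy(a, b)
        assert r.fraction == 0.0
        assert np.isnan(list(r.midpoint_distances.values())[0])

    def test_constant_shift_recovered_as_modal_distance(self):
        rng = np.random.default_rng(3)
        starts = np.sort(rng.choice(10_000_000, size=100, replace=False)) * 3
        a = PeakSet("a", [Peak("chr1", int(s), int(s) + 1000, f"a{i}", 1.0)
                          for i, s in enumerate(starts)])
        b = PeakSet("b", [Peak("chr1", int(s) + 200, int(s) + 1200, f"b{i}", 1.0)
                          for i, s in enumerate(starts)])
        r = tfsig.cooccupancy(a, b)
        assert r.fraction == 1.0
        dists = list(r.midpoint_distances.values())
        values, counts = np.unique(dists, return_counts=True)
        assert values[np.argmax(counts)] == 200.0
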