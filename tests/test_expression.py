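import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import tfsig
from tfsig import ValidationError
from tfsig.expression import contrast_name

from conftest import make_table

SAMPLES = ["ctrl:1", "ctrl:2", "stim:1", "stim:2"]
CONDS = ["ctrl", "ctrl", "stim", "stim"]
CONTRAST = ("stim", "ctrl")


class TestCollapseTranscripts:
    def test_highest_mean_transcript_wins_and_ties_break_lexicographically(self):
        import pandas as pd

        idx = pd.MultiIndex.from_tuples(
            [("geneX", "t2"), ("geneX", "t1"), ("geneY", "t2"),
             ("geneY", "t1"), ("geneZ", "t9")],
            names=["gene_id", "transcript_id"],
        )
        rpkm = pd.DataFrame(
            [[5, 5, 5, 5],   # (geneX, t2) mean 5
             [7, 7, 7, 7],   # (geneX, t1) mean 7 -> wins
             [1, 3, 3, 5],   # (geneY, t2) mean 3: exact tie with t1
             [3, 3, 3, 3],   # (geneY, t1) mean 3 -> wins the tie lexicographically
             [1, 2, 3, 4]],  # single-transcript gene passes through
            index=idx, columns=SAMPLES, dtype=float,
        )
        table = tfsig.ExpressionTable(
            rpkm=rpkm, sample_conditions=dict(zip(SAMPLES, CONDS))
        )
        collapsed = tfsig.collapse_transcripts(table)
        assert list(collapsed.rpkm.index) == ["geneX", "geneY", "geneZ"]
        assert collapsed.rpkm.loc["geneX"].tolist() == [7, 7, 7, 7]
        assert collapsed.rpkm.loc["geneY"].tolist() == [3, 3, 3, 3]

    def test_idempotent(self, worked_table):
        once = tfsig.collapse_transcripts(worked_table)
        twice = tfsig.collapse_transcripts(once)
        assert twice.rpkm.equals(once.rpkm)


class TestAddOffset:
    def test_offset_is_pooled_median(self):
        table = make_table({"g": [0, 1, 2, 3, 4]},
                           [f"c:{i}" for i in range(5)], ["c"] * 5)
        out, offset = tfsig.add_offset(table)
        assert offset == 2
        assert out.rpkm.loc["g"].tolist() == [2, 3, 4, 5, 6]

    def test_even_count_median_is_midpoint(self):
        table = make_table({"g": [1, 2, 3, 4]}, SAMPLES, CONDS)
        _, offset = tfsig.add_offset(table)
        assert offset == 2.5

    def test_all_zero_table_unchanged(self):
        table = make_table({"g": [0, 0, 0, 0]}, SAMPLES, CONDS)
        out, offset = tfsig.add_offset(table)
        assert offset == 0
        assert out.rpkm.loc["g"].tolist() == [0, 0, 0, 0]

    def test_double_application_rejected(self, worked_table):
        out, _ = tfsig.add_offset(worked_table)
        with pytest.raises(ValidationError, match="already"):
            tfsig.add_offset(out)

    def test_invariant_under_row_and_column_permutation(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(1, 1, size=(6, 4))
        table = make_table(
            {f"g{i}": values[i] for i in range(6)}, SAMPLES, CONDS
        )
        perm = make_table(
            {f"g{i}": values[i][::-1] for i in reversed(range(6))},
            SAMPLES[::-1], CONDS[::-1],
        )
        assert tfsig.add_offset(table)[1] == tfsig.add_offset(perm)[1]


class TestFilterLowAbundance:
    def test_kept_iff_some_condition_mean_reaches_threshold(self):
        table = make_table(
            {"lo": [0.2, 0.2, 0.8, 0.8],     # means 0.2 / 0.8 -> removed
             "edge": [0.2, 0.2, 1.0, 1.0],   # boundary mean 1.0 -> kept
             "hi": [5, 5, 5, 5]},
            SAMPLES, CONDS,
        )
        out = tfsig.filter_low_abundance(table)
        assert list(out.rpkm.index) == ["edge", "hi"]

    def test_zero_threshold_is_identity_and_idempotent(self, worked_table):
        assert tfsig.filter_low_abundance(worked_table, 0).rpkm.equals(
            worked_table.rpkm
        )
        once = tfsig.filter_low_abundance(worked_table)
        assert tfsig.filter_low_abundance(once).rpkm.equals(once.rpkm)


class TestFoldChanges:
    def test_ratio_of_condition_means(self):
        table = make_table({"g": [4, 4, 9, 9]}, SAMPLES, CONDS)
        assert tfsig.compute_fold_changes(table, CONTRAST)["g"] == 2.25

    def test_identical_means_give_unity(self):
        table = make_table({"g": [3, 5, 5, 3]}, SAMPLES, CONDS)
        assert tfsig.compute_fold_changes(table, CONTRAST)["g"] == 1.0

    def test_offset_damps_low_abundance_artifacts(self):
        # raw ratio would be 100x; with a unit offset it is ~1.1x
        table = make_table({"g": [0.001, 0.001, 0.1, 0.1]}, SAMPLES, CONDS)
        table = table._replace(rpkm=table.rpkm + 1.0, offset=1.0)
        fc = tfsig.compute_fold_changes(table, CONTRAST)["g"]
        assert fc == pytest.approx(1.1 / 1.001)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(0, 2, size=(5, 4))
        table = make_table({f"g{i}": values[i] for i in range(5)},
                           SAMPLES, CONDS)
        ab = tfsig.compute_fold_changes(table, ("stim", "ctrl"))
        ba = tfsig.compute_fold_changes(table, ("ctrl", "stim"))
        assert np.allclose(ab * ba, 1.0)


class TestCallDegs:
    def test_strict_thresholds(self, two_condition_samples):
        samples, conds = two_condition_samples
        table = make_table(
            # post-offset FCs engineered: offset 0 rows below are pre-offset;
            # use offset-free table (offset None) so FC is the raw ratio
            {"exact": [2, 2, 3, 3],      # FC 1.5 exactly -> not a DEG
             "down": [5, 5, 2, 2],       # FC 0.4 -> DEG down (1/0.4 > 1.5)
             "weak_p": [1, 1, 3, 3]},    # FC 3.0, p 0.06 -> not a DEG
            samples, conds,
            pvalues={"stim_vs_ctrl":
                     {"exact": 0.01, "down": 0.01, "weak_p": 0.06}},
        )
        degs = tfsig.call_degs(table, CONTRAST)
        assert degs.deg_ids == {"down"}
        assert degs.table.loc["down", "direction"] == "down"

    def test_builtin_requires_replicates(self):
        table = make_table(
            {"g": [1, 2]}, ["ctrl:1", "stim:1"], ["ctrl", "stim"],
            counts={"g": [10, 20]},
        )
        with pytest.raises(ValidationError, match="replicates"):
            tfsig.call_degs(table, CONTRAST, p_source="builtin")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(1.1, 4.0), st.floats(0.001, 0.2))
    def test_monotonic_in_thresholds(self, seed, fc_thr, p_thr):
        rng = np.random.default_rng(seed)
        n = 30
        values = rng.lognormal(0, 1.5, size=(n, 4))
        pvals = rng.uniform(0, 0.2, size=n)
        table = make_table(
            {f"g{i}": values[i] for i in range(n)}, SAMPLES, CONDS,
            pvalues={"stim_vs_ctrl": {f"g{i}": pvals[i] for i in range(n)}},
        )
        base = tfsig.call_degs(table, CONTRAST, fc_thr, p_thr).deg_ids
        stricter_fc = tfsig.call_degs(table, CONTRAST, fc_thr * 1.5, p_thr).deg_ids
        stricter_p = tfsig.call_degs(table, CONTRAST, fc_thr, p_thr / 2).deg_ids
        assert stricter_fc <= base
        assert stricter_p <= base


def oracle_nb_doubletail(counts_a, counts_b, dispersion):
    """Independent conditional double-tail p via scipy NB pmfs."""
    na, nb = len(counts_a), len(counts_b)
    sa, sb = sum(counts_a), sum(counts_b)
    s = sa + sb
    ra, rb = na / dispersion, nb / dispersion
    p0 = 0.5  # any common success probability cancels in the conditioning
    k = np.arange(s + 1)
    joint = stats.nbinom.pmf(k, ra, p0) * stats.nbinom.pmf(s - k, rb, p0)
    pmf = joint / joint.sum()
    return float(pmf[pmf <= pmf[sa] * (1 + 1e-12)].sum())


class TestNbExactTest:
    def test_identical_groups_give_p_one(self):
        assert tfsig.nb_exact_test([5, 5], [5, 5]) == 1.0

    def test_clearly_different_groups_significant(self):
        assert tfsig.nb_exact_test([100, 110], [10, 12]) < 0.01

    @pytest.mark.parametrize("a,b,disp", [
        ([100, 110], [10, 12], 0.05),
        ([5, 8, 6], [9, 7, 11], 0.1),
        ([0, 1], [4, 3], 0.2),
    ])
    def test_matches_independent_enumeration(self, a, b, disp):
        ours = tfsig.nb_exact_test(a, b, dispersion=disp)
        assert ours == pytest.approx(oracle_nb_doubletail(a, b, disp), rel=1e-9)

    def test_all_zero_counts_give_p_one(self):
        assert tfsig.nb_exact_test([0, 0, 0], [0, 0, 0]) == 1.0

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.poisson(20, size=3)
            b = rng.poisson(20, size=3)
            p = tfsig.nb_exact_test(a, b)
            assert 0 < p <= 1


class TestWorkedExample:
    def test_full_preprocessing_chain(self, worked_table):
        table, offset = tfsig.preprocess(worked_table)
        assert offset == 4.0  # pooled median of the 12 cells
        fc = tfsig.compute_fold_changes(table, CONTRAST)
        assert fc["gA"] == pytest.approx(13 / 6)
        assert fc["gB"] == 1.0
        assert fc["gC"] == pytest.approx(6 / 14)
        degs = tfsig.call_degs(table, CONTRAST)
        assert degs.deg_ids == {"gA", "gC"}
        assert degs.table.loc["gC", "direction"] == "down"
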