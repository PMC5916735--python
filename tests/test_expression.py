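import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stickleseq as ss


def make_matrix(counts_dict, groups, lib=None, index=None):
    counts = pd.DataFrame(counts_dict, index=index or [f"g{i}" for i in range(
        len(next(iter(counts_dict.values()))))])
    lib_s = pd.Series(lib) if lib is not None else None
    return ss.CountMatrix(counts, pd.Series(groups), lib_s)


class TestCpm:
    def test_linear_scaling(self):
        m = make_matrix({"s1": [10], "s2": [10]}, {"s1": "A", "s2": "B"},
                        lib={"s1": 1e6, "s2": 1e6})
        assert ss.cpm(m).iloc[0, 0] == 10.0

    def test_log_mode_with_prior(self):
        m = make_matrix({"s1": [0], "s2": [0]}, {"s1": "A", "s2": "B"},
                        lib={"s1": 1e6, "s2": 1e6})
        expected = math.log2(0.5 / (1e6 + 1) * 1e6)
        assert ss.cpm(m, log=True, prior_count=0.5).iloc[0, 0] == pytest.approx(expected)
        assert expected == pytest.approx(-1.0, abs=2e-6)

    def test_scale_invariance(self):
        m1 = make_matrix({"s1": [5, 7], "s2": [3, 9]}, {"s1": "A", "s2": "B"})
        m2 = make_matrix({"s1": [10, 14], "s2": [6, 18]}, {"s1": "A", "s2": "B"})
        pd.testing.assert_frame_equal(ss.cpm(m1), ss.cpm(m2))


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        m = make_matrix(
            {"s1": [10, 20, 30], "s2": [10, 20, 30], "s3": [10, 20, 30],
             "s4": [10, 20, 30]},
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        )
        f = ss.tmm_factors(m)
        assert np.allclose(f.factors, 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(7)
        base = rng.poisson(100, 500)
        m = make_matrix(
            {"s1": base, "s2": 2 * base, "s3": base, "s4": base},
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        )
        f = ss.tmm_factors(m)
        assert np.allclose(f.factors, 1.0, atol=1e-6)

    def test_inflated_sample_gets_factor_below_one(self):
        # 5% of genes 16-fold inflated in s1: its factor must drop below 1;
        # value frozen from a reference run of this construction
        rng = np.random.default_rng(30)
        n = 2000
        base = rng.poisson(rng.lognormal(5, 1, n)[:, None] * np.ones((n, 4)))
        counts = pd.DataFrame(
            base, index=[f"g{i}" for i in range(n)], columns=["s1", "s2", "s3", "s4"]
        )
        infl = rng.choice(n, size=100, replace=False)
        counts.iloc[infl, 0] *= 16
        m = ss.CountMatrix(
            counts, pd.Series({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
        )
        f = ss.tmm_factors(m)
        assert f.factors["s1"] < 1.0
        assert f.factors["s1"] == pytest.approx(0.64441, rel=0.02)

    def test_geometric_mean_is_one(self, de_run):
        _, _, matrix, _, _ = de_run
        f = ss.tmm_factors(matrix)
        assert np.exp(np.mean(np.log(f.factors))) == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        m = make_matrix(
            {"s1": [0, 0], "s2": [1, 2], "s3": [1, 2], "s4": [3, 4]},
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
            lib={"s1": 1.0, "s2": 3.0, "s3": 3.0, "s4": 7.0},
        )
        with pytest.raises(ss.InputError, match="all-zero"):
            ss.tmm_factors(m)


class TestDispersion:
    def test_constant_genes_give_zero(self):
        m = make_matrix(
            {"s1": [10, 50], "s2": [10, 50], "s3": [10, 50], "s4": [10, 50]},
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        )
        assert ss.estimate_common_dispersion(m) == 0.0

    def test_no_replicates_is_an_error(self):
        m = make_matrix(
            {"s1": [10, 50], "s2": [12, 55]}, {"s1": "A", "s2": "B"}
        )
        with pytest.raises(ss.InputError, match="replicate"):
            ss.estimate_common_dispersion(m)


class TestExactTest:
    def equal_lib(self, a_counts, b_counts):
        n_a, n_b = len(a_counts), len(b_counts)
        cols = {f"a{i}": [c] for i, c in enumerate(a_counts)}
        cols.update({f"b{i}": [c] for i, c in enumerate(b_counts)})
        groups = {f"a{i}": "A" for i in range(n_a)}
        groups.update({f"b{i}": "B" for i in range(n_b)})
        lib = {s: 1e6 for s in cols}
        return make_matrix(cols, groups, lib=lib, index=["g0"])

    def test_balanced_symmetric_counts_give_pvalue_one(self):
        m = self.equal_lib([50, 60], [60, 50])
        out = ss.nb_exact_test(m, 0.1)
        assert out.loc[0, "pvalue"] == pytest.approx(1.0)
        assert out.loc[0, "logFC"] == pytest.approx(0.0)

    def test_poisson_limit_equals_doubled_binomial_tail(self):
        # 0 vs 10 with one sample per group and phi = 0: the conditional
        # split is Binomial(10, 1/2), so P = 2 * (1/2)^10
        m = self.equal_lib([0], [10])
        out = ss.nb_exact_test(m, 0.0)
        assert out.loc[0, "pvalue"] == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_label_swap_negates_logfc_keeps_pvalue(self, de_run):
        _, _, matrix, _, _ = de_run
        sub = ss.CountMatrix(
            matrix.counts.iloc[:200], matrix.group, matrix.library_size
        )
        flipped_group = matrix.group.map({"F": "M", "M": "F"})
        flipped = ss.CountMatrix(sub.counts, flipped_group, matrix.library_size)
        a = ss.nb_exact_test(sub, 0.1)
        b = ss.nb_exact_test(flipped, 0.1)
        np.testing.assert_allclose(a["pvalue"], b["pvalue"], rtol=1e-10)
        np.testing.assert_allclose(a["logFC"], -b["logFC"], atol=1e-10)

    def test_all_zero_gene_flagged_untestable(self):
        m = make_matrix(
            {"s1": [0, 5], "s2": [0, 6], "s3": [0, 7], "s4": [0, 8]},
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
            lib={s: 1e6 for s in ["s1", "s2", "s3", "s4"]},
        )
        out = ss.nb_exact_test(m, 0.1)
        assert out.loc[0, "pvalue"] == 1.0
        assert out.loc[0, "logFC"] == 0.0
        assert not out.loc[0, "testable"]
        assert out.loc[1, "testable"]


class TestBhAdjust:
    def test_single_p_of_one(self):
        assert ss.bh_adjust([1.0])[0] == 1.0

    def test_n_total_smaller_than_list_rejected(self):
        with pytest.raises(ss.InputError):
            ss.bh_adjust([0.1, 0.2], n_total=1)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_step_up_properties(self, pvals):
        adj = ss.bh_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)   # monotone in p-rank

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_monotonization_step_is_idempotent(self, pvals):
        # the step-up minimum (cummin from the largest rank) is a
        # projection: applying it to its own output changes nothing
        x = np.sort(np.asarray(pvals))
        once = np.minimum.accumulate(x[::-1])[::-1]
        twice = np.minimum.accumulate(once[::-1])[::-1]
        np.testing.assert_array_equal(once, twice)


class TestMds:
    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5, 2, (100, 4))
        x[:, 1] = x[:, 0]
        logcpm = pd.DataFrame(x, columns=["a", "b", "c", "d"])
        coords = ss.mds_leading_logfc(logcpm, top_n=100, k=2)
        np.testing.assert_allclose(
            coords.loc["a"], coords.loc["b"], atol=1e-8
        )

    def test_full_rank_coordinates_reproduce_distances(self):
        # with top_n = all genes the leading-logFC distance is Euclidean
        # (scaled), so classical MDS at k = n - 1 is exact
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (50, 5))
        logcpm = pd.DataFrame(x, columns=list("abcde"))
        coords = ss.mds_leading_logfc(logcpm, top_n=50, k=4).to_numpy()
        n = 5
        want = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                want[i, j] = np.sqrt(np.mean((x[:, i] - x[:, j]) ** 2))
        got = np.sqrt(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        )
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_planted_group_effect_separates_in_dim1(self, de_run):
        _, _, matrix, _, _ = de_run
        f = ss.tmm_factors(matrix)
        coords = ss.mds_leading_logfc(ss.cpm(matrix, log=True, norm_factors=f))
        d1 = coords["dim1"]
        groups = matrix.group
        a_vals = d1[groups[groups == "F"].index]
        b_vals = d1[groups[groups == "M"].index]
        assert a_vals.max() < b_vals.min() or b_vals.max() < a_vals.min()

    def test_too_few_samples_rejected(self):
        logcpm = pd.DataFrame(np.ones((10, 2)), columns=["a", "b"])
        with pytest.raises(ss.InputError):
            ss.mds_leading_logfc(logcpm)


class TestDeAnalysis:
    def test_fdr_column_follows_pvalue_ranks(self, de_run):
        _, _, _, _, result = de_run
        t = result.table.sort_values("pvalue")
        assert np.all(np.diff(t["fdr"]) >= -1e-15)
        assert np.all(t["fdr"] >= t["pvalue"] - 1e-15)

    def test_up_down_counts_sum_to_n_de(self, de_run):
        _, _, _, _, result = de_run
        assert result.n_up + result.n_down == result.n_de
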