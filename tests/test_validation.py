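"""Preservation statistics, connectivity change, ranking statistic and GSEA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plaquenet import validation as val
from plaquenet.errors import ParameterError


def _expr(n_samples, genes, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((n_samples, len(genes))),
        index=[f"s{i}" for i in range(n_samples)],
        columns=genes,
    )


def _factor_expr(n_samples, genes, loadings, seed=0):
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n_samples)
    X = rng.standard_normal((n_samples, len(genes)))
    for j, l in enumerate(loadings):
        X[:, j] = l * f + np.sqrt(1 - l**2) * X[:, j]
    return pd.DataFrame(X, index=[f"s{i}" for i in range(n_samples)], columns=genes)


class TestPairwiseCorr:
    def test_linear_relation_is_one(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2 * x + 3})
        C = val.pairwise_corr_matrix(df)
        assert C.loc["x", "y"] == pytest.approx(1.0)
        assert np.allclose(np.diag(C), 1.0)

    def test_hand_computed_pair(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 6.0])
        expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        C = val.pairwise_corr_matrix(pd.DataFrame({"x": x, "y": y}))
        assert C.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_zero_and_min_samples(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        C = val.pairwise_corr_matrix(df)
        assert C.loc["x", "flat"] == 0.0
        with pytest.raises(ParameterError):
            val.pairwise_corr_matrix(df.iloc[:2])


class TestPreservationStats:
    def test_self_preservation_is_perfect(self):
        expr = _factor_expr(50, ["a", "b", "c", "d"], [0.9, 0.7, 0.5, 0.8])
        C = val.pairwise_corr_matrix(expr)
        s = val.preservation_stats(C, C, ["a", "b", "c", "d"], expr)
        assert s["cor_cor"] == pytest.approx(1.0)
        assert s["cor_degree"] == pytest.approx(1.0)
        assert 0 <= s["avg_cor"] <= 1 and 0 <= s["avg_contrib"] <= 1

    def test_avg_cor_forced_value(self):
        genes = ["a", "b", "c"]
        C = pd.DataFrame(0.5, index=genes, columns=genes)
        np.fill_diagonal(C.to_numpy(), 1.0)
        C = pd.DataFrame(np.where(np.eye(3), 1.0, 0.5), index=genes, columns=genes)
        s = val.preservation_stats(C, C, genes)
        assert s["avg_cor"] == pytest.approx(0.5)

    def test_cor_cor_matches_hand_vectorization(self):
        d = _factor_expr(40, list("abcd"), [0.9, 0.6, 0.8, 0.5], seed=1)
        t = _factor_expr(40, list("abcd"), [0.9, 0.6, 0.8, 0.5], seed=2)
        D = val.pairwise_corr_matrix(d)
        T = val.pairwise_corr_matrix(t)
        s = val.preservation_stats(D, T, list("abcd"))
        iu = np.triu_indices(4, 1)
        hand = np.corrcoef(D.to_numpy()[iu], T.to_numpy()[iu])[0, 1]
        assert s["cor_cor"] == pytest.approx(hand, abs=1e-12)

    def test_small_module_errors(self):
        expr = _expr(20, ["a", "b", "c"])
        C = val.pairwise_corr_matrix(expr)
        with pytest.raises(ParameterError):
            val.preservation_stats(C, C, ["a", "b"])


class TestPreservationPermutation:
    def test_planted_module_is_preserved(self):
        genes = [f"m{i}" for i in range(12)] + [f"b{i}" for i in range(150)]
        loads = list(np.linspace(0.5, 0.95, 12)) + [0.0] * 150
        disc = _factor_expr(60, genes, loads, seed=1)
        test = _factor_expr(60, genes, loads, seed=2)
        res = val.preservation_permutation(disc, test, genes[:12], n_perm=199, seed=0)
        assert res.preserved
        assert max(res.p_values.values()) <= 0.01

    def test_random_module_rarely_preserved(self):
        genes = [f"g{i}" for i in range(150)]
        disc = _expr(60, genes, seed=3)
        test = _expr(60, genes, seed=4)
        rng = np.random.default_rng(0)
        false_pos = 0
        for i in range(20):
            mod = list(rng.choice(genes, size=10, replace=False))
            res = val.preservation_permutation(disc, test, mod, n_perm=99, seed=i)
            false_pos += int(res.preserved)
        assert false_pos <= 2

    def test_deterministic_under_seed(self):
        genes = [f"g{i}" for i in range(60)]
        disc = _expr(30, genes, seed=5)
        test = _expr(30, genes, seed=6)
        r1 = val.preservation_permutation(disc, test, genes[:5], n_perm=49, seed=9)
        r2 = val.preservation_permutation(disc, test, genes[:5], n_perm=49, seed=9)
        assert r1.p_values == r2.p_values

    def test_too_few_permutations(self):
        genes = [f"g{i}" for i in range(40)]
        disc = _expr(20, genes)
        test = _expr(20, genes)
        with pytest.raises(ParameterError):
            val.preservation_permutation(disc, test, genes[:5], n_perm=10)


class TestConnectivity:
    def test_duplicated_control_is_null(self):
        mock = _factor_expr(6, list("abcde"), [0.8] * 5, seed=7)
        out = val.connectivity_change({"Mock": mock, "copy": mock.copy()},
                                      list("abcde"), control="Mock")
        assert out.loc["copy", "mean_pairwise_cor"] == pytest.approx(
            out.loc["Mock", "mean_pairwise_cor"]
        )
        assert np.isnan(out.loc["Mock", "p_vs_control"])
        assert out["mean_pairwise_cor"].between(-1, 1).all()

    def test_matches_brute_force_double_loop(self):
        expr = _factor_expr(8, list("abcde"), [0.9, 0.6, 0.8, 0.7, 0.5], seed=8)
        out = val.connectivity_change({"Mock": expr}, list("abcde"), control="Mock")
        vals = []
        cols = list("abcde")
        for i in range(5):
            for j in range(i + 1, 5):
                vals.append(np.corrcoef(expr[cols[i]], expr[cols[j]])[0, 1])
        assert out.loc["Mock", "mean_pairwise_cor"] == pytest.approx(
            np.mean(vals), abs=1e-12
        )

    def test_collapse_detected_with_power(self):
        detections = 0
        runs = 100
        for i in range(runs):
            mock = _factor_expr(4, [f"g{j}" for j in range(20)], [0.9] * 20, seed=i)
            pert = _expr(4, [f"g{j}" for j in range(20)], seed=1000 + i)
            out = val.connectivity_change({"Mock": mock, "kd": pert},
                                          [f"g{j}" for j in range(20)],
                                          control="Mock")
            if (out.loc["kd", "p_vs_control"] < 0.05
                    and out.loc["kd", "mean_pairwise_cor"]
                    < out.loc["Mock", "mean_pairwise_cor"]):
                detections += 1
        assert detections / runs >= 0.90

    def test_small_module_errors(self):
        with pytest.raises(ParameterError):
            val.connectivity_change({"Mock": _expr(5, ["a", "b"])}, ["a", "b"],
                                    control="Mock")


class TestDeRankStat:
    def _counts(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        X = rng.poisson(100, size=(8, 30))
        return pd.DataFrame(X, index=[f"s{i}" for i in range(8)], columns=genes)

    def test_identical_groups_zero(self):
        counts = self._counts()
        counts.iloc[4:] = counts.iloc[:4].to_numpy()
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.index)
        stat = val.de_rank_stat(counts, groups, "a", "b")
        assert np.allclose(stat, 0.0)

    def test_antisymmetric_under_swap(self):
        counts = self._counts(1)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.index)
        s1 = val.de_rank_stat(counts, groups, "a", "b")
        s2 = val.de_rank_stat(counts, groups, "b", "a")
        assert np.allclose(s1, -s2)

    def test_upregulated_gene_ranks_high(self):
        counts = self._counts(2)
        counts.iloc[:4, 0] *= 10
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.index)
        stat = val.de_rank_stat(counts, groups, "a", "b")
        assert stat.idxmax() == "g0"

    def test_zero_library_errors(self):
        counts = self._counts()
        counts.iloc[0] = 0
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.index)
        with pytest.raises(ParameterError, match="s0"):
            val.de_rank_stat(counts, groups, "a", "b")


class TestGsea:
    def _ranked(self):
        return pd.Series([3.0, 2.0, 1.0, -1.0, -2.0],
                         index=["a", "b", "c", "d", "e"])

    def test_top_set_hits_plus_one(self):
        res = val.gsea(self._ranked(), ["a", "b"], n_perm=99, seed=0)
        assert res.es == pytest.approx(1.0)
        assert res.nes > 0

    def test_bottom_set_hits_minus_one(self):
        res = val.gsea(self._ranked(), ["d", "e"], n_perm=99, seed=0)
        assert res.es == pytest.approx(-1.0)
        assert res.nes < 0

    def test_es_invariant_to_monotone_rank_rescaling(self):
        ranked = self._ranked()
        # unweighted running sum depends only on rank order when weights are
        # equalized; with exponent 1 we check order preservation of |ES| sign
        res1 = val.gsea(ranked, ["a", "b"], n_perm=49, seed=1)
        res2 = val.gsea(ranked * 10, ["a", "b"], n_perm=49, seed=1)
        assert res1.es == pytest.approx(res2.es)

    def test_small_overlap_and_zero_stats_error(self):
        with pytest.raises(ParameterError):
            val.gsea(self._ranked(), ["a"], n_perm=19)
        with pytest.raises(ParameterError):
            val.gsea(pd.Series(0.0, index=list("abc")), ["a", "b"], n_perm=19)

    def test_null_p_values_are_calibrated(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(100)]
        ps = []
        for i in range(100):
            ranked = pd.Series(rng.standard_normal(100), index=genes)
            fake_set = list(rng.choice(genes, size=10, replace=False))
            ps.append(val.gsea(ranked, fake_set, n_perm=99, seed=i).p)
        # permutation p under the null is super-uniform
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01 or np.mean(np.array(ps) < 0.05) <= 0.07

    def test_screen_applies_bh(self):
        ranked = self._ranked()
        df = val.gsea_screen(ranked, {"top": ["a", "b"], "bottom": ["d", "e"]},
                             n_perm=99, seed=0)
        assert set(df.index) == {"top", "bottom"}
        assert (df["q"] >= df["p"] - 1e-12).all()
        assert np.sign(df.loc["top", "NES"]) == np.sign(df.loc["top", "ES"])
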