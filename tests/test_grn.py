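"""Hypergeometric/BH oracles, attribution, phenotype association, driver ranking."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquenet import grn
from plaquenet.errors import ParameterError
from plaquenet.networks import GeneNetwork
from plaquenet.simulate import StagedExpression


def enum_hypergeom_upper(N, K, n, k):
    """Enumeration oracle with exact rational arithmetic."""
    total = Fraction(0)
    for kk in range(k, min(K, n) + 1):
        total += Fraction(comb(K, kk) * comb(N - K, n - kk), comb(N, n))
    return float(total)


class TestHypergeom:
    def test_full_overlap(self):
        assert grn.hypergeom_upper(20, 5, 5, 5) == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_partial_overlap(self):
        assert grn.hypergeom_upper(10, 4, 3, 2) == pytest.approx(
            Fraction(comb(4, 2) * comb(6, 1) + comb(4, 3), comb(10, 3)), rel=1e-12
        )

    def test_zero_overlap_is_one(self):
        assert grn.hypergeom_upper(100, 10, 10, 0) == 1.0

    def test_inconsistent_arguments(self):
        with pytest.raises(ParameterError):
            grn.hypergeom_upper(10, 12, 3, 1)
        with pytest.raises(ParameterError):
            grn.hypergeom_upper(10, 4, 3, 4)

    @given(st.integers(2, 25), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_enumeration(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert grn.hypergeom_upper(N, K, n, k) == pytest.approx(
            enum_hypergeom_upper(N, K, n, k), rel=1e-10, abs=1e-300
        )


class TestBH:
    def test_hand_step_up(self):
        q = grn.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_order_invariant(self, ps):
        p = np.array(ps)
        q = grn.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = grn.bh_adjust(p[perm])
        assert np.allclose(q_perm, q[perm])
        assert np.all(q >= p - 1e-12) and np.all(q <= 1 + 1e-12)


class TestEnrichmentScreen:
    def _networks(self):
        return [
            GeneNetwork("N1", frozenset(f"g{i}" for i in range(10))),
            GeneNetwork("N2", frozenset(f"g{i}" for i in range(10, 20))),
        ]

    def test_disjoint_set_all_null(self):
        universe = {f"g{i}" for i in range(30)}
        screen = grn.enrichment_screen(
            {"S": [f"g{i}" for i in range(20, 30)]}, self._networks(), universe
        )
        assert (screen["q"] == 1.0).all()
        assert not screen["significant"].any()

    def test_planted_overlap_significant(self):
        universe = {f"g{i}" for i in range(200)}
        screen = grn.enrichment_screen(
            {"S": [f"g{i}" for i in range(8)]}, self._networks(), universe
        )
        row = screen.set_index("network_id").loc["N1"]
        assert row["k"] == 8
        assert row["q"] < 0.10 and row["significant"]

    def test_empty_universe_errors(self):
        with pytest.raises(ParameterError):
            grn.enrichment_screen({"S": ["a"]}, self._networks(), set())


class TestAttribution:
    def test_pure_marker_network(self, demo):
        nm, truth, labels = demo["nm"], demo["truth"], demo["labels"]
        ec_markers = [g for g in truth.subcluster_markers["EC1"]
                      if g in set(nm.var_names)]
        net = GeneNetwork("pureEC", frozenset(ec_markers))
        props = grn.grn_cell_attribution(net, nm, labels)
        assert props["EC"] == pytest.approx(1.0)

    def test_absent_gene_counts_nd(self, demo):
        nm, labels = demo["nm"], demo["labels"]
        net = GeneNetwork("ghost", frozenset({"NOT_A_GENE_1", "NOT_A_GENE_2",
                                              "NOT_A_GENE_3"}))
        props = grn.grn_cell_attribution(net, nm, labels)
        assert props["ND"] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self, demo):
        nm, truth, labels = demo["nm"], demo["truth"], demo["labels"]
        rng = np.random.default_rng(0)
        for _ in range(5):
            genes = rng.choice(nm.var_names, size=40, replace=False)
            net = GeneNetwork("R", frozenset(genes))
            props = grn.grn_cell_attribution(net, nm, labels)
            assert props.sum() == pytest.approx(1.0, abs=1e-12)


class TestPhenotypeAssoc:
    def test_t_conversion_closed_form(self):
        rng = np.random.default_rng(0)
        # construct data with exactly r = 0.5 via Gram-Schmidt
        x = rng.standard_normal(20)
        e = rng.standard_normal(20)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (e @ x) / (x @ x)
        e /= np.sqrt((e @ e) / ((x @ x)))
        y = 0.5 * x + np.sqrt(1 - 0.25) * e
        r, t, p = grn.pearson_with_t(x, y)
        assert r == pytest.approx(0.5, abs=1e-9)
        assert t == pytest.approx(0.5 * np.sqrt(18 / 0.75), abs=1e-6)

    def test_perfect_correlation_caps_score(self):
        samples = [f"s{i}" for i in range(12)]
        v = np.arange(12.0)
        bulk = pd.DataFrame({"a": v, "b": v, "c": v}, index=samples)
        phen = pd.DataFrame({"y": v}, index=samples)
        net = GeneNetwork("N", frozenset({"a", "b", "c"}))
        res = grn.grn_phenotype_assoc([net], bulk, phen)
        assert res[0].score == 100.0

    def test_constant_phenotype_scores_zero(self):
        samples = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        bulk = pd.DataFrame(rng.standard_normal((10, 3)),
                            index=samples, columns=["a", "b", "c"])
        phen = pd.DataFrame({"y": np.ones(10)}, index=samples)
        net = GeneNetwork("N", frozenset({"a", "b", "c"}))
        res = grn.grn_phenotype_assoc([net], bulk, phen)
        assert res[0].score == 0.0
        assert (res[0].gene_detail["p"] == 1.0).all()

    def test_score_cap_never_exceeded(self, demo):
        from plaquenet.simulate import simulate_phenotypes

        phen, bulk = simulate_phenotypes(demo["truth"], demo["params"], 80)
        res = grn.grn_phenotype_assoc(demo["networks"], bulk, phen)
        assert all(0 <= r.score <= 100 for r in res)

    def test_unknown_aggregator_errors(self):
        with pytest.raises(ParameterError):
            grn._aggregate_p(np.array([0.5]), "nope")


def _staged(values: dict[str, list[float]], stages, sexes) -> StagedExpression:
    idx = pd.Index([f"m{i}" for i in range(len(stages))], name="sample_id")
    return StagedExpression(
        expr=pd.DataFrame(values, index=idx),
        stage=pd.Series(stages, index=idx),
        sex=pd.Series(sexes, index=idx),
    )


class TestStageTrend:
    def test_monotone_series_rho_one(self):
        staged = _staged({"g": [1, 2, 3]}, ["baseline", "early", "advanced"],
                         ["M", "M", "M"])
        rho, p_two, p_one = grn.stage_trend_test(staged, "g", "M")
        assert rho == pytest.approx(1.0)
        assert p_one < p_two or p_two == 0

    def test_constant_expression(self):
        staged = _staged({"g": [1, 1, 1, 1]},
                         ["baseline", "baseline", "early", "advanced"],
                         ["M"] * 4)
        assert grn.stage_trend_test(staged, "g", "M") == (0.0, 1.0, 1.0)

    def test_shuffled_labels_calibrated(self):
        rng = np.random.default_rng(0)
        stages = ["baseline"] * 4 + ["early"] * 6 + ["advanced"] * 6
        rejections = 0
        runs = 200
        for _ in range(runs):
            staged = _staged(
                {"g": rng.standard_normal(16)},
                list(rng.permutation(stages)), ["M"] * 16,
            )
            _, p_two, _ = grn.stage_trend_test(staged, "g", "M")
            rejections += int(p_two < 0.05)
        assert rejections / runs <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / runs)


class TestRankKeyDrivers:
    def _scenario(self):
        net = GeneNetwork(
            "GRNX", frozenset({"DRV", "other1", "other2", "filler"}),
            key_driver_rank={"DRV": 1, "other1": 2, "other2": 3},
        )
        sexde = pd.DataFrame(
            {"log2fc": [1.2, -0.5, 0.1], "p": [1e-8, 0.3, 0.6]},
            index=["DRV", "other1", "other2"],
        )
        rng = np.random.default_rng(0)
        stages = ["baseline"] * 4 + ["early"] * 6 + ["advanced"] * 6
        idx = pd.Index([f"m{i}" for i in range(16)])
        expr = pd.DataFrame(rng.standard_normal((16, 3)),
                            index=idx, columns=["DRV", "other1", "other2"])
        stage_num = pd.Series([0] * 4 + [1] * 6 + [2] * 6, index=idx)
        expr["DRV"] += 3.0 * stage_num
        staged = StagedExpression(
            expr=expr,
            stage=pd.Series(stages, index=idx),
            sex=pd.Series(["M"] * 16, index=idx),
        )
        return net, sexde, staged

    def test_planted_driver_ranks_first(self):
        net, sexde, staged = self._scenario()
        ranking = grn.rank_key_drivers(net, sexde, staged, "M")
        assert ranking.index[0] == "DRV"
        assert ranking.loc["DRV", "final_rank"] == 1

    def test_single_driver_rank_one(self):
        net = GeneNetwork("G1", frozenset({"a", "b"}), key_driver_rank={"a": 1})
        _, sexde, staged = self._scenario()
        sexde = pd.DataFrame({"log2fc": [0.5], "p": [0.1]}, index=["a"])
        staged.expr["a"] = staged.expr["DRV"]
        ranking = grn.rank_key_drivers(net, sexde, staged, "M")
        assert ranking.loc["a", "final_rank"] == 1

    def test_missing_evidence_marked_nd_at_end(self):
        net, sexde, staged = self._scenario()
        sexde = sexde.drop(index="other2")
        ranking = grn.rank_key_drivers(net, sexde, staged, "M")
        assert ranking.index[-1] == "other2"
        assert np.isnan(ranking.loc["other2", "composite"])
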