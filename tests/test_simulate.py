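"""Generator tests: determinism, planted rates, marker elevation, truth round-trip."""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plaquenet.errors import ParameterError
from plaquenet.grn import enrichment_screen
from plaquenet.simulate import (
    SimParams,
    SimTruth,
    simulate_cells,
    simulate_grns,
    simulate_mouse_course,
    simulate_perturbation,
    simulate_phenotypes,
)
from plaquenet.grn import stage_trend_test

from conftest import small_params


def test_same_seed_is_bit_identical():
    a1, t1 = simulate_cells(small_params(seed=3))
    a2, t2 = simulate_cells(small_params(seed=3))
    assert np.array_equal(a1.X, a2.X)
    pd.testing.assert_frame_equal(t1.cells, t2.cells)


def test_different_seed_differs():
    a1, _ = simulate_cells(small_params(seed=3))
    a2, _ = simulate_cells(small_params(seed=4))
    assert not np.array_equal(a1.X, a2.X)


def test_sex_probability_recovered_within_binomial_ci():
    params = small_params(
        seed=11,
        n_cells=900,
        sex_probs={"SMC1": 0.9, "SMC2": 0.5, "SMC3": 0.5, "EC1": 0.5, "EC2": 0.5},
    )
    _, truth = simulate_cells(params)
    cells = truth.cells[truth.cells["subcluster"] == "SMC1"]
    n = len(cells)
    assert n >= 200
    k = int((cells["sex"] == "F").sum())
    ci = stats.binomtest(k, n).proportion_ci(0.95)
    assert ci.low <= 0.9 <= ci.high


def test_doublets_exceed_read_ceiling_at_planted_rate():
    params = small_params(seed=5, n_cells=1000, doublet_rate=0.05,
                          debris_rate=0.0, dead_rate=0.0)
    adata, truth = simulate_cells(params)
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    dbl = truth.cells["is_doublet"].to_numpy()
    assert np.all(totals[dbl] >= 750_000)
    frac = float((totals >= 750_000).mean())
    ci = stats.binomtest(int(dbl.sum()), 1000).proportion_ci(0.99)
    assert ci.low <= frac <= ci.high
    # debris cells sit below the QC floor
    params2 = small_params(seed=5, n_cells=600, debris_rate=0.05)
    adata2, truth2 = simulate_cells(params2)
    t2 = np.asarray(adata2.X.sum(axis=1)).ravel()
    assert np.all(t2[truth2.cells["is_debris"].to_numpy()] < 50_000)


def test_dead_cells_have_high_mito_fraction():
    params = small_params(seed=9, dead_rate=0.05, doublet_rate=0.0, debris_rate=0.0)
    adata, truth = simulate_cells(params)
    X = adata.X
    mito = X[:, adata.var["is_mito"].to_numpy(bool)].sum(axis=1)
    frac = mito / X.sum(axis=1)
    dead = truth.cells["is_dead"].to_numpy()
    assert np.median(frac[dead]) >= 0.10
    assert np.median(frac[~dead]) < 0.10


def test_markers_elevated_in_their_subcluster(demo):
    """Planted markers have larger mean counts inside their subcluster."""
    adata, truth = demo["adata"], demo["truth"]
    X = np.asarray(adata.X, dtype=float)
    sub = truth.cells["subcluster"].to_numpy()
    gene_idx = {g: i for i, g in enumerate(adata.var_names)}
    ok = total = 0
    for k, genes in truth.subcluster_markers.items():
        inside = sub == k
        for g in genes:
            j = gene_idx[g]
            ok += X[inside, j].mean() > X[~inside, j].mean()
            total += 1
    assert ok / total >= 0.95


def test_invalid_params_raise():
    with pytest.raises(ParameterError):
        small_params(marker_fold=0.5)
    with pytest.raises(ParameterError):
        small_params(sex_probs={"SMC1": 1.5})
    with pytest.raises(ParameterError):
        small_params(n_cells=-5)
    with pytest.raises(ParameterError):
        small_params(planted_overlap=1.2)


def test_truth_round_trips_through_json(tmp_path, demo):
    truth = demo["truth"]
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = SimTruth.from_json(path)
    pd.testing.assert_frame_equal(truth.cells, back.cells, check_dtype=False)
    assert back.subcluster_markers == truth.subcluster_markers
    assert back.networks == truth.networks
    assert back.sex_probs == truth.sex_probs
    assert back.trend_genes == truth.trend_genes


def test_grns_forced_overlap_and_driver_invariants(demo):
    truth, params = demo["truth"], demo["params"]
    t = copy.deepcopy(truth)
    t.networks.clear()
    nets = simulate_grns(t, small_params(planted_overlap=1.0))
    partner = t.networks[nets[0].network_id]["partner"]
    overlap = set(nets[0].nodes) & set(t.subcluster_markers[partner])
    assert len(overlap) == len(t.subcluster_markers[partner])
    for net in nets:
        assert set(net.key_driver_rank) <= set(net.nodes)
        assert sorted(net.key_driver_rank.values()) == list(
            range(1, len(net.key_driver_rank) + 1)
        )
        for s, d in net.edges:
            assert s in net.nodes and d in net.nodes


def test_zero_overlap_networks_are_hypergeometric_background(demo):
    """At rho = 0 the planted pair shows no enrichment in >= 95% of runs."""
    truth = demo["truth"]
    null_sig = 0
    runs = 100
    for i in range(runs):
        t = copy.deepcopy(truth)
        t.networks.clear()
        t.trend_genes.clear()
        nets = simulate_grns(t, small_params(seed=1000 + i, planted_overlap=0.0))
        universe = set(t.genes)
        partner = t.networks[nets[0].network_id]["partner"]
        screen = enrichment_screen(
            {partner: t.subcluster_markers[partner]}, nets, universe
        )
        row = screen[screen["network_id"] == nets[0].network_id].iloc[0]
        null_sig += int(row["q"] < 0.10)
    assert null_sig / runs <= 0.05


def test_phenotype_null_is_calibrated(demo):
    """With all betas zero, few networks reach q < 0.05."""
    from plaquenet.grn import grn_phenotype_assoc

    truth, params = demo["truth"], demo["params"]
    hits = total = 0
    for s in range(5):
        t = copy.deepcopy(truth)
        t.phenotype_betas = {"X": {}, "Y": {}}
        p = small_params(seed=300 + s)
        phen, bulk = simulate_phenotypes(t, p, 100)
        res = grn_phenotype_assoc(demo["networks"], bulk, phen)
        hits += sum(r.q < 0.05 for r in res)
        total += len(res)
    assert hits / total <= 0.10


def test_phenotype_planted_signal_is_top(demo):
    from plaquenet.grn import assoc_scores, grn_phenotype_assoc

    truth = demo["truth"]
    t = copy.deepcopy(truth)
    t.phenotype_betas = {"SYNTAX": {"GRN2": 2.0}}
    phen, bulk = simulate_phenotypes(t, demo["params"], 150)
    scores = assoc_scores(grn_phenotype_assoc(demo["networks"], bulk, phen))
    assert scores["SYNTAX"].idxmax() == "GRN2"


def test_phenotype_requires_networks_and_samples(demo):
    t = copy.deepcopy(demo["truth"])
    with pytest.raises(ParameterError):
        simulate_phenotypes(t, demo["params"], n_samples=5)
    t.networks.clear()
    with pytest.raises(ParameterError):
        simulate_phenotypes(t, demo["params"], n_samples=50)


def test_mouse_design_and_trend_planting(demo):
    truth, params = demo["truth"], demo["params"]
    staged = simulate_mouse_course(truth, params)
    assert staged.stage.value_counts().to_dict() == {
        "advanced": 20, "early": 18, "baseline": 8
    }
    by = staged.stage.groupby([staged.stage, staged.sex]).size()
    assert by[("baseline", "F")] == 2 and by[("baseline", "M")] == 6
    assert by[("early", "F")] == 6 and by[("early", "M")] == 12
    assert by[("advanced", "F")] == 10 and by[("advanced", "M")] == 10


def test_mouse_trend_type1_and_power(demo):
    truth, params = demo["truth"], demo["params"]
    # type I: with delta = 0 no gene trends beyond chance
    rejections = 0
    runs = 100
    for i in range(runs):
        t = copy.deepcopy(truth)
        t.trend_genes.clear()
        staged = simulate_mouse_course(t, small_params(seed=500 + i, stage_effect=0.0))
        gene = staged.expr.columns[0]
        _, p_two, _ = stage_trend_test(staged, gene, "M")
        rejections += int(p_two < 0.05)
    assert rejections / runs <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / runs)

    # power: delta = 3 sd detected in >= 90% of runs
    detected = 0
    for i in range(runs):
        t = copy.deepcopy(truth)
        t.trend_genes = {"GENE00050": "M"}
        staged = simulate_mouse_course(t, small_params(seed=700 + i, stage_effect=3.0))
        _, p_two, _ = stage_trend_test(staged, "GENE00050", "M")
        detected += int(p_two < 0.05)
    assert detected / runs >= 0.90


def test_perturbation_collapses_module_correlation(demo):
    truth, params = demo["truth"], demo["params"]
    pert = simulate_perturbation(truth, params, "GRN1")
    from plaquenet.validation import pairwise_corr_matrix

    mod = pert["module"]
    mock = pairwise_corr_matrix(pert["expr"]["Mock"], mod).to_numpy()
    kd = pairwise_corr_matrix(pert["expr"]["perturbed"], mod).to_numpy()
    iu = np.triu_indices(len(mod), 1)
    assert mock[iu].mean() > kd[iu].mean()
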