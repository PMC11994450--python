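"""Pipeline orchestration: artifact-producing runs and planted-truth benchmarks.

Two entry points:

* :func:`run_pipeline` executes the full stage sequence configured by a
  :class:`~plaquenet.config.RunConfig` (simulate -> QC -> normalize ->
  cluster -> annotate -> subcluster -> markers -> composition -> enrichment ->
  phenotypes -> drivers -> preservation -> perturbation), writing every
  artifact plus a manifest into the run directory.
* :func:`run_synthetic_study` runs the same chain in memory on default
  synthetic data and scores recovery of every planted structure against the
  simulation truth, returning a flat metrics dict.

All stage randomness derives from one seed salted with the stage name, so
stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from plaquenet import composition as comp
from plaquenet import grn as grn_mod
from plaquenet import io as pio
from plaquenet import markers as mk
from plaquenet import pipeline as pl
from plaquenet import validation as val
from plaquenet.config import RunConfig
from plaquenet.errors import ParameterError, PipelineError
from plaquenet.simulate import (
    SimParams,
    SimTruth,
    simulate_cells,
    simulate_grns,
    simulate_mouse_course,
    simulate_perturbation,
    simulate_phenotypes,
    stage_seed,
)

log = logging.getLogger(__name__)

_TYPE_PREFIX = re.compile(r"^([A-Za-z]+)")


def major_type_of(subcluster_id: str) -> str:
    """Major-type prefix of a subcluster id (``SMC3`` -> ``SMC``)."""
    m = _TYPE_PREFIX.match(subcluster_id)
    if not m:
        raise ParameterError(f"malformed subcluster id {subcluster_id!r}")
    return m.group(1)


def cluster_and_annotate(nm, config: RunConfig, panels=None) -> pd.DataFrame:
    """HVG -> PCA -> graph clustering -> panel annotation -> subclustering.

    Returns a per-cell label frame with ``major_type`` and ``subcluster``
    columns; cells of types too small to subcluster keep a single
    type-prefixed subcluster id.
    """
    genes = pl.select_hvg(nm, n=min(config.n_hvg, nm.n_vars))
    emb = pl.embed_pca(nm, genes, k=config.n_pcs, seed=config.seed)
    clusters = pl.cluster_graph(
        emb, k_neighbors=config.k_neighbors, resolution=config.resolution,
        seed=config.seed,
    )
    major, _ = pl.annotate_types(nm, clusters, panels=panels)
    labels = pd.DataFrame({"major_type": major})
    labels["subcluster"] = pd.Series(dtype=object)
    for typ in sorted(set(major.dropna()) - {"unassigned"}):
        n_cells = int((major == typ).sum())
        if n_cells >= 2 * config.k_neighbors:
            sub = pl.subcluster(
                nm, major, typ, n_hvg=config.n_hvg, k_pcs=config.n_pcs,
                k_neighbors=config.k_neighbors, resolution=config.resolution,
                seed=config.seed,
            )
            labels.loc[sub.index, "subcluster"] = sub
        else:
            labels.loc[major == typ, "subcluster"] = f"{typ}1"
    return labels


def _map_to_truth(labels: pd.DataFrame, truth: SimTruth) -> dict[str, str]:
    """Majority-vote mapping from detected subcluster to planted subcluster."""
    truth_sub = truth.cells["subcluster"]
    mapping: dict[str, str] = {}
    for sub in sorted(labels["subcluster"].dropna().unique()):
        cells = labels.index[labels["subcluster"] == sub]
        votes = truth_sub.reindex(cells).value_counts()
        if len(votes):
            mapping[sub] = votes.index[0]
    return mapping


def run_synthetic_study(
    seed: int = 0,
    params: SimParams | None = None,
    config: RunConfig | None = None,
    n_power_sims: int = 100,
    n_random_modules: int = 100,
) -> dict:
    """End-to-end planted-truth benchmark on default synthetic data.

    Returns a dict of recovery metrics (sensitivity of sex-bias detection,
    null calibration, planted-enrichment ranking, marker recovery, clustering
    agreement, key-driver rank, preservation and perturbation outcomes) plus
    the intermediate objects under the ``"objects"`` key.
    """
    config = config or RunConfig(seed=seed)
    params = params or SimParams(seed=seed)
    metrics: dict[str, float] = {}

    # --- generate
    adata, truth = simulate_cells(params)
    networks = simulate_grns(truth, params)

    # --- QC and normalization
    kept, qc_report = pl.qc_cells(
        adata, lo=config.qc_lo, hi=config.qc_hi,
        mito_max=config.qc_mito_max, spike_max=config.qc_spike_max,
    )
    kept = pl.qc_genes(kept, min_cells=config.gene_min_cells,
                       min_total=config.gene_min_total)
    nm = pl.normalize_log(kept)
    metrics["n_cells_pass_qc"] = float(nm.n_obs)
    flagged = truth.cells[["is_doublet", "is_debris", "is_dead"]].any(axis=1)
    removed = set(qc_report["cell_id"])
    metrics["qc_flagged_removed_frac"] = float(
        np.mean([c in removed for c in truth.cells.index[flagged]])
    )

    # --- clustering and annotation
    labels = cluster_and_annotate(nm, config)
    truth_kept = truth.cells.reindex(nm.obs_names)
    ok_type = labels["major_type"] == truth_kept["type"]
    metrics["major_type_accuracy"] = float(ok_type.mean())

    aris = []
    for typ in ("SMC", "MP", "EC"):
        mask = (labels["major_type"] == typ) & (truth_kept["type"] == typ)
        if mask.sum() > 10:
            aris.append(
                adjusted_rand_score(
                    truth_kept.loc[mask, "subcluster"], labels.loc[mask, "subcluster"]
                )
            )
    metrics["subcluster_ari_min"] = float(min(aris)) if aris else float("nan")
    mapping = _map_to_truth(labels, truth)

    # --- markers
    sig_sets: dict[str, list[str]] = {}
    for sub in sorted(labels["subcluster"].dropna().unique()):
        typ = major_type_of(sub)
        if (labels.loc[labels["major_type"] == typ, "subcluster"].nunique()) < 2:
            continue
        table = mk.subcluster_markers(nm, labels, sub)
        sig_sets[sub] = table.index[table["significant"]].tolist()
    # marker recovery is scored per planted subcluster (types with a single
    # planted program have no within-type contrast and are excluded)
    sub_counts = labels["subcluster"].value_counts()
    marker_hits, marker_total, false_markers, tested_genes = 0, 0, 0, 0
    planted_multi = [
        s for s, gs in truth.subcluster_markers.items()
        if sum(t.startswith(major_type_of(s)) for t in truth.subcluster_markers) > 1
    ]
    for planted_sub in planted_multi:
        cands = [s for s, t in mapping.items() if t == planted_sub and s in sig_sets]
        if not cands:
            continue
        best = max(cands, key=lambda s: sub_counts.get(s, 0))
        sig = set(sig_sets[best])
        planted = set(truth.subcluster_markers[planted_sub])
        typ = major_type_of(planted_sub)
        marker_hits += len(planted & sig)
        marker_total += len(planted)
        false_markers += len(sig - planted - set(truth.type_markers.get(typ, [])))
        tested_genes += nm.n_vars
    metrics["marker_sensitivity"] = marker_hits / marker_total if marker_total else float("nan")
    metrics["marker_false_rate"] = false_markers / tested_genes if tested_genes else float("nan")

    # --- sex composition
    biased = set(truth.biased_subclusters())
    detected_biased = set()
    rates, weights = [], []
    for typ in sorted(set(labels["major_type"].dropna()) - {"unassigned"}):
        in_type = labels[labels["major_type"] == typ]
        if in_type["subcluster"].nunique() < 2:
            continue
        table = comp.composition_table(in_type, nm.obs)
        bias = comp.per_cluster_bias(table)
        sizes = (bias["O_F"] + bias["O_M"]).tolist()
        rates.append(comp.null_rejection_rate(
            sizes, n_rep=1000, seed=stage_seed(params.seed, f"null-{typ}")
        ))
        weights.append(len(sizes))
        for sub, row in bias.iterrows():
            planted = mapping.get(sub)
            if planted in biased and row["p"] < 0.05:
                planted_dir = "F" if truth.sex_probs[planted] > 0.5 else "M"
                if row["dominant_sex"] == planted_dir:
                    detected_biased.add(planted)
    metrics["sex_bias_sensitivity"] = (
        len(detected_biased & biased) / len(biased) if biased else float("nan")
    )
    metrics["sex_bias_null_type1"] = float(np.average(rates, weights=weights)) if rates else float("nan")

    # --- GRN enrichment
    universe = set(nm.var_names) & {g for net in networks for g in net.nodes}
    screen = grn_mod.enrichment_screen(sig_sets, networks, universe, fdr=config.fdr_level)
    planted_pairs = [
        (info["partner"], nid) for nid, info in truth.networks.items()
        if info["partner"] is not None
    ]
    top3, sig_pairs, n_pairs = 0, 0, 0
    worst_q = 0.0
    for partner, nid in planted_pairs:
        cands = [s for s, t in mapping.items() if t == partner and s in sig_sets]
        if not cands:
            continue
        n_pairs += 1
        sub = max(cands, key=lambda s: len(sig_sets[s]))
        rows = screen[screen["set_id"] == sub].sort_values("p")
        rank = rows.reset_index(drop=True).index[rows["network_id"].to_numpy() == nid]
        qv = float(rows.loc[rows["network_id"] == nid, "q"].iloc[0])
        worst_q = max(worst_q, qv)
        if len(rank) and rank[0] < 3:
            top3 += 1
        if qv < config.fdr_level:
            sig_pairs += 1
    metrics["enrichment_pairs_evaluated"] = float(n_pairs)
    metrics["enrichment_top3_rate"] = top3 / n_pairs if n_pairs else float("nan")
    metrics["enrichment_sig_rate"] = sig_pairs / n_pairs if n_pairs else float("nan")
    metrics["enrichment_worst_q"] = worst_q

    # --- phenotype association
    phen, bulk = simulate_phenotypes(truth, params, config.n_phenotype_samples)
    assoc = grn_mod.grn_phenotype_assoc(networks, bulk, phen,
                                        method=config.assoc_aggregation)
    scores = grn_mod.assoc_scores(assoc)
    for pname, betas in truth.phenotype_betas.items():
        if betas:
            target = max(betas, key=betas.get)
            metrics[f"assoc_top_is_planted_{pname}"] = float(
                scores[pname].idxmax() == target
            )
            metrics[f"assoc_score_{pname}"] = float(scores.loc[target, pname])

    # --- key drivers
    target_net = networks[0]
    info = truth.networks[target_net.network_id]
    partner = info["partner"]
    target_sex = "F" if truth.sex_probs[partner] > 0.5 else "M"
    staged = simulate_mouse_course(truth, params)
    typ = major_type_of(partner)
    type_cells = labels.index[labels["major_type"] == typ]
    sexde = mk.sex_de(nm[nm.obs_names.isin(type_cells)].copy(),
                      nm.obs["sex"], target_sex)
    ranking = grn_mod.rank_key_drivers(target_net, sexde, staged, target_sex)
    planted_driver = info["key_drivers"][0]
    metrics["planted_driver_rank"] = float(ranking.loc[planted_driver, "final_rank"])

    # --- preservation
    _, bulk_test = simulate_phenotypes(truth, params, config.n_phenotype_samples,
                                       salt="phenotypes-test")
    module = info["members"]
    pres = val.preservation_permutation(
        bulk, bulk_test, module, n_perm=config.n_perm_preservation,
        seed=stage_seed(params.seed, "preserve"), module_id=target_net.network_id,
    )
    metrics["preservation_max_p"] = float(max(pres.p_values.values()))
    metrics["preservation_preserved"] = float(pres.preserved)

    rng = np.random.default_rng(stage_seed(params.seed, "preserve-null"))
    non_module = [g for g in bulk.columns if g not in set(module)]
    false_pres = 0
    for i in range(n_random_modules):
        rand_mod = list(rng.choice(non_module, size=30, replace=False))
        r = val.preservation_permutation(
            bulk, bulk_test, rand_mod, n_perm=config.n_perm_preservation,
            seed=stage_seed(params.seed, f"preserve-null-{i}"),
        )
        false_pres += int(r.preserved)
    metrics["random_module_nonpreserved_rate"] = (
        1 - false_pres / n_random_modules if n_random_modules else float("nan")
    )

    # --- perturbation
    pert = simulate_perturbation(truth, params, target_net.network_id)
    conn = val.connectivity_change(pert["expr"], pert["module"], control="Mock")
    metrics["connectivity_mock_mean"] = float(conn.loc["Mock", "mean_pairwise_cor"])
    metrics["connectivity_perturbed_mean"] = float(
        conn.loc["perturbed", "mean_pairwise_cor"]
    )
    metrics["connectivity_p"] = float(conn.loc["perturbed", "p_vs_control"])
    stat = val.de_rank_stat(pert["counts"], pert["groups"], "perturbed", "Mock")
    gres = val.gsea(stat, pert["module"], n_perm=config.n_perm_gsea,
                    seed=stage_seed(params.seed, "gsea"), set_id=target_net.network_id)
    metrics["perturbation_nes"] = float(gres.nes)
    metrics["perturbation_gsea_p"] = float(gres.p)

    hits = 0
    for i in range(n_power_sims):
        p_i = simulate_perturbation(
            truth, params, target_net.network_id,
            seed=stage_seed(params.seed, f"power-{i}"),
        )
        c_i = val.connectivity_change(p_i["expr"], p_i["module"], control="Mock")
        drop = (c_i.loc["perturbed", "mean_pairwise_cor"]
                < c_i.loc["Mock", "mean_pairwise_cor"])
        if drop and c_i.loc["perturbed", "p_vs_control"] < 0.05:
            hits += 1
    metrics["connectivity_power"] = hits / n_power_sims if n_power_sims else float("nan")

    metrics["objects"] = {
        "params": params, "truth": truth, "adata": adata, "nm": nm,
        "labels": labels, "networks": networks, "mapping": mapping,
        "screen": screen, "scores": scores, "ranking": ranking,
        "preservation": pres, "connectivity": conn, "gsea": gres,
        "qc_report": qc_report,
    }
    return metrics


# --------------------------------------------------------------- full pipeline

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stage sequence, writing artifacts and a manifest.

    Every stage appends to the manifest as it completes; a failing stage
    aborts with a :class:`PipelineError` naming the stage, and the manifest is
    flagged incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": [],
        "complete": False,
        "inputs": {},
    }

    def finish_stage(name: str) -> None:
        manifest["stages"].append(name)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def fail(name: str, exc: Exception) -> None:
        manifest["incomplete_stage"] = name
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    truth = None
    networks = None
    params = None

    # simulate or load
    try:
        if config.simulate:
            params = SimParams(seed=config.seed, n_genes=config.sim_n_genes,
                               n_cells=config.sim_n_cells)
            adata, truth = simulate_cells(params)
            networks = simulate_grns(truth, params)
            pio.write_count_matrix(adata, outdir / "counts")
            truth.to_json(outdir / "truth.json")
            pio.write_networks(networks, outdir / "network_nodes.tsv",
                               outdir / "network_edges.tsv")
        else:
            if config.counts_path is None:
                raise ParameterError("counts_path required when simulate is false")
            adata = pio.read_count_matrix(config.counts_path, config.cell_meta_path)
            if config.network_nodes_path:
                networks = pio.read_networks(config.network_nodes_path,
                                             config.network_edges_path)
            for key in ("counts_path", "cell_meta_path", "network_nodes_path",
                        "network_edges_path"):
                p = getattr(config, key)
                if p and Path(p).is_file():
                    manifest["inputs"][key] = _sha256(Path(p))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("simulate" if config.simulate else "load", exc)
    finish_stage("simulate" if config.simulate else "load")

    try:
        kept, qc_report = pl.qc_cells(adata, lo=config.qc_lo, hi=config.qc_hi,
                                      mito_max=config.qc_mito_max,
                                      spike_max=config.qc_spike_max)
        kept = pl.qc_genes(kept, config.gene_min_cells, config.gene_min_total)
        pio.write_table(qc_report, outdir / "qc_report.tsv",
                        meta={"stage": "qc", "seed": config.seed}, index=False)
    except Exception as exc:  # noqa: BLE001
        fail("qc", exc)
    finish_stage("qc")

    try:
        nm = pl.normalize_log(kept)
    except Exception as exc:  # noqa: BLE001
        fail("normalize", exc)
    finish_stage("normalize")

    try:
        labels = cluster_and_annotate(nm, config)
        pio.write_table(labels, outdir / "labels.tsv",
                        meta={"stage": "cluster", "seed": config.seed})
    except Exception as exc:  # noqa: BLE001
        fail("cluster", exc)
    finish_stage("cluster")

    sig_sets: dict[str, list[str]] = {}
    try:
        markers_dir = outdir / "markers"
        markers_dir.mkdir(exist_ok=True)
        for sub in sorted(labels["subcluster"].dropna().unique()):
            typ = major_type_of(sub)
            if labels.loc[labels["major_type"] == typ, "subcluster"].nunique() < 2:
                continue
            table = mk.subcluster_markers(nm, labels, sub)
            pio.write_table(mk.top_markers(table), markers_dir / f"{sub}.tsv",
                            meta={"subcluster": sub})
            sig_sets[sub] = table.index[table["significant"]].tolist()
    except Exception as exc:  # noqa: BLE001
        fail("markers", exc)
    finish_stage("markers")

    try:
        comp_rows = []
        omni = {}
        for typ in sorted(set(labels["major_type"].dropna()) - {"unassigned"}):
            in_type = labels[labels["major_type"] == typ]
            if in_type["subcluster"].nunique() < 2:
                continue
            table = comp.composition_table(in_type, nm.obs)
            bias = comp.per_cluster_bias(table)
            comp_rows.append(bias)
            omni[typ] = comp.omnibus_test(table)
        if comp_rows:
            pio.write_table(pd.concat(comp_rows), outdir / "composition.tsv",
                            meta={"stage": "composition"})
        (outdir / "composition_omnibus.json").write_text(json.dumps(omni, indent=1))
    except Exception as exc:  # noqa: BLE001
        fail("composition", exc)
    finish_stage("composition")

    if networks:
        try:
            universe = set(nm.var_names) & {g for net in networks for g in net.nodes}
            screen = grn_mod.enrichment_screen(sig_sets, networks, universe,
                                               fdr=config.fdr_level)
            pio.write_table(screen, outdir / "enrichment.tsv",
                            meta={"stage": "enrichment", "fdr": config.fdr_level},
                            index=False)
        except Exception as exc:  # noqa: BLE001
            fail("enrichment", exc)
        finish_stage("enrichment")

    if config.simulate and truth is not None and networks:
        try:
            phen, bulk = simulate_phenotypes(truth, params, config.n_phenotype_samples)
            assoc = grn_mod.grn_phenotype_assoc(networks, bulk, phen,
                                                method=config.assoc_aggregation)
            pio.write_table(grn_mod.assoc_scores(assoc), outdir / "phenotype_scores.tsv",
                            meta={"stage": "phenotype"})
        except Exception as exc:  # noqa: BLE001
            fail("phenotype", exc)
        finish_stage("phenotype")

        try:
            info = truth.networks[networks[0].network_id]
            partner = info["partner"]
            target_sex = "F" if truth.sex_probs[partner] > 0.5 else "M"
            staged = simulate_mouse_course(truth, params)
            typ = major_type_of(partner)
            type_cells = labels.index[labels["major_type"] == typ]
            sexde = mk.sex_de(nm[nm.obs_names.isin(type_cells)].copy(),
                              nm.obs["sex"], target_sex)
            ranking = grn_mod.rank_key_drivers(networks[0], sexde, staged, target_sex)
            pio.write_table(ranking, outdir / "key_drivers.tsv",
                            meta={"network": networks[0].network_id,
                                  "target_sex": target_sex})
        except Exception as exc:  # noqa: BLE001
            fail("drivers", exc)
        finish_stage("drivers")

        if config.run_preservation:
            try:
                _, bulk_test = simulate_phenotypes(
                    truth, params, config.n_phenotype_samples, salt="phenotypes-test"
                )
                pres = val.preservation_permutation(
                    bulk, bulk_test, info["members"],
                    n_perm=config.n_perm_preservation,
                    seed=stage_seed(config.seed, "preserve"),
                    module_id=networks[0].network_id,
                )
                pres_df = pd.DataFrame(
                    {"observed": pres.observed, "p": pres.p_values}
                )
                pio.write_table(pres_df, outdir / "preservation.tsv",
                                meta={"module": pres.module_id,
                                      "n_perm": pres.n_perm,
                                      "preserved": pres.preserved})
            except Exception as exc:  # noqa: BLE001
                fail("preserve", exc)
            finish_stage("preserve")

        if config.run_perturbation:
            try:
                pert = simulate_perturbation(truth, params, networks[0].network_id)
                conn = val.connectivity_change(pert["expr"], pert["module"],
                                               control="Mock")
                pio.write_table(conn, outdir / "connectivity.tsv",
                                meta={"network": networks[0].network_id})
                stat = val.de_rank_stat(pert["counts"], pert["groups"],
                                        "perturbed", "Mock")
                gdf = val.gsea_screen(stat, {networks[0].network_id: pert["module"]},
                                      n_perm=config.n_perm_gsea,
                                      seed=stage_seed(config.seed, "gsea"))
                pio.write_table(gdf, outdir / "gsea.tsv", meta={"stage": "perturb"})
            except Exception as exc:  # noqa: BLE001
                fail("perturb", exc)
            finish_stage("perturb")

    manifest["complete"] = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
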