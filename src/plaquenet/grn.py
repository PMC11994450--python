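"""GRN integration: enrichment, cell-type attribution, phenotype association, drivers.

The screen asks which gene-regulatory networks are over-represented in a gene
set (e.g. a subcluster's sex-biased markers) via the hypergeometric upper
tail with Benjamini-Hochberg adjustment over all (set, network) pairs at 10%
FDR. Network genes are attributed to major cell types by maximal cluster-mean
z-scored expression; network-phenotype association aggregates gene-level
Pearson correlation t-tests; key drivers are prioritized by a composite of
network rank, sex-biased expression and progression trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from plaquenet.errors import ParameterError
from plaquenet.networks import GeneNetwork
from plaquenet.pipeline import _dense
from plaquenet.simulate import StagedExpression

log = logging.getLogger(__name__)

FDR_LEVEL = 0.10
ATTRIBUTION_Z_MIN = 0.25
SCORE_CAP = 100.0

#: Pluggable gene-level p-value aggregators for network-phenotype association.
AGGREGATORS = ("fisher", "stouffer", "minp_sidak")


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric overlap probability P(X >= k).

    ``N`` universe size, ``K`` network genes in the universe, ``n`` query
    genes in the universe, ``k`` observed overlap. Computed by summing the
    log pmf for numerical stability.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ParameterError(f"inconsistent hypergeometric arguments N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    ks = np.arange(k, min(K, n) + 1)
    return float(np.exp(logsumexp(stats.hypergeom.logpmf(ks, N, K, n))))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def enrichment_screen(
    sets: dict[str, list[str]],
    networks: list[GeneNetwork],
    universe: set[str],
    fdr: float = FDR_LEVEL,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every gene set in every network.

    Genes outside the universe are dropped with a log message; BH adjustment
    runs jointly over all (set, network) pairs and pairs with q below the FDR
    level (default 10%) are flagged significant.
    """
    if not universe:
        raise ParameterError("empty universe")
    universe = set(universe)
    N = len(universe)
    records = []
    for set_id in sorted(sets):
        genes = set(sets[set_id])
        dropped = genes - universe
        if dropped:
            log.info("enrichment_screen: %s: %d genes outside universe dropped",
                     set_id, len(dropped))
        query = genes & universe
        for net in networks:
            members = set(net.nodes) & universe
            k = len(query & members)
            p = hypergeom_upper(N, len(members), len(query), k)
            records.append(
                {
                    "set_id": set_id,
                    "network_id": net.network_id,
                    "N": N,
                    "K": len(members),
                    "n": len(query),
                    "k": k,
                    "p": p,
                }
            )
    out = pd.DataFrame(records)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["neglog10_q"] = -np.log10(np.maximum(out["q"], 1e-300))
    out["significant"] = out["q"] < fdr
    return out


def grn_cell_attribution(
    network: GeneNetwork, nm: ad.AnnData, labels: pd.DataFrame
) -> pd.Series:
    """Fraction of network genes attributable to each major cell type.

    Each network gene is assigned to the major type with maximal
    cluster-mean z-scored expression; genes absent from the matrix or with a
    top z below 0.25 count as ``"ND"`` (not determined). Proportions sum to 1.
    """
    types = sorted(set(labels["major_type"].dropna()) - {"unassigned"})
    if len(types) < 2:
        raise ParameterError("need at least 2 major types for attribution")
    X = _dense(nm.X)
    lab = labels["major_type"].reindex(nm.obs_names)
    means = np.vstack([X[(lab == t).to_numpy()].mean(axis=0) for t in types])
    mu, sd = means.mean(axis=0), means.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (means - mu) / np.maximum(sd, 1e-300), 0.0)
    zdf = pd.DataFrame(z, index=types, columns=nm.var_names)

    counts = {t: 0 for t in types}
    counts["ND"] = 0
    for g in sorted(network.nodes):
        if g not in zdf.columns:
            counts["ND"] += 1
            continue
        col = zdf[g]
        if col.max() < ATTRIBUTION_Z_MIN:
            counts["ND"] += 1
        else:
            counts[col.idxmax()] += 1
    total = sum(counts.values())
    return pd.Series({t: c / total for t, c in counts.items()}, name=network.network_id)


def _aggregate_p(p: np.ndarray, method: str) -> float:
    """Combine gene-level p-values into one network-level p."""
    p = np.clip(np.asarray(p, float), 1e-300, 1.0)
    if method == "fisher":
        chi = -2.0 * np.log(p).sum()
        return float(stats.chi2.sf(chi, 2 * p.size))
    if method == "stouffer":
        z = stats.norm.isf(p / 2).sum() / np.sqrt(p.size)
        return float(2 * stats.norm.sf(abs(z)))
    if method == "minp_sidak":
        return float(1 - (1 - p.min()) ** p.size)
    raise ParameterError(f"unknown aggregation method {method!r}; choose from {AGGREGATORS}")


@dataclass
class PhenotypeAssoc:
    """Aggregated network-phenotype association with gene-level detail."""

    network_id: str
    phenotype: str
    gene_detail: pd.DataFrame  # per gene: r, t, p
    aggregated_p: float
    q: float
    score: float  # min(100, -log10 q)


def pearson_with_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson r, its t statistic and the two-sided p on pairwise-complete data."""
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ParameterError("need at least 3 complete sample pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 0.0, 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, np.inf if r > 0 else -np.inf, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return r, float(t), p


def grn_phenotype_assoc(
    networks: list[GeneNetwork],
    bulk: pd.DataFrame,
    phenotypes: pd.DataFrame,
    method: str = "minp_sidak",
) -> list[PhenotypeAssoc]:
    """Score every (network, phenotype) pair by aggregated gene-level association.

    Per member gene present in the bulk table, the Pearson correlation with
    the phenotype and its two-sided t-test p are computed (constant columns
    yield p = 1 with a log message). Gene p-values are aggregated into one
    network-level p (default min-p with Sidak correction, which stays
    calibrated under the strong positive correlation of co-expressed member
    genes; Fisher's combined statistic and Stouffer's method are pluggable),
    BH-adjusted per phenotype across the network collection, and reported as
    ``score = min(100, -log10 q)``. A network without usable genes scores 0.
    """
    results: list[PhenotypeAssoc] = []
    for phen in phenotypes.columns:
        y = phenotypes[phen].to_numpy(float)
        per_net: list[tuple[GeneNetwork, pd.DataFrame, float]] = []
        for net in networks:
            genes = sorted(set(net.nodes) & set(bulk.columns))
            rows = []
            for g in genes:
                x = bulk[g].to_numpy(float)
                if np.ptp(x[np.isfinite(x)]) == 0 or np.ptp(y[np.isfinite(y)]) == 0:
                    log.info("grn_phenotype_assoc: constant %s/%s, p set to 1", g, phen)
                    rows.append({"gene": g, "r": 0.0, "t": 0.0, "p": 1.0})
                    continue
                r, t, p = pearson_with_t(x, y)
                rows.append({"gene": g, "r": r, "t": t, "p": p})
            detail = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
                columns=["r", "t", "p"]
            )
            agg = _aggregate_p(detail["p"].to_numpy(), method) if len(detail) else 1.0
            per_net.append((net, detail, agg))
        qs = bh_adjust(np.array([a for _, _, a in per_net]))
        for (net, detail, agg), q in zip(per_net, qs):
            score = 0.0 if len(detail) == 0 else min(
                SCORE_CAP, float(-np.log10(max(q, 10**-SCORE_CAP)))
            )
            results.append(
                PhenotypeAssoc(
                    network_id=net.network_id,
                    phenotype=phen,
                    gene_detail=detail,
                    aggregated_p=agg,
                    q=float(q),
                    score=score,
                )
            )
    return results


def assoc_scores(results: list[PhenotypeAssoc]) -> pd.DataFrame:
    """Network x phenotype score table (radar-plot layout)."""
    df = pd.DataFrame(
        [(r.network_id, r.phenotype, r.score) for r in results],
        columns=["network_id", "phenotype", "score"],
    )
    return df.pivot(index="network_id", columns="phenotype", values="score")


def stage_trend_test(
    staged: StagedExpression, gene: str, sex: str
) -> tuple[float, float, float]:
    """Spearman progression-trend test for one gene in one sex.

    Correlates expression with the ordered stage index (baseline 0, early 1,
    advanced 2). Returns (rho, two-sided p, one-sided increasing p); constant
    expression yields (0, 1, 1).
    """
    mask = (staged.sex == sex).to_numpy()
    if gene not in staged.expr.columns:
        raise ParameterError(f"gene {gene!r} absent from staged expression")
    x = staged.stage_index().to_numpy()[mask]
    v = staged.expr[gene].to_numpy(float)[mask]
    if np.unique(x).size < 2:
        raise ParameterError(f"fewer than 2 stages present for sex {sex!r}")
    if np.ptp(v) == 0:
        return 0.0, 1.0, 1.0
    rho, p_two = stats.spearmanr(v, x)
    if np.isnan(rho):
        return 0.0, 1.0, 1.0
    p_one = p_two / 2 if rho > 0 else 1 - p_two / 2
    return float(rho), float(p_two), float(p_one)


def rank_key_drivers(
    network: GeneNetwork,
    human_sex_de: pd.DataFrame,
    staged: StagedExpression,
    target_sex: str,
) -> pd.DataFrame:
    """Composite prioritization of a network's key drivers for one sex.

    Ranks the key drivers on three criteria: (a) the network's own
    key-driver rank, (b) evidence of target-sex-up differential expression in
    the human single-cell data (-log10 p, zero unless upregulated in the
    target sex), (c) evidence of an increasing progression trend in the
    target sex of the mouse course (-log10 one-sided p). The composite is the
    unweighted mean of the three criterion ranks, ties broken by key-driver
    rank; drivers missing from any evidence source carry composite NaN ("ND")
    and sort last.
    """
    drivers = network.key_drivers
    if not drivers:
        raise ParameterError(f"{network.network_id}: no key drivers")
    rows = []
    for g in drivers:
        kd_rank = network.key_driver_rank[g]
        de_ev = trend_ev = np.nan
        if g in human_sex_de.index:
            de = human_sex_de.loc[g]
            up = de["log2fc"] > 0
            de_ev = float(-np.log10(max(de["p"], 1e-300))) if up else 0.0
        if g in staged.expr.columns:
            _, _, p_one = stage_trend_test(staged, g, target_sex)
            trend_ev = float(-np.log10(max(p_one, 1e-300)))
        rows.append({"gene": g, "key_driver_rank": kd_rank,
                     "sex_de_evidence": de_ev, "trend_evidence": trend_ev})
    df = pd.DataFrame(rows).set_index("gene")
    complete = df.dropna().copy()
    if len(complete):
        r_kd = stats.rankdata(complete["key_driver_rank"])
        r_de = stats.rankdata(-complete["sex_de_evidence"])
        r_tr = stats.rankdata(-complete["trend_evidence"])
        complete["composite"] = (r_kd + r_de + r_tr) / 3.0
    df["composite"] = complete["composite"] if len(complete) else np.nan
    df = df.sort_values(
        ["composite", "key_driver_rank"], na_position="last", kind="mergesort"
    )
    df["final_rank"] = [
        i + 1 if np.isfinite(c) else np.nan for i, c in enumerate(df["composite"])
    ]
    return df
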