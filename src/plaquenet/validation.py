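"""Permutation module preservation, perturbation connectivity and GSEA.

Preservation asks whether a module's co-expression structure recurs in an
independent test dataset. Four statistics are computed between the discovery
and test correlation structures (mean |pairwise correlation|, correlation of
vectorized correlation matrices, correlation of within-module weighted
degrees, mean |gene-to-module-summary correlation|) and compared with a null
of random same-size gene sets drawn from the test data's non-module genes;
the module counts as preserved when every statistic is permutation
significant. Connectivity change compares within-module pairwise correlation
multisets between perturbed conditions and a control. GSEA is the classic
weighted Kolmogorov-Smirnov running sum with a gene-label permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from plaquenet.errors import ParameterError
from plaquenet.grn import bh_adjust

log = logging.getLogger(__name__)

PRESERVATION_STATS = ("avg_cor", "cor_cor", "cor_degree", "avg_contrib")


def pairwise_corr_matrix(expr: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Gene x gene Pearson correlation matrix of a sample x gene table.

    Symmetric with unit diagonal; genes constant across samples correlate 0
    with everything (logged).
    """
    if genes is not None:
        missing = set(genes) - set(expr.columns)
        if missing:
            raise ParameterError(f"genes absent from expression table: {sorted(missing)[:5]}")
        expr = expr[genes]
    if expr.shape[0] < 3:
        raise ParameterError("need at least 3 samples for correlations")
    X = expr.to_numpy(float)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        log.warning("pairwise_corr_matrix: %d constant genes correlate 0", int(const.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.where(np.isfinite(C), C, 0.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=expr.columns, columns=expr.columns)


def _module_summary(expr: np.ndarray) -> np.ndarray:
    """First-principal-component module summary, sign-aligned to mean expression."""
    centered = expr - expr.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    score = u[:, 0] * s[0]
    mean_profile = centered.mean(axis=1)
    if np.dot(score, mean_profile) < 0:
        score = -score
    return score


def preservation_stats(
    disc_corr: pd.DataFrame,
    test_corr: pd.DataFrame,
    module: list[str],
    test_expr: pd.DataFrame | None = None,
) -> dict[str, float]:
    """The four module-preservation statistics for one module.

    ``avg_cor``: mean |pairwise correlation| among module genes in the test
    data. ``cor_cor``: Pearson correlation between the vectorized off-diagonal
    discovery and test correlation matrices. ``cor_degree``: correlation of
    within-module weighted degrees (row sums of |correlation|, diagonal
    excluded). ``avg_contrib``: mean |gene-to-module-summary correlation| in
    the test data (requires ``test_expr``; otherwise NaN).
    """
    module = list(module)
    present = [g for g in module if g in test_corr.index and g in disc_corr.index]
    dropped = set(module) - set(present)
    if dropped:
        log.info("preservation_stats: %d module genes missing, dropped", len(dropped))
    if len(present) < 3:
        raise ParameterError("fewer than 3 module genes available in both datasets")
    D = disc_corr.loc[present, present].to_numpy(float)
    T = test_corr.loc[present, present].to_numpy(float)
    iu = np.triu_indices(len(present), k=1)

    avg_cor = float(np.abs(T[iu]).mean())
    d_off, t_off = D[iu], T[iu]
    if np.ptp(d_off) == 0 or np.ptp(t_off) == 0:
        cor_cor = 0.0
    else:
        cor_cor = float(np.corrcoef(d_off, t_off)[0, 1])
    deg_d = np.abs(D).sum(axis=1) - 1.0
    deg_t = np.abs(T).sum(axis=1) - 1.0
    if np.ptp(deg_d) == 0 or np.ptp(deg_t) == 0:
        cor_degree = 1.0 if np.allclose(deg_d, deg_t) else 0.0
    else:
        cor_degree = float(np.corrcoef(deg_d, deg_t)[0, 1])

    avg_contrib = np.nan
    if test_expr is not None:
        E = test_expr[present].to_numpy(float)
        summary = _module_summary(E)
        contribs = []
        for j in range(E.shape[1]):
            if np.ptp(E[:, j]) == 0 or np.ptp(summary) == 0:
                contribs.append(0.0)
            else:
                contribs.append(abs(np.corrcoef(E[:, j], summary)[0, 1]))
        avg_contrib = float(np.mean(contribs))
    return {
        "avg_cor": avg_cor,
        "cor_cor": cor_cor,
        "cor_degree": cor_degree,
        "avg_contrib": avg_contrib,
    }


@dataclass
class PreservationResult:
    """Observed preservation statistics with permutation p-values."""

    module_id: str
    observed: dict[str, float]
    p_values: dict[str, float]
    n_perm: int
    preserved: bool  # every statistic permutation-significant


def preservation_permutation(
    disc_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    module: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    module_id: str = "module",
) -> PreservationResult:
    """Permutation test of module preservation in an independent dataset.

    The null draws random gene sets of the module's size from the test
    data's non-module genes and recomputes each statistic against the
    module's discovery structure. Upper-tail p-values carry the +1
    correction: ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 19:
        raise ParameterError("n_perm must be at least 19 for any p-value resolution")
    rng = np.random.default_rng(seed)
    module = [g for g in module if g in test_expr.columns and g in disc_expr.columns]
    if len(module) < 3:
        raise ParameterError("fewer than 3 module genes present in both datasets")
    background = [g for g in test_expr.columns if g not in set(module)]
    if len(background) < 10 * len(module):
        log.warning(
            "preservation_permutation: background %d < 10x module size %d",
            len(background), len(module),
        )
    if len(background) < len(module):
        raise ParameterError("background smaller than module; cannot permute")

    disc_corr = pairwise_corr_matrix(disc_expr, module)
    test_corr_full = pairwise_corr_matrix(test_expr)
    observed = preservation_stats(disc_corr, test_corr_full, module, test_expr)

    m = len(module)
    exceed = {s: 0 for s in PRESERVATION_STATS}
    bg = np.array(background)
    for _ in range(n_perm):
        perm_genes = list(rng.choice(bg, size=m, replace=False))
        # null keeps the module's discovery structure, swaps in random test genes
        fake_test = test_corr_full.loc[perm_genes, perm_genes]
        fake_test.index = module
        fake_test.columns = module
        fake_expr = test_expr[perm_genes].copy()
        fake_expr.columns = module
        null = preservation_stats(disc_corr, fake_test, module, fake_expr)
        for s in PRESERVATION_STATS:
            if null[s] >= observed[s]:
                exceed[s] += 1
    p_values = {s: (1 + exceed[s]) / (1 + n_perm) for s in PRESERVATION_STATS}
    preserved = max(p_values.values()) < alpha
    return PreservationResult(
        module_id=module_id, observed=observed, p_values=p_values,
        n_perm=n_perm, preserved=preserved,
    )


def connectivity_change(
    expr_by_condition: dict[str, pd.DataFrame],
    module: list[str],
    control: str,
) -> pd.DataFrame:
    """Within-module pairwise-correlation means per condition vs a control.

    For each condition the multiset of pairwise Pearson correlations among
    module genes is collected; each non-control condition is compared with
    the control multiset by a two-sided t-test (unadjusted).
    """
    if control not in expr_by_condition:
        raise ParameterError(f"control condition {control!r} not provided")
    if len(module) < 3:
        raise ParameterError("module must have at least 3 genes")
    corrs: dict[str, np.ndarray] = {}
    for cond, expr in expr_by_condition.items():
        if expr.shape[0] < 3:
            raise ParameterError(f"condition {cond!r} has fewer than 3 replicates")
        C = pairwise_corr_matrix(expr, module).to_numpy()
        iu = np.triu_indices(len(module), k=1)
        corrs[cond] = C[iu]
    rows = []
    for cond in expr_by_condition:
        if cond == control:
            p = np.nan
        else:
            p = float(stats.ttest_ind(corrs[cond], corrs[control]).pvalue)
        rows.append(
            {
                "condition": cond,
                "mean_pairwise_cor": float(corrs[cond].mean()),
                "n_pairs": corrs[cond].size,
                "p_vs_control": p,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def de_rank_stat(
    counts: pd.DataFrame, groups: pd.Series, condition: str, control: str
) -> pd.Series:
    """Welch-t ranking statistic on log2(CPM + 1), condition minus control.

    A simple signed per-gene statistic to rank genes for GSEA from raw bulk
    counts.
    """
    groups = groups.reindex(counts.index)
    mask_a = (groups == condition).to_numpy()
    mask_b = (groups == control).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ParameterError("need at least 2 samples per group")
    X = counts.to_numpy(float)
    lib = X.sum(axis=1)
    if np.any(lib <= 0):
        bad = counts.index[np.flatnonzero(lib <= 0)[0]]
        raise ParameterError(f"sample {bad!r} has zero library size")
    logcpm = np.log2(1e6 * X / lib[:, None] + 1.0)
    res = stats.ttest_ind(logcpm[mask_a], logcpm[mask_b], axis=0, equal_var=False)
    t = np.asarray(res.statistic, float)
    t[~np.isfinite(t)] = 0.0
    return pd.Series(t, index=counts.columns, name="stat")


@dataclass
class GseaResult:
    """Enrichment score, normalized score and permutation significance of one set."""

    set_id: str
    es: float
    nes: float
    p: float
    q: float = np.nan
    n_hits: int = 0


def _running_es(order_stats: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0) -> float:
    """Classic weighted KS enrichment score on a pre-ranked list."""
    w = np.abs(order_stats) ** weight
    nr = w[hit_mask].sum()
    n_miss = (~hit_mask).sum()
    if nr == 0 or n_miss == 0:
        raise ParameterError("gene set covers none or all of the ranked genes")
    steps = np.where(hit_mask, w / nr, -1.0 / n_miss)
    run = np.cumsum(steps)
    return float(run[np.argmax(np.abs(run))])


def gsea(
    ranked: pd.Series,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    set_id: str = "set",
) -> GseaResult:
    """Pre-ranked GSEA of one gene set with a gene-label permutation null.

    Genes are ordered by decreasing statistic; the weighted (exponent 1)
    Kolmogorov-Smirnov running sum gives the enrichment score. The null
    permutes which genes belong to the set; NES divides the observed score by
    the mean |permuted score| of the same sign, and the upper-tail p carries
    the +1 correction.
    """
    stats_ = ranked.to_numpy(float)
    if np.all(stats_ == 0):
        raise ParameterError("all ranking statistics are zero")
    hits = ranked.index.isin(set(gene_set))
    if hits.sum() < 2:
        raise ParameterError("gene set shares fewer than 2 genes with the ranking")
    order = np.argsort(-stats_, kind="mergesort")
    s_sorted = stats_[order]
    hit_sorted = hits[order]
    es = _running_es(s_sorted, hit_sorted)

    rng = np.random.default_rng(seed)
    n_hit = int(hits.sum())
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        fake = np.zeros(ranked.size, dtype=bool)
        fake[rng.choice(ranked.size, size=n_hit, replace=False)] = True
        perm_es[i] = _running_es(s_sorted, fake)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(perm_es).mean()
    nes = es / denom if denom > 0 else 0.0
    # p conditions on the observed sign (the standard GSEA convention):
    # among same-sign permutations, how often is the score at least as extreme
    n_ge = int(np.sum(np.abs(same_sign) >= abs(es)))
    p = (1 + n_ge) / (1 + same_sign.size)
    return GseaResult(set_id=set_id, es=es, nes=float(nes), p=float(p), n_hits=n_hit)


def gsea_screen(
    ranked: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """GSEA over a collection of sets with BH adjustment across sets."""
    results = [
        gsea(ranked, genes, n_perm=n_perm, seed=seed + i, set_id=sid)
        for i, (sid, genes) in enumerate(sorted(sets.items()))
    ]
    qs = bh_adjust(np.array([r.p for r in results]))
    rows = []
    for r, q in zip(results, qs):
        r.q = float(q)
        rows.append({"set_id": r.set_id, "ES": r.es, "NES": r.nes,
                     "p": r.p, "q": r.q, "n_hits": r.n_hits})
    return pd.DataFrame(rows).set_index("set_id")
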