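"""Wilcoxon rank-sum marker (differential-expression) calling for subclusters.

Subcluster marker genes are those differentially expressed in one subcluster
against all other subclusters of the same major cell type, tested with the
two-sided Mann-Whitney / Wilcoxon rank-sum test; significance uses
log2 fold change > 0.3 together with Bonferroni-adjusted P < 0.005.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from plaquenet.errors import ParameterError
from plaquenet.pipeline import _dense

log = logging.getLogger(__name__)

LOG2FC_MIN = 0.3
P_BONF_MAX = 0.005
_FC_EPS = 1e-9


def rank_sum_test(a, b) -> tuple[float, float]:
    """Mann-Whitney U statistic and two-sided p for two samples.

    Uses the exact null distribution when the pooled size is at most 12 and
    the data carry no ties, otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("rank_sum_test: both groups must be nonempty")
    pooled = np.concatenate([a, b])
    exact = a.size + b.size <= 12 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def _vectorized_ranksum(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p values (normal approximation)."""
    res = stats.mannwhitneyu(Xa, Xb, alternative="two-sided", method="asymptotic", axis=0)
    return np.asarray(res.pvalue, dtype=float)


def two_group_de(
    nm: ad.AnnData, mask_a: np.ndarray, mask_b: np.ndarray
) -> pd.DataFrame:
    """Per-gene rank-sum differential expression of group A versus group B.

    Works on log-normalized values; the fold change de-logs the group means
    (``mean(exp(v) - 1)``) with a 1e-9 pseudocount before taking log2.
    Returns a table with ``log2fc``, ``p``, ``p_bonf``, ``pct_in``,
    ``pct_out``, ``direction`` and the joint ``significant`` flag.
    """
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ParameterError("two_group_de: both groups must be nonempty")
    X = _dense(nm.X).astype(np.float64)
    Xa, Xb = X[mask_a], X[mask_b]

    if mask_a.sum() + mask_b.sum() <= 12:
        p = np.array([rank_sum_test(Xa[:, j], Xb[:, j])[1] for j in range(X.shape[1])])
    else:
        p = _vectorized_ranksum(Xa, Xb)
    # a gene constant across both groups carries no evidence
    const = np.ptp(np.vstack([Xa, Xb]), axis=0) == 0
    p[const] = 1.0

    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    log2fc = np.log2((mean_a + _FC_EPS) / (mean_b + _FC_EPS))
    m = X.shape[1]
    p_bonf = np.minimum(1.0, p * m)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_bonf": p_bonf,
            "pct_in": (Xa > 0).mean(axis=0),
            "pct_out": (Xb > 0).mean(axis=0),
            "direction": np.where(log2fc > 0, "up", "down"),
            "significant": (log2fc > LOG2FC_MIN) & (p_bonf < P_BONF_MAX),
        },
        index=pd.Index(nm.var_names, name="gene"),
    )
    return table


def subcluster_markers(
    nm: ad.AnnData, labels: pd.DataFrame, target: str
) -> pd.DataFrame:
    """Marker table for one subcluster versus its same-type background.

    ``labels`` must carry ``major_type`` and ``subcluster`` columns indexed by
    cell. The background is every other subcluster of the target's major
    type; a type with a single subcluster has no background and errors.
    """
    labels = labels.reindex(nm.obs_names)
    if target not in set(labels["subcluster"].dropna()):
        raise ParameterError(f"unknown subcluster {target!r}")
    major = labels.loc[labels["subcluster"] == target, "major_type"].iloc[0]
    in_type = (labels["major_type"] == major).to_numpy()
    mask_a = (labels["subcluster"] == target).to_numpy()
    mask_b = in_type & ~mask_a
    if mask_b.sum() == 0:
        raise ParameterError(
            f"subcluster {target!r} has no same-type background ({major} has one subcluster)"
        )
    return two_group_de(nm, mask_a, mask_b)


def sex_de(nm: ad.AnnData, sexes: pd.Series, target_sex: str) -> pd.DataFrame:
    """Differential expression of the target sex versus the other sex."""
    sexes = sexes.reindex(nm.obs_names)
    mask_a = (sexes == target_sex).to_numpy()
    mask_b = (~(sexes == target_sex) & sexes.notna().to_numpy()).to_numpy()
    return two_group_de(nm, mask_a, mask_b)


def top_markers(table: pd.DataFrame, n: int = 100) -> pd.DataFrame:
    """Top-``n`` upregulated markers ordered by p then fold change."""
    up = table[table["direction"] == "up"]
    return up.sort_values(["p", "log2fc"], ascending=[True, False]).head(n)
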