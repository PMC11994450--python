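"""Sex-composition contingency analysis of subcellular clusters.

The chi-square construction follows the classic contingency recipe: expected
counts are (row total) x (column total) / (grand total), the statistic is
sum((O - E)^2 / E) on (rows-1)(cols-1) degrees of freedom. Per-subcluster sex
bias is assessed with a one-vs-rest 2x2 table within the cluster's own cell
type; printed percentages use round-half-to-even to the nearest integer.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from plaquenet.errors import ParameterError

log = logging.getLogger(__name__)

SEXES = ("F", "M")


def composition_table(labels: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Exact subcluster x sex cross-tabulation with margins.

    ``labels`` carries a ``subcluster`` column; ``meta`` a ``sex`` column in
    {F, M}; both are indexed by cell id. Cells with missing or invalid sex
    raise an error that lists them.
    """
    sex = meta["sex"].reindex(labels.index)
    bad = labels.index[~sex.isin(SEXES)].tolist()
    if bad:
        raise ParameterError(f"cells with missing or invalid sex metadata: {bad[:10]}")
    table = pd.crosstab(labels["subcluster"], sex, margins=True, margins_name="total")
    table = table.reindex(columns=[*SEXES, "total"], fill_value=0)
    table.index.name = "subcluster"
    table.columns.name = "sex"
    return table


def _strip_margins(table: pd.DataFrame) -> pd.DataFrame:
    t = table.drop(index="total", errors="ignore")
    return t.drop(columns="total", errors="ignore")


def chi_square_test(table: pd.DataFrame, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square of independence on a contingency table.

    Expected counts are row total x column total / grand total. No continuity
    correction by default; ``yates=True`` applies the Yates correction
    (meaningful for 2x2 tables).
    """
    O = _strip_margins(table).to_numpy(dtype=float)
    if O.shape[0] < 2 or O.shape[1] < 2:
        raise ParameterError("contingency table needs at least 2 rows and 2 columns")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ParameterError("zero row or column margin in contingency table")
    E = np.outer(row, col) / O.sum()
    diff = np.abs(O - E)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def per_cluster_bias(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-vs-rest 2x2 sex-bias test for every subcluster row of the table.

    For each subcluster, the 2x2 table opposes that subcluster to all other
    subclusters of the same compartment by sex. Reports observed and expected
    counts, integer sex percentages (round-half-to-even), the dominant sex and
    a dominance flag at the given significance level.
    """
    counts = _strip_margins(table)
    if counts.shape[0] < 2:
        raise ParameterError("need at least 2 subclusters for one-vs-rest testing")
    total = counts.to_numpy(dtype=float).sum(axis=0)
    rows = []
    for sub, row in counts.iterrows():
        o_f, o_m = float(row["F"]), float(row["M"])
        n = o_f + o_m
        if n == 0:
            log.warning("per_cluster_bias: subcluster %s has 0 cells, skipped", sub)
            continue
        rest = total - np.array([o_f, o_m])
        two = pd.DataFrame([[o_f, o_m], rest], index=[sub, "rest"], columns=["F", "M"])
        grand = two.to_numpy().sum()
        e_f = n * total[0] / grand
        e_m = n * total[1] / grand
        chi2, _, p = chi_square_test(two)
        pct_f = round(100 * o_f / n)
        pct_m = round(100 * o_m / n)
        rows.append(
            {
                "subcluster": sub,
                "O_F": int(o_f),
                "O_M": int(o_m),
                "E_F": e_f,
                "E_M": e_m,
                "pct_F": int(pct_f),
                "pct_M": int(pct_m),
                "dominant_sex": "F" if o_f / n > 0.5 else ("M" if o_m / n > 0.5 else "none"),
                "chi2": chi2,
                "p": p,
                "dominance": bool(p < alpha) and o_f != o_m,
            }
        )
    return pd.DataFrame(rows).set_index("subcluster")


def omnibus_test(table: pd.DataFrame, yates: bool = False) -> dict[str, float]:
    """Global subclusters x sex chi-square summary of one compartment."""
    chi2, df, p = chi_square_test(table, yates=yates)
    return {"chi2": chi2, "df": df, "p": p}


def null_rejection_rate(
    cluster_sizes: list[int],
    p_female: float = 0.5,
    n_rep: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I rate of the one-vs-rest 2x2 test under no sex bias.

    Resamples each cell's sex i.i.d. Bernoulli(``p_female``) for the given
    cluster sizes ``n_rep`` times and reports the fraction of (replicate,
    cluster) tests rejecting at level ``alpha``. The chi-square statistic is
    computed from the same observed-vs-expected construction used by
    :func:`chi_square_test`, vectorized over replicates.
    """
    rng = np.random.default_rng(seed)
    sizes = np.asarray(cluster_sizes, dtype=int)
    if sizes.size < 2:
        raise ParameterError("need at least 2 clusters")
    grand = sizes.sum()
    rejections = 0
    tests = 0
    for k, n_k in enumerate(sizes):
        rest = grand - n_k
        a = rng.binomial(n_k, p_female, size=n_rep).astype(float)  # cluster F
        c = rng.binomial(rest, p_female, size=n_rep).astype(float)  # rest F
        O = np.stack(
            [np.stack([a, n_k - a], axis=1), np.stack([c, rest - c], axis=1)], axis=1
        )  # n_rep x 2 x 2
        row = O.sum(axis=2, keepdims=True)
        col = O.sum(axis=1, keepdims=True)
        E = row * col / grand
        valid = (E > 0).all(axis=(1, 2))
        chi2 = ((O - E) ** 2 / np.where(E > 0, E, 1.0)).sum(axis=(1, 2))
        pvals = stats.chi2.sf(chi2[valid], 1)
        rejections += int((pvals < alpha).sum())
        tests += int(valid.sum())
    return rejections / tests if tests else float("nan")
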