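"""QC, normalization, feature selection, embedding, graph clustering, annotation.

Counts travel as :class:`anndata.AnnData` (cells x genes, raw integer counts,
``obs`` columns ``donor``/``sex``/``gate``, ``var`` flags ``is_mito``/
``is_spikein``). The stage order is fixed: cell QC, then gene QC, then
log-normalization (spike-ins excluded from size factors and dropped), then
binned-dispersion feature selection, PCA embedding and shared-nearest-neighbor
modularity clustering.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from plaquenet.errors import NoCellsPassQCError, ParameterError

log = logging.getLogger(__name__)

#: Library-size floor: libraries at or below this read count are discarded.
QC_MIN_READS = 50_000
#: Doublet ceiling: libraries at or above this read count are discarded.
QC_MAX_READS = 750_000
#: Maximal tolerated mitochondrial (and ERCC) read fraction, exclusive keep.
QC_MAX_MITO_FRAC = 0.10
QC_MAX_SPIKE_FRAC = 0.10

#: Shared-nearest-neighbor Jaccard weights below 1/15 are pruned.
SNN_PRUNE = 1.0 / 15.0

DEFAULT_TYPE_PANELS: dict[str, list[str]] = {
    "SMC": ["MYH11", "ACTA2", "ACTC1"],
    "EC": ["PECAM1", "VWF", "CLDN5"],
    "MP": ["PTPRC", "CD68"],
    "T": ["CD3E"],
    "pericyte": ["PDGFRB", "RGS5"],
}


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def qc_cells(
    adata: ad.AnnData,
    lo: float = QC_MIN_READS,
    hi: float = QC_MAX_READS,
    mito_max: float = QC_MAX_MITO_FRAC,
    spike_max: float = QC_MAX_SPIKE_FRAC,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove low-quality libraries; return the filtered matrix and a report.

    A cell is removed when its total read count is <= ``lo`` (low library) or
    >= ``hi`` (putative doublet), or when its mitochondrial or spike-in read
    fraction is >= the respective maximum. The report lists every removed
    cell with all reasons that applied.
    """
    if not lo < hi:
        raise ParameterError(f"lo ({lo}) must be below hi ({hi})")
    for frac in (mito_max, spike_max):
        if not 0 <= frac <= 1:
            raise ParameterError("QC fractions must be in [0, 1]")

    X = _dense(adata.X)
    total = X.sum(axis=1)
    mito = X[:, adata.var["is_mito"].to_numpy(bool)].sum(axis=1)
    spike = X[:, adata.var["is_spikein"].to_numpy(bool)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 1.0)
        spike_frac = np.where(total > 0, spike / np.maximum(total, 1), 1.0)

    reasons = {
        "low_counts": total <= lo,
        "high_counts": total >= hi,
        "high_mito": mito_frac >= mito_max,
        "high_spikein": spike_frac >= spike_max,
    }
    removed = np.zeros(adata.n_obs, dtype=bool)
    for mask in reasons.values():
        removed |= mask

    rows = []
    for i in np.flatnonzero(removed):
        rows.append(
            {
                "cell_id": adata.obs_names[i],
                "total_counts": int(total[i]),
                "mito_frac": float(mito_frac[i]),
                "spike_frac": float(spike_frac[i]),
                "reasons": ";".join(name for name, mask in reasons.items() if mask[i]),
            }
        )
    report = pd.DataFrame(rows, columns=["cell_id", "total_counts", "mito_frac", "spike_frac", "reasons"])
    kept = adata[~removed].copy()
    if kept.n_obs == 0:
        raise NoCellsPassQCError("no cells pass QC")
    return kept, report


def qc_genes(adata: ad.AnnData, min_cells: int = 3, min_total: int = 300) -> ad.AnnData:
    """Drop genes detected in < ``min_cells`` cells or with total < ``min_total`` reads."""
    if min_cells < 0:
        raise ParameterError("min_cells must be nonnegative")
    X = _dense(adata.X)
    detected = (X > 0).sum(axis=0)
    total = X.sum(axis=0)
    keep = (detected >= min_cells) & (total >= min_total)
    return adata[:, keep].copy()


def normalize_log(adata: ad.AnnData) -> ad.AnnData:
    """Library-size normalize to 10k and natural-log transform.

    The size factor ``L_c`` is the per-cell total over retained non-spike-in
    genes; spike-ins are then dropped from the output. Values are
    ``ln(1 + 1e4 * x / L_c)``.
    """
    endo = ~adata.var["is_spikein"].to_numpy(bool)
    X = _dense(adata.X)[:, endo].astype(np.float64)
    L = X.sum(axis=1)
    if np.any(L <= 0):
        bad = adata.obs_names[np.flatnonzero(L <= 0)[0]]
        raise ParameterError(f"cell {bad!r} has zero total count over non-spike-in genes")
    norm = np.log1p(1e4 * X / L[:, None])
    out = ad.AnnData(
        X=norm.astype(np.float32),
        obs=adata.obs.copy(),
        var=adata.var.loc[endo].copy(),
    )
    return out


def select_hvg(nm: ad.AnnData, n: int = 2000) -> list[str]:
    """Top-``n`` highly variable genes by binned standardized dispersion.

    Genes are binned into 20 equal-width bins of mean log-expression; within
    each bin the dispersion (variance / mean) is z-scored, and the genes with
    the largest standardized dispersion are returned. Ties break by gene id.
    """
    if nm.n_vars < 2:
        raise ParameterError("need at least 2 genes for feature selection")
    if n > nm.n_vars:
        raise ParameterError(f"requested {n} genes but only {nm.n_vars} available")
    X = _dense(nm.X).astype(np.float64)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(nm.n_vars)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

    lo, hi = mean.min(), mean.max()
    width = (hi - lo) / 20 or 1.0
    bins = np.minimum(((mean - lo) / width).astype(int), 19)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = disp[sel].mean(), disp[sel].std(ddof=0)
        z[sel] = (disp[sel] - mu) / sd if sd > 0 else 0.0

    order = sorted(range(nm.n_vars), key=lambda i: (-z[i], nm.var_names[i]))
    return [nm.var_names[i] for i in order[:n]]


def embed_pca(
    nm: ad.AnnData, genes: list[str] | None = None, k: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Scaled, clipped PCA embedding of the cells.

    Selected genes are centered and unit-scaled with z-values clipped to
    +/- 10 before the top-``k`` principal component projection. Zero-variance
    genes are dropped with a log message. The sign convention makes the
    largest-magnitude loading of each component positive.
    """
    if genes is None:
        genes = list(nm.var_names)
    X = _dense(nm[:, genes].X).astype(np.float64)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.info("embed_pca: dropping %d zero-variance genes", int((~keep).sum()))
        X, sd = X[:, keep], sd[keep]
    if X.shape[1] == 0:
        raise ParameterError("no varying genes left for PCA")
    Z = np.clip((X - X.mean(axis=0)) / sd, -10, 10)
    k = min(k, nm.n_obs - 1, Z.shape[1] - 1)
    if k < 1:
        raise ParameterError("need at least 2 cells and 2 genes for PCA")
    pca = PCA(n_components=k, svd_solver="randomized", random_state=seed)
    emb = pca.fit_transform(Z)
    # deterministic sign: flip each component so its extreme loading is positive
    for j in range(k):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            emb[:, j] = -emb[:, j]
    return pd.DataFrame(emb, index=nm.obs_names, columns=[f"PC{j + 1}" for j in range(k)])


def _snn_graph(embedding: np.ndarray, k_neighbors: int) -> sp.csr_matrix:
    """Shared-nearest-neighbor Jaccard weight matrix, pruned below 1/15."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    idx = idx[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sp.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n), dtype=np.float64
    )
    knn_union = ((A + A.T) > 0).astype(np.float64)
    shared = (A @ A.T).multiply(knn_union)
    shared = shared.tocoo()
    union = 2 * k_neighbors - shared.data
    jacc = shared.data / union
    W = sp.coo_matrix((jacc, (shared.row, shared.col)), shape=(n, n)).tocsr()
    W.data[W.data < SNN_PRUNE] = 0.0
    W.eliminate_zeros()
    W = W.maximum(W.T)
    W.setdiag(0)
    W.eliminate_zeros()
    return W


def cluster_graph(
    embedding: pd.DataFrame,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> pd.Series:
    """Graph-based clustering: KNN, SNN Jaccard weights, modularity communities.

    Euclidean K-nearest neighbors (default 20) define a shared-nearest-neighbor
    graph whose Jaccard edge weights below 1/15 are pruned; Leiden
    resolution-scaled modularity maximization at the given resolution and seed
    partitions the graph. Cluster ids are relabeled by decreasing size.
    """
    import igraph
    import leidenalg

    n = embedding.shape[0]
    if k_neighbors >= n:
        log.warning("cluster_graph: k_neighbors %d >= cells %d, reducing", k_neighbors, n)
        k_neighbors = n - 1
    if k_neighbors < 1:
        raise ParameterError("need at least 2 cells to cluster")
    W = _snn_graph(embedding.to_numpy(np.float64), k_neighbors)
    W = sp.triu(W, k=1).tocoo()
    g = igraph.Graph(
        n=n, edges=list(zip(W.row.tolist(), W.col.tolist())), directed=False
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=W.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel by decreasing cluster size, ties by original label
    sizes = pd.Series(labels).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {c: i for i, c in enumerate(order)}
    out = pd.Series([remap[c] for c in labels], index=embedding.index, name="cluster")
    return out


def annotate_types(
    nm: ad.AnnData,
    clusters: pd.Series,
    panels: dict[str, list[str]] | None = None,
) -> tuple[pd.Series, dict[int, str]]:
    """Assign each cluster a major cell type from marker-panel scores.

    Per gene, cluster-mean expression is z-scored across clusters; a cluster's
    panel score is the mean z over the panel's genes and the argmax panel wins.
    Clusters whose top score is negative, or whose top two scores are within
    1e-6, are labeled ``"unassigned"``. Returns per-cell labels and the
    cluster -> type map.
    """
    panels = panels or DEFAULT_TYPE_PANELS
    if not panels:
        raise ParameterError("panels must be nonempty")
    present = {t: [g for g in gs if g in nm.var_names] for t, gs in panels.items()}
    for t, gs in panels.items():
        missing = set(gs) - set(present[t])
        if missing:
            log.info("annotate_types: panel %s missing genes %s", t, sorted(missing))
    if not any(present.values()):
        raise ParameterError("no panel gene present in the matrix")

    X = _dense(nm.X)
    clusters = clusters.reindex(nm.obs_names)
    ids = sorted(clusters.unique())
    means = np.vstack([X[(clusters == c).to_numpy()].mean(axis=0) for c in ids])
    mu, sd = means.mean(axis=0), means.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (means - mu) / np.maximum(sd, 1e-300), 0.0)
    zdf = pd.DataFrame(z, index=ids, columns=nm.var_names)

    cluster_to_type: dict[int, str] = {}
    for c in ids:
        scores = {
            t: float(zdf.loc[c, gs].mean()) for t, gs in present.items() if gs
        }
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        top_t, top_s = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else -np.inf
        if top_s < 0 or top_s - second < 1e-6:
            cluster_to_type[c] = "unassigned"
        else:
            cluster_to_type[c] = top_t
    labels = clusters.map(cluster_to_type)
    labels.name = "major_type"
    return labels, cluster_to_type


def subcluster(
    nm: ad.AnnData,
    major_labels: pd.Series,
    major_type: str,
    n_hvg: int = 2000,
    k_pcs: int = 50,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> pd.Series:
    """Recluster the cells of one major type into type-prefixed subclusters.

    Reruns feature selection, PCA and graph clustering restricted to the
    type's cells; subcluster ids are ``f"{type}{i}"`` ordered by decreasing
    size (``SMC1`` largest).
    """
    mask = (major_labels.reindex(nm.obs_names) == major_type).to_numpy()
    n_cells = int(mask.sum())
    if n_cells < 2 * k_neighbors:
        raise ParameterError(
            f"too few cells to subcluster {major_type!r}: {n_cells} < {2 * k_neighbors}"
        )
    sub = nm[mask].copy()
    genes = select_hvg(sub, n=min(n_hvg, sub.n_vars))
    emb = embed_pca(sub, genes, k=k_pcs, seed=seed)
    raw = cluster_graph(emb, k_neighbors=k_neighbors, resolution=resolution, seed=seed)
    labels = raw.map(lambda c: f"{major_type}{c + 1}")
    labels.name = "subcluster"
    return labels
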