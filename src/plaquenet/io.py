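"""Readers and writers for the package's on-disk formats.

Count matrices travel as a Matrix Market triplet directory (``matrix.mtx``
genes x cells, ``genes.tsv``, ``barcodes.tsv``) plus cell-metadata TSV, or as
a dense gene x cell TSV for small fixtures. Gene sets use GMT; networks use
a node TSV (network_id, gene, key_driver_rank) plus an edge TSV
(network_id, src, dst), with a GMT fallback producing membership-only
networks. Output tables are TSV with a leading ``#key=value`` metadata
comment block.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from plaquenet.errors import ParameterError
from plaquenet.networks import GeneNetwork

log = logging.getLogger(__name__)

MITO_PREFIX = "MT-"
SPIKE_PREFIX = "ERCC-"


# ---------------------------------------------------------------- count matrix

def write_count_matrix(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write an MTX triplet plus cell- and gene-metadata TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.csr_matrix(X) if not sp.issparse(X) else X
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat.T.astype(np.int64))  # genes x cells
    gene_meta = adata.var.reset_index().rename(columns={"index": "gene"})
    if "gene" not in gene_meta.columns:
        gene_meta.insert(0, "gene", adata.var_names)
    gene_meta.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="cell_id").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    cell_meta = adata.obs.reset_index().rename(columns={"index": "cell_id"})
    if "cell_id" not in cell_meta.columns:
        cell_meta.insert(0, "cell_id", adata.obs_names)
    cell_meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    return outdir


def _validate_counts(X: np.ndarray, where: str) -> np.ndarray:
    if np.any(X < 0):
        i, j = np.argwhere(X < 0)[0]
        raise ParameterError(f"{where}: negative count at row {i}, column {j}")
    if not np.allclose(X, np.round(X)):
        i, j = np.argwhere(~np.isclose(X, np.round(X)))[0]
        raise ParameterError(f"{where}: non-integer count at row {i}, column {j}")
    return X.astype(np.int64)


def read_count_matrix(
    path: str | Path,
    cell_meta: str | Path | None = None,
    mito_prefix: str = MITO_PREFIX,
    spike_prefix: str = SPIKE_PREFIX,
) -> ad.AnnData:
    """Read a count matrix from an MTX triplet directory or a dense TSV.

    The dense form is a gene x cell table with gene ids in the first column
    and cell ids as the header. Gene flags are inferred from name prefixes
    unless a ``genes.tsv`` with explicit ``is_mito``/``is_spikein`` columns is
    present. ``cell_meta`` (TSV with at least ``cell_id``, ``donor``, ``sex``)
    overrides or supplies the cell annotations.
    """
    path = Path(path)
    if path.is_dir():
        mat = scipy.io.mmread(str(path / "matrix.mtx"))
        X = np.asarray(sp.csr_matrix(mat).todense()).T  # cells x genes
        genes_df = pd.read_csv(path / "genes.tsv", sep="\t")
        gene_ids = genes_df.iloc[:, 0].astype(str).tolist()
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
        if len(gene_ids) != X.shape[1]:
            raise ParameterError(
                f"genes.tsv has {len(gene_ids)} rows but matrix has {X.shape[1]} genes"
            )
        if len(barcodes) != X.shape[0]:
            raise ParameterError(
                f"barcodes.tsv has {len(barcodes)} rows but matrix has {X.shape[0]} cells"
            )
        if cell_meta is None and (path / "cells.tsv").exists():
            cell_meta = path / "cells.tsv"
    else:
        dense = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = dense.index.astype(str).tolist()
        barcodes = dense.columns.astype(str).tolist()
        X = dense.to_numpy().T
        genes_df = pd.DataFrame({"gene": gene_ids})

    X = _validate_counts(np.asarray(X, dtype=float), str(path))
    if len(set(gene_ids)) != len(gene_ids):
        raise ParameterError("duplicate gene ids")
    if len(set(barcodes)) != len(barcodes):
        raise ParameterError("duplicate cell ids")

    if {"is_mito", "is_spikein"} <= set(genes_df.columns):
        var = genes_df.set_index(genes_df.columns[0])[["is_mito", "is_spikein"]].astype(bool)
        var.index = pd.Index(gene_ids, name="gene")
    else:
        var = pd.DataFrame(
            {
                "is_mito": [g.startswith(mito_prefix) for g in gene_ids],
                "is_spikein": [g.startswith(spike_prefix) for g in gene_ids],
            },
            index=pd.Index(gene_ids, name="gene"),
        )

    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    if cell_meta is not None:
        meta = pd.read_csv(cell_meta, sep="\t")
        required = {"cell_id", "donor", "sex"}
        if not required <= set(meta.columns):
            raise ParameterError(f"cell metadata must carry columns {sorted(required)}")
        meta = meta.set_index("cell_id")
        missing = set(barcodes) - set(meta.index)
        if missing:
            raise ParameterError(
                f"cell metadata missing {len(missing)} cells, e.g. {sorted(missing)[:3]}"
            )
        obs = meta.reindex(barcodes)
        obs.index.name = "cell_id"
    return ad.AnnData(X=X.astype(np.int32), obs=obs, var=var)


# ----------------------------------------------------------------------- GMT

def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered mapping of set id to gene list."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParameterError(f"{path}:{lineno}: malformed GMT line (needs id, "
                                 f"description and at least one gene)")
        set_id, _desc, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise ParameterError(f"{path}:{lineno}: empty gene set {set_id!r}")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            log.warning("read_gene_sets: %s: duplicate genes de-duplicated", set_id)
        sets[set_id] = deduped
    return sets


def write_gene_sets(sets: dict[str, list[str]], path: str | Path,
                    description: str = "plaquenet") -> None:
    lines = [
        "\t".join([set_id, description, *genes]) for set_id, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------- networks

def read_networks(node_path: str | Path, edge_path: str | Path | None = None
                  ) -> list[GeneNetwork]:
    """Read networks from node + edge TSVs.

    Node TSV columns: ``network_id``, ``gene``, optional ``key_driver_rank``
    (empty for non-drivers), optional ``tissue``. Edge TSV columns:
    ``network_id``, ``src``, ``dst``. Edges referencing unknown nodes raise.
    """
    nodes = pd.read_csv(node_path, sep="\t")
    if not {"network_id", "gene"} <= set(nodes.columns):
        raise ParameterError("node table needs columns network_id and gene")
    edges = (
        pd.read_csv(edge_path, sep="\t") if edge_path is not None
        else pd.DataFrame(columns=["network_id", "src", "dst"])
    )
    networks = []
    for nid, grp in nodes.groupby("network_id", sort=True):
        members = set(grp["gene"].astype(str))
        ranks = {}
        if "key_driver_rank" in grp.columns:
            for _, row in grp.dropna(subset=["key_driver_rank"]).iterrows():
                ranks[str(row["gene"])] = int(row["key_driver_rank"])
        e = edges[edges["network_id"] == nid]
        edge_list = []
        for _, row in e.iterrows():
            s, d = str(row["src"]), str(row["dst"])
            if s not in members or d not in members:
                raise ParameterError(f"{nid}: edge ({s}, {d}) references an unknown node")
            edge_list.append((s, d))
        tissue = str(grp["tissue"].iloc[0]) if "tissue" in grp.columns else "AOR"
        networks.append(GeneNetwork(network_id=str(nid), nodes=frozenset(members),
                                    edges=edge_list, key_driver_rank=ranks, tissue=tissue))
    return networks


def write_networks(networks: list[GeneNetwork], node_path: str | Path,
                   edge_path: str | Path) -> None:
    node_rows, edge_rows = [], []
    for net in networks:
        for g in sorted(net.nodes):
            node_rows.append(
                {"network_id": net.network_id, "gene": g,
                 "key_driver_rank": net.key_driver_rank.get(g, np.nan),
                 "tissue": net.tissue}
            )
        for s, d in net.edges:
            edge_rows.append({"network_id": net.network_id, "src": s, "dst": d})
    pd.DataFrame(node_rows).to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(edge_rows).to_csv(edge_path, sep="\t", index=False)


def networks_from_gmt(path: str | Path) -> list[GeneNetwork]:
    """Membership-only networks (no edges, no drivers) from a GMT file."""
    return [
        GeneNetwork(network_id=set_id, nodes=frozenset(genes))
        for set_id, genes in read_gene_sets(path).items()
    ]


# --------------------------------------------------------------- result tables

def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None,
                index: bool = True) -> None:
    """TSV with a leading ``#key=value`` self-description block."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"#{key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
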