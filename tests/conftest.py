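"""Shared fixtures: one small planted-truth dataset reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plaquenet import pipeline as pl
from plaquenet.simulate import SimParams, simulate_cells, simulate_grns


def small_params(seed: int = 7, **overrides) -> SimParams:
    """A two-type, five-subcluster simulation small enough for unit tests."""
    defaults = dict(
        n_genes=800,
        n_cells=700,
        type_props={"SMC": 0.6, "EC": 0.4},
        subclusters_per_type={"SMC": 3, "EC": 2},
        markers_per_subcluster=20,
        type_markers_per_type=6,
        n_spikein=30,
        n_networks=6,
        network_size=60,
        seed=seed,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


@pytest.fixture(scope="session")
def demo():
    """Simulated counts, truth, networks and normalized matrix with true labels."""
    params = small_params()
    adata, truth = simulate_cells(params)
    networks = simulate_grns(truth, params)
    kept, report = pl.qc_cells(adata)
    kept = pl.qc_genes(kept)
    nm = pl.normalize_log(kept)
    tk = truth.cells.reindex(nm.obs_names)
    labels = pd.DataFrame(
        {"major_type": tk["type"], "subcluster": tk["subcluster"]}, index=nm.obs_names
    )
    return {
        "params": params,
        "adata": adata,
        "truth": truth,
        "networks": networks,
        "nm": nm,
        "labels": labels,
        "qc_report": report,
    }
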