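"""Run configuration: every pipeline default in one serializable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from plaquenet.errors import ParameterError


@dataclass
class RunConfig:
    """All thresholds and defaults of the pipeline plus input/output paths.

    Unknown keys are rejected on load so that typos in configuration files
    fail loudly instead of silently falling back to defaults.
    """

    # paths (inputs optional when the simulate stage provides them)
    counts_path: str | None = None
    cell_meta_path: str | None = None
    network_nodes_path: str | None = None
    network_edges_path: str | None = None
    outdir: str = "plaquenet_run"

    # simulation
    simulate: bool = True
    sim_n_genes: int = 3000
    sim_n_cells: int = 3000

    # QC
    qc_lo: float = 50_000
    qc_hi: float = 750_000
    qc_mito_max: float = 0.10
    qc_spike_max: float = 0.10
    gene_min_cells: int = 3
    gene_min_total: int = 300

    # clustering
    n_hvg: int = 2000
    n_pcs: int = 50
    k_neighbors: int = 20
    resolution: float = 0.8

    # markers
    deg_log2fc: float = 0.3
    deg_p_bonf: float = 0.005

    # integration / validation
    fdr_level: float = 0.10
    assoc_aggregation: str = "minp_sidak"
    n_phenotype_samples: int = 200
    n_perm_preservation: int = 199
    n_perm_gsea: int = 500

    # reproducibility
    seed: int = 0
    threads: int = 1
    log_level: str = "INFO"

    run_preservation: bool = True
    run_perturbation: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"configuration file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
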