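"""Synthetic single-cell, network, phenotype and mouse-progression data with planted truth.

The generator emulates the statistical structure of a deep (Smart-Seq2-depth)
plaque scRNA-seq study: library sizes in the tens-to-hundreds of thousands of
reads, mitochondrial and ERCC spike-in fractions, doublets and debris, major
cell types carrying disjoint subcluster marker programs, per-subcluster
sex-composition probabilities, GRNs with planted marker overlaps and key
drivers, phenotypes driven by latent module factors, and a three-stage mouse
atherosclerosis progression course. Everything is deterministic under the
single ``seed`` in :class:`SimParams`; all planted structure is returned in a
:class:`SimTruth` so downstream recovery can be scored.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd

from plaquenet.errors import ParameterError
from plaquenet.networks import GeneNetwork

# Marker panels used for cell-type annotation; the first genes of each type's
# shared marker program are given these canonical names so that panel-based
# annotation works on simulated data exactly as it does on real data.
DEFAULT_PANELS: dict[str, list[str]] = {
    "SMC": ["MYH11", "ACTA2", "ACTC1"],
    "EC": ["PECAM1", "VWF", "CLDN5"],
    "MP": ["PTPRC", "CD68"],
    "T": ["CD3E"],
    "pericyte": ["PDGFRB", "RGS5"],
}

_MITO_NAMES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]

#: Female-probability pattern cycled over a type's subclusters. Alternates
#: strongly male-biased, strongly female-biased and balanced subclusters so the
#: default run plants both detectable biases and true negatives.
_SEX_PROB_CYCLE = (0.15, 0.85, 0.5, 0.2, 0.8)

_STAGES = ("baseline", "early", "advanced")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from one master seed.

    Salting by stage name makes every randomized stage independently
    reproducible while keeping a single seed in the configuration.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class SimParams:
    """All tunable parameters of the synthetic study.

    Defaults describe the study conditions being emulated: ~15 donors (7
    female, 8 male), five FACS-sorted major cell types dominated by SMCs, MPs
    and ECs, subclusters with disjoint 30-gene marker programs at 4-fold
    elevation, log-normal library sizes with median 200k reads, NB size 2,
    92 ERCC spike-ins, 13 mitochondrial genes and a 12-network GRN collection
    with 5 ranked key drivers each.
    """

    n_genes: int = 3000  # endogenous genes, mitochondrial included
    n_cells: int = 3000
    type_props: Mapping[str, float] = field(
        default_factory=lambda: {
            "SMC": 0.42, "MP": 0.36, "EC": 0.12, "T": 0.06, "pericyte": 0.04,
        }
    )
    subclusters_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"SMC": 5, "MP": 4, "EC": 3, "T": 1, "pericyte": 1}
    )
    markers_per_subcluster: int = 30
    type_markers_per_type: int = 10
    marker_fold: float = 4.0
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    dispersion: float = 2.0  # negative-binomial size theta
    libsize_median: float = 2.0e5
    libsize_log_sd: float = 0.35  # sd on the natural-log scale
    sex_probs: dict[str, float] | None = None  # subcluster id -> P(female)
    n_donors_f: int = 7
    n_donors_m: int = 8
    donor_log_sd: float = 0.1
    doublet_rate: float = 0.03
    debris_rate: float = 0.02
    dead_rate: float = 0.03
    mito_frac_mean: float = 0.04
    spike_frac_mean: float = 0.03
    n_mito_genes: int = 13
    n_spikein: int = 92
    n_networks: int = 12
    network_size: int = 100
    planted_overlap: float = 0.8  # rho
    n_key_drivers: int = 5
    phenotype_betas: dict[str, dict[str, float]] | None = None
    stage_effect: float = 1.0  # per-stage mean increment, units of noise sd
    stage_noise_sd: float = 1.0
    mouse_design: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("baseline", "F"): 2, ("baseline", "M"): 6,
            ("early", "F"): 6, ("early", "M"): 12,
            ("advanced", "F"): 10, ("advanced", "M"): 10,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex_probs is None:
            self.sex_probs = {
                sub: (_SEX_PROB_CYCLE[i % len(_SEX_PROB_CYCLE)] if n > 1 else 0.5)
                for typ, n in self.subclusters_per_type.items()
                for i, sub in enumerate(subcluster_ids(typ, n))
            }
        if self.phenotype_betas is None:
            self.phenotype_betas = {"SYNTAX": {"GRN1": 1.5}, "Duke": {"GRN3": 1.2}, "BMI": {}}
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "n_cells", "markers_per_subcluster", "n_mito_genes",
                     "n_spikein", "n_networks", "network_size", "n_key_drivers",
                     "n_donors_f", "n_donors_m", "type_markers_per_type"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ParameterError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ParameterError("n_cells and n_genes must be positive")
        if self.marker_fold <= 1:
            raise ParameterError(f"marker_fold must exceed 1, got {self.marker_fold}")
        if self.dispersion <= 0:
            raise ParameterError(f"dispersion must be positive, got {self.dispersion}")
        if not 0 <= self.planted_overlap <= 1:
            raise ParameterError(f"planted_overlap must be in [0, 1], got {self.planted_overlap}")
        props = np.array(list(self.type_props.values()), dtype=float)
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-8:
            raise ParameterError("type_props must be nonnegative and sum to 1")
        for rate_name in ("doublet_rate", "debris_rate", "dead_rate",
                          "mito_frac_mean", "spike_frac_mean"):
            r = getattr(self, rate_name)
            if not 0 <= r <= 1:
                raise ParameterError(f"{rate_name} must be in [0, 1], got {r}")
        for sub, p in self.sex_probs.items():
            if not 0 <= p <= 1:
                raise ParameterError(f"sex_probs[{sub!r}] must be in [0, 1], got {p}")
        if set(self.type_props) != set(self.subclusters_per_type):
            raise ParameterError("type_props and subclusters_per_type must list the same types")
        n_marked = sum(self.subclusters_per_type.values()) * self.markers_per_subcluster
        n_marked += len(self.type_props) * self.type_markers_per_type
        if n_marked + self.n_mito_genes > self.n_genes:
            raise ParameterError(
                f"marker programs need {n_marked} genes plus {self.n_mito_genes} "
                f"mitochondrial genes but only {self.n_genes} endogenous genes requested"
            )
        if self.stage_effect < 0:
            raise ParameterError("stage_effect must be nonnegative")
        for stg in _STAGES:
            if not any(k[0] == stg for k in self.mouse_design):
                raise ParameterError(f"mouse_design is missing stage {stg!r}")


def subcluster_ids(cell_type: str, n: int) -> list[str]:
    """Type-prefixed subcluster names, e.g. ``SMC1 .. SMC5``."""
    return [f"{cell_type}{i + 1}" for i in range(n)]


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic data.

    ``cells`` has one row per emitted cell with its true type, subcluster,
    sex, donor and doublet/debris/dead flags. Marker dictionaries map
    subcluster / type to the planted elevated genes. ``networks`` records,
    per GRN, its partner subcluster (or None), member genes and ranked key
    drivers. ``trend_genes`` maps planted progression genes to the sex in
    which they rise.
    """

    cells: pd.DataFrame
    subcluster_markers: dict[str, list[str]]
    type_markers: dict[str, list[str]]
    sex_probs: dict[str, float]
    genes: list[str] = field(default_factory=list)  # endogenous non-mito genes
    networks: dict[str, dict] = field(default_factory=dict)
    phenotype_betas: dict[str, dict[str, float]] = field(default_factory=dict)
    trend_genes: dict[str, str] = field(default_factory=dict)
    stage_effect: float = 0.0
    seed: int = 0

    def biased_subclusters(self, margin: float = 0.3) -> list[str]:
        """Subclusters whose planted female probability differs from 0.5 by >= margin."""
        return [k for k, p in self.sex_probs.items() if abs(p - 0.5) >= margin]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cells": self.cells.to_dict(orient="list"),
            "cell_ids": list(self.cells.index),
            "subcluster_markers": self.subcluster_markers,
            "type_markers": self.type_markers,
            "sex_probs": self.sex_probs,
            "genes": self.genes,
            "networks": self.networks,
            "phenotype_betas": self.phenotype_betas,
            "trend_genes": self.trend_genes,
            "stage_effect": self.stage_effect,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        cells = pd.DataFrame(payload["cells"], index=payload["cell_ids"])
        cells.index.name = "cell_id"
        return cls(
            cells=cells,
            subcluster_markers=payload["subcluster_markers"],
            type_markers=payload["type_markers"],
            sex_probs=payload["sex_probs"],
            genes=list(payload["genes"]),
            networks={k: dict(v) for k, v in payload["networks"].items()},
            phenotype_betas=payload["phenotype_betas"],
            trend_genes=payload["trend_genes"],
            stage_effect=payload["stage_effect"],
            seed=payload["seed"],
        )


@dataclass
class StagedExpression:
    """Normalized expression across an ordered disease-progression course.

    ``expr`` is sample x gene; ``stage`` and ``sex`` align with its rows.
    Stages form the total order baseline < early < advanced.
    """

    expr: pd.DataFrame
    stage: pd.Series
    sex: pd.Series
    stage_order: tuple[str, ...] = _STAGES

    def __post_init__(self) -> None:
        if not self.expr.index.equals(self.stage.index) or not self.expr.index.equals(self.sex.index):
            raise ParameterError("expr, stage and sex must share the same sample index")
        unknown = set(self.stage) - set(self.stage_order)
        if unknown:
            raise ParameterError(f"unknown stage labels: {sorted(unknown)}")

    def stage_index(self) -> pd.Series:
        """Numeric stage coding baseline=0, early=1, advanced=2."""
        mapping = {s: i for i, s in enumerate(self.stage_order)}
        return self.stage.map(mapping)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts with mean ``mean`` and size theta."""
    lam = rng.gamma(shape=size_param, scale=np.maximum(mean, 1e-12) / size_param)
    return rng.poisson(lam)


def simulate_cells(params: SimParams) -> tuple[ad.AnnData, SimTruth]:
    """Draw a raw gene x cell count matrix plus its planted truth.

    Counts are negative binomial with cell mean ``L_c * p_g(c)`` where the
    relative abundances ``p_g`` renormalize log-normal baseline means with the
    cell's type and subcluster marker genes multiplied by ``marker_fold`` and
    a per-donor log-normal factor. Sex is Bernoulli(``sex_probs``) per
    subcluster. Doublets are sums of two profiles with inflated library sizes
    (total >= 750k by construction), debris cells draw library sizes below the
    QC floor, and dead cells have their mitochondrial mass raised to a >= 10%
    fraction. ERCC spike-ins receive a noisy fixed per-cell proportion.
    """
    params.validate()
    rng = np.random.default_rng(stage_seed(params.seed, "cells"))

    types = list(params.type_props)
    n_endo = params.n_genes
    n_mito = params.n_mito_genes

    # --- gene names: endogenous (non-mito), mitochondrial, spike-ins
    mito_names = list(_MITO_NAMES[:n_mito]) + [f"MT-G{i}" for i in range(len(_MITO_NAMES), n_mito)]
    n_plain = n_endo - n_mito
    plain_names = [f"GENE{i:05d}" for i in range(n_plain)]
    spike_names = [f"ERCC-{i:05d}" for i in range(params.n_spikein)]

    # --- marker allocation (disjoint), canonical panel names first per type
    cursor = 0
    type_markers: dict[str, list[str]] = {}
    for typ in types:
        block = plain_names[cursor:cursor + params.type_markers_per_type]
        canon = DEFAULT_PANELS.get(typ, [])[:len(block)]
        for j, name in enumerate(canon):
            plain_names[cursor + j] = name
            block[j] = name
        type_markers[typ] = block
        cursor += params.type_markers_per_type
    sub_markers: dict[str, list[str]] = {}
    for typ in types:
        for sub in subcluster_ids(typ, params.subclusters_per_type[typ]):
            sub_markers[sub] = plain_names[cursor:cursor + params.markers_per_subcluster]
            cursor += params.markers_per_subcluster

    gene_names = plain_names + mito_names
    gene_idx = {g: i for i, g in enumerate(gene_names)}

    # --- baseline relative abundances; mitochondrial mass pinned to its mean share
    lam = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, size=n_endo)
    mito_slice = slice(n_plain, n_endo)
    non_mito_total = lam[:n_plain].sum()
    if n_mito:
        target = params.mito_frac_mean / max(1 - params.mito_frac_mean, 1e-12)
        lam[mito_slice] *= target * non_mito_total / lam[mito_slice].sum()
    spike_lam = rng.lognormal(0.0, 1.0, size=params.n_spikein)
    spike_lam /= spike_lam.sum() if params.n_spikein else 1.0

    # --- cell-level assignments
    n_cells = params.n_cells
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    type_of = rng.choice(types, size=n_cells, p=[params.type_props[t] for t in types])
    sub_of = np.empty(n_cells, dtype=object)
    for typ in types:
        idx = np.flatnonzero(type_of == typ)
        subs = subcluster_ids(typ, params.subclusters_per_type[typ])
        # decreasing subcluster sizes so that id 1 is largest
        w = np.arange(len(subs), 0, -1, dtype=float)
        sub_of[idx] = rng.choice(subs, size=idx.size, p=w / w.sum())
    sex = np.where(
        rng.random(n_cells) < np.array([params.sex_probs[s] for s in sub_of]), "F", "M"
    )
    donors_f = [f"F{i + 1}" for i in range(params.n_donors_f)]
    donors_m = [f"M{i + 1}" for i in range(params.n_donors_m)]
    donor = np.where(
        sex == "F",
        rng.choice(donors_f, size=n_cells) if donors_f else "F1",
        rng.choice(donors_m, size=n_cells) if donors_m else "M1",
    )
    gate_of = {"SMC": "PDGFRB+", "pericyte": "PDGFRB+", "EC": "CD31+/CD144+",
               "MP": "CD45+", "T": "CD45+"}
    gate = np.array([gate_of.get(t, "bulk") for t in type_of])

    # --- QC-failure planting: disjoint doublet / debris / dead subsets
    n_bad = {
        "doublet": int(round(params.doublet_rate * n_cells)),
        "debris": int(round(params.debris_rate * n_cells)),
        "dead": int(round(params.dead_rate * n_cells)),
    }
    flagged = rng.choice(n_cells, size=sum(n_bad.values()), replace=False)
    is_doublet = np.zeros(n_cells, bool)
    is_debris = np.zeros(n_cells, bool)
    is_dead = np.zeros(n_cells, bool)
    a = n_bad["doublet"]
    b = a + n_bad["debris"]
    is_doublet[flagged[:a]] = True
    is_debris[flagged[a:b]] = True
    is_dead[flagged[b:]] = True

    # --- per-donor multiplicative factors on endogenous abundances
    all_donors = donors_f + donors_m
    donor_fac = rng.lognormal(0.0, params.donor_log_sd, size=(len(all_donors), n_endo))
    donor_row = {d: i for i, d in enumerate(all_donors)}

    fold = params.marker_fold
    theta = params.dispersion

    def endo_weights(typ: str, sub: str, dnr: str, dead: bool) -> np.ndarray:
        w = lam * donor_fac[donor_row[dnr]]
        for g in type_markers[typ]:
            w[gene_idx[g]] *= fold
        for g in sub_markers[sub]:
            w[gene_idx[g]] *= fold
        if dead:
            frac = rng.uniform(0.10, 0.30)
            w[mito_slice] *= frac / (1 - frac) * w[:n_plain].sum() / max(w[mito_slice].sum(), 1e-12)
        return w

    # --- library sizes
    log_med = math.log(params.libsize_median)
    libsize = rng.lognormal(log_med, params.libsize_log_sd, size=n_cells)
    libsize[is_debris] = rng.uniform(5e3, 4e4, size=is_debris.sum())

    n_total_genes = n_endo + params.n_spikein
    counts = np.zeros((n_cells, n_total_genes), dtype=np.int64)
    spike_cap = 0.09

    def one_profile(typ, sub, dnr, dead, lsize):
        w = endo_weights(typ, sub, dnr, dead)
        s_frac = min(params.spike_frac_mean * rng.lognormal(0.0, 0.25), spike_cap)
        p = np.concatenate([w / w.sum() * (1 - s_frac), spike_lam * s_frac])
        return _nb_draw(rng, lsize * p, theta)

    for i in range(n_cells):
        if is_doublet[i]:
            # two truncated-high component libraries: the summed profile
            # exceeds the 750k doublet ceiling by construction
            l1, l2 = np.maximum(rng.lognormal(math.log(4.2e5), 0.12, size=2), 4.0e5)
            j = int(rng.integers(n_cells))
            counts[i] = one_profile(type_of[i], sub_of[i], donor[i], False, l1)
            counts[i] += one_profile(type_of[j], sub_of[j], donor[i], False, l2)
        else:
            counts[i] = one_profile(type_of[i], sub_of[i], donor[i], bool(is_dead[i]), libsize[i])

    var = pd.DataFrame(
        {
            "is_mito": [g.startswith("MT-") for g in gene_names + spike_names],
            "is_spikein": [g.startswith("ERCC-") for g in gene_names + spike_names],
        },
        index=gene_names + spike_names,
    )
    var.index.name = "gene"
    obs = pd.DataFrame(
        {"donor": donor, "sex": sex, "gate": gate}, index=pd.Index(cell_ids, name="cell_id")
    )
    adata = ad.AnnData(X=counts.astype(np.int32), obs=obs, var=var)

    truth_cells = pd.DataFrame(
        {
            "type": type_of,
            "subcluster": sub_of.astype(str),
            "sex": sex,
            "donor": donor,
            "is_doublet": is_doublet,
            "is_debris": is_debris,
            "is_dead": is_dead,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    truth = SimTruth(
        cells=truth_cells,
        subcluster_markers=sub_markers,
        type_markers=type_markers,
        sex_probs=dict(params.sex_probs),
        genes=list(plain_names),
        phenotype_betas={k: dict(v) for k, v in params.phenotype_betas.items()},
        stage_effect=params.stage_effect,
        seed=params.seed,
    )
    return adata, truth


def simulate_grns(truth: SimTruth, params: SimParams) -> list[GeneNetwork]:
    """Build a GRN collection with planted subcluster overlaps and key drivers.

    Sex-biased subclusters (planted |pi - 0.5| >= 0.3) are paired with the
    first networks; each paired network receives ``ceil(rho * n_markers)`` of
    its partner's marker genes, topped up with genes drawn at random from the
    remaining endogenous pool (so at rho = 0 the marker overlap is purely
    hypergeometric). Key drivers are the designated top-out-degree hub nodes;
    in a paired network the rank-1 driver is a partner marker gene and is also
    planted as a progression-trend gene for the partner's dominant sex.
    """
    if not truth.subcluster_markers:
        raise ParameterError("truth carries no marker lists")
    rng = np.random.default_rng(stage_seed(params.seed, "grns"))
    rho = params.planted_overlap
    size = params.network_size

    universe = sorted(truth.genes)
    if not universe:
        raise ParameterError("truth carries no gene universe")

    partners = truth.biased_subclusters()
    networks: list[GeneNetwork] = []
    for m in range(params.n_networks):
        net_id = f"GRN{m + 1}"
        partner = partners[m] if m < len(partners) else None
        members: list[str] = []
        if partner is not None:
            markers = truth.subcluster_markers[partner]
            k_in = math.ceil(rho * len(markers))
            if k_in > size:
                raise ParameterError(
                    f"{net_id}: planted overlap {k_in} exceeds network size {size}"
                )
            members = [str(g) for g in rng.choice(markers, size=k_in, replace=False)]
        pool = np.array([g for g in universe if g not in set(members)])
        fill = rng.choice(pool, size=size - len(members), replace=False)
        members = members + [str(g) for g in fill]

        # hub edges: driver ranked r points at size-1-3*(r-1) distinct targets
        drivers: list[str] = []
        if partner is not None and members:
            drivers.append(members[0])  # rank-1 driver is a partner marker
        for g in reversed(members):
            if len(drivers) >= params.n_key_drivers:
                break
            if g not in drivers:
                drivers.append(g)
        edges: list[tuple[str, str]] = []
        others = [g for g in members if g not in set(drivers)]
        for r, drv in enumerate(drivers, start=1):
            n_out = max(len(members) - 1 - 3 * (r - 1), 1)
            targets = rng.choice([g for g in members if g != drv], size=n_out, replace=False)
            edges.extend((drv, t) for t in targets)
        for g in others:
            targets = rng.choice([h for h in members if h != g], size=min(2, len(members) - 1),
                                 replace=False)
            edges.extend((g, t) for t in targets)

        net = GeneNetwork(
            network_id=net_id,
            nodes=frozenset(members),
            edges=edges,
            key_driver_rank={g: r for r, g in enumerate(drivers, start=1)},
            tissue="AOR",
        )
        networks.append(net)
        # per-gene factor loadings give the module a heterogeneous, and hence
        # recognizable, co-expression structure across independent cohorts
        loadings = {g: float(l) for g, l in zip(members, rng.uniform(0.4, 0.95, len(members)))}
        truth.networks[net_id] = {
            "partner": partner,
            "members": members,
            "key_drivers": drivers,
            "loadings": loadings,
        }
        if partner is not None and drivers:
            dominant = "F" if truth.sex_probs[partner] > 0.5 else "M"
            truth.trend_genes[drivers[0]] = dominant
    return networks


def simulate_phenotypes(
    truth: SimTruth, params: SimParams, n_samples: int = 200, salt: str = "phenotypes"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent-factor bulk expression plus phenotypes for GRN association.

    Each network carries a per-sample latent factor; member genes load on it
    with their planted per-gene loadings plus independent noise, and each
    phenotype is a linear combination of the factors given by
    ``phenotype_betas`` plus unit noise. Returns
    ``(phenotypes, bulk_expression)`` as sample x column DataFrames.
    ``salt`` switches the random stream, giving independent cohorts with the
    same planted structure (e.g. a discovery and a test cohort).
    """
    if n_samples < 10:
        raise ParameterError(f"n_samples must be >= 10, got {n_samples}")
    if not truth.networks:
        raise ParameterError("truth carries no networks; run simulate_grns first")
    rng = np.random.default_rng(stage_seed(params.seed, salt))
    net_ids = sorted(truth.networks, key=lambda s: int(s.removeprefix("GRN")))
    factors = pd.DataFrame(
        rng.standard_normal((n_samples, len(net_ids))),
        columns=net_ids,
        index=[f"S{i + 1:03d}" for i in range(n_samples)],
    )

    gene_to_net: dict[str, str] = {}
    for nid in net_ids:
        for g in truth.networks[nid]["members"]:
            gene_to_net.setdefault(g, nid)
    extra = truth.genes[:200] if truth.genes else []
    genes = sorted(set(gene_to_net) | set(extra))
    expr = rng.standard_normal((n_samples, len(genes)))
    for j, g in enumerate(genes):
        nid = gene_to_net.get(g)
        if nid is not None:
            loading = truth.networks[nid].get("loadings", {}).get(g, 0.8)
            resid = math.sqrt(max(1 - loading**2, 0.0))
            expr[:, j] = loading * factors[nid].to_numpy() + resid * expr[:, j]
    bulk = pd.DataFrame(expr, index=factors.index, columns=genes)

    phen = {}
    for pname, betas in truth.phenotype_betas.items():
        y = rng.standard_normal(n_samples)
        for nid, beta in betas.items():
            if nid in factors:
                y = y + beta * factors[nid].to_numpy()
        phen[pname] = y
    phenotypes = pd.DataFrame(phen, index=factors.index)
    return phenotypes, bulk


def simulate_mouse_course(truth: SimTruth, params: SimParams) -> StagedExpression:
    """Three-stage mouse aortic-arch progression course with planted trends.

    The default design follows a chow-fed LDLR-null / apoB100 progression
    study: 8 baseline (2 F, 6 M), 18 early (6 F, 12 M) and 20 advanced
    (10 F, 10 M) animals. Planted trend genes rise by ``stage_effect`` noise
    sds per stage in their target sex only; every other (gene, sex) series is
    flat with i.i.d. Gaussian noise.
    """
    if params.stage_effect < 0:
        raise ParameterError("stage_effect must be nonnegative")
    rng = np.random.default_rng(stage_seed(params.seed, "mouse"))

    rows = []
    for (stg, sx), n in params.mouse_design.items():
        if stg not in _STAGES:
            raise ParameterError(f"unknown stage {stg!r}")
        rows.extend((stg, sx) for _ in range(n))
    stage = pd.Series([r[0] for r in rows])
    sex = pd.Series([r[1] for r in rows])
    index = pd.Index([f"mouse{i + 1:02d}" for i in range(len(rows))], name="sample_id")
    stage.index = index
    sex.index = index

    driver_genes = [g for nd in truth.networks.values() for g in nd["key_drivers"]]
    background = truth.genes[:100] if truth.genes else []
    genes = sorted(set(driver_genes) | set(truth.trend_genes) | set(background))

    stage_idx = stage.map({s: i for i, s in enumerate(_STAGES)}).to_numpy()
    expr = rng.normal(0.0, params.stage_noise_sd, size=(len(rows), len(genes)))
    for j, g in enumerate(genes):
        target = truth.trend_genes.get(g)
        if target is not None:
            mask = (sex == target).to_numpy()
            expr[mask, j] += params.stage_effect * params.stage_noise_sd * stage_idx[mask]
    return StagedExpression(
        expr=pd.DataFrame(expr, index=index, columns=genes), stage=stage, sex=sex
    )


def simulate_perturbation(
    truth: SimTruth,
    params: SimParams,
    network_id: str,
    n_replicates: int = 4,
    knockdown: float = 0.5,
    seed: int | None = None,
) -> dict:
    """Key-driver perturbation experiment for one network.

    Emulates overexpressing/knocking a network's top key driver in cultured
    cells followed by RNA-seq with ``n_replicates`` per condition: under
    ``Mock`` (control) the network's latent factor drives its member genes
    with their planted loadings; under ``perturbed`` the factor is abolished,
    collapsing within-module co-expression, and member genes are additionally
    scaled by ``knockdown`` in the count space.

    Returns a dict with ``expr`` (condition -> sample x gene normalized
    expression for connectivity analysis), ``counts`` (sample x gene raw
    counts) and ``groups`` (sample -> condition) for ranking statistics.
    """
    if network_id not in truth.networks:
        raise ParameterError(f"unknown network {network_id!r}")
    if n_replicates < 3:
        raise ParameterError("need at least 3 replicates per condition")
    rng = np.random.default_rng(
        stage_seed(params.seed, f"perturb-{network_id}") if seed is None else seed
    )
    info = truth.networks[network_id]
    members = list(info["members"])
    loadings = info.get("loadings", {g: 0.8 for g in members})
    background = [g for g in truth.genes[:200] if g not in set(members)]
    genes = members + background

    expr: dict[str, pd.DataFrame] = {}
    base_mean = rng.lognormal(4.0, 1.0, size=len(genes))  # counts scale
    counts_rows, group_rows, sample_ids = [], [], []
    for cond in ("Mock", "perturbed"):
        f = rng.standard_normal(n_replicates)
        E = rng.standard_normal((n_replicates, len(genes)))
        if cond == "Mock":
            for j, g in enumerate(members):
                l = loadings[g]
                E[:, j] = l * f + math.sqrt(max(1 - l**2, 0.0)) * E[:, j]
        idx = [f"{cond}_{r + 1}" for r in range(n_replicates)]
        expr[cond] = pd.DataFrame(E, index=idx, columns=genes)
        mean = np.tile(base_mean, (n_replicates, 1))
        if cond == "perturbed":
            mean[:, : len(members)] *= knockdown
        counts_rows.append(_nb_draw(rng, mean, params.dispersion))
        group_rows.extend([cond] * n_replicates)
        sample_ids.extend(idx)
    counts = pd.DataFrame(np.vstack(counts_rows), index=sample_ids, columns=genes)
    groups = pd.Series(group_rows, index=sample_ids, name="condition")
    return {"expr": expr, "counts": counts, "groups": groups, "module": members}
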