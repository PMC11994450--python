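"""Gene-regulatory-network container.

A GRN here is an *input*: a directed co-expression module inferred elsewhere
from genotype-coupled bulk expression, carried as a node set, a directed edge
list and a hierarchical key-driver ranking (1 = top driver).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from plaquenet.errors import ParameterError


@dataclass
class GeneNetwork:
    """One gene-regulatory network.

    Parameters
    ----------
    network_id
        Unique identifier, e.g. ``"GRN195"``.
    nodes
        Member gene symbols.
    edges
        Directed ``(src, dst)`` pairs; both ends must be members.
    key_driver_rank
        Map gene -> positive integer rank, 1 = top key driver. Ranks are
        unique within a network and drivers are a subset of the nodes.
    tissue
        Tissue label of the network (e.g. ``"AOR"`` for aortic arterial wall).
    """

    network_id: str
    nodes: frozenset[str]
    edges: list[tuple[str, str]] = field(default_factory=list)
    key_driver_rank: dict[str, int] = field(default_factory=dict)
    tissue: str = "AOR"

    def __post_init__(self) -> None:
        self.nodes = frozenset(self.nodes)
        self.validate()

    def validate(self) -> None:
        if not self.nodes:
            raise ParameterError(f"{self.network_id}: empty node set")
        for src, dst in self.edges:
            if src not in self.nodes or dst not in self.nodes:
                raise ParameterError(
                    f"{self.network_id}: edge ({src}, {dst}) references a non-member gene"
                )
        drivers = set(self.key_driver_rank)
        if not drivers <= set(self.nodes):
            missing = sorted(drivers - set(self.nodes))
            raise ParameterError(
                f"{self.network_id}: key drivers not in node set: {missing}"
            )
        ranks = list(self.key_driver_rank.values())
        if any(r < 1 for r in ranks):
            raise ParameterError(f"{self.network_id}: key-driver ranks must be >= 1")
        if len(set(ranks)) != len(ranks):
            raise ParameterError(f"{self.network_id}: duplicate key-driver ranks")

    @property
    def key_drivers(self) -> list[str]:
        """Key-driver genes ordered by rank (best first)."""
        return sorted(self.key_driver_rank, key=self.key_driver_rank.__getitem__)

    def __len__(self) -> int:
        return len(self.nodes)
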