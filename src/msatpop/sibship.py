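"""Extended sibship networks and nested full-sib families.

An extended sibship network is a connected component of the graph whose
edges are within-population dyads classified half-sib or full-sib: if A
shares a parent with B and B shares a parent with C, then A and C belong
to the same network even without a common parent.  Full-sib families are
the connected components of the FS-only subgraph, each nested inside one
network.  Components of size 1 are reported as unrelated singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .relatedness import DyadRelationship

__all__ = [
    "SibshipPartition",
    "build_sibship_graph",
    "extended_networks",
    "network_report",
]


@dataclass
class SibshipPartition:
    """Networks (≥2 members), singletons, and nested FS families."""

    networks: list[set[str]] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)
    fs_families: list[set[str]] = field(default_factory=list)

    def validate(self, individuals: Iterable[str]) -> None:
        individuals = set(individuals)
        covered: set[str] = set()
        for net in self.networks:
            if len(net) < 2:
                raise ValueError("networks must have >= 2 members")
            if covered & net:
                raise ValueError("networks overlap")
            covered |= net
        if covered & set(self.singletons):
            raise ValueError("singleton also in a network")
        covered |= set(self.singletons)
        if covered != individuals:
            raise ValueError("networks + singletons must partition the population")
        for fam in self.fs_families:
            if len(fam) < 2:
                raise ValueError("FS families must have >= 2 members")
            if not any(fam <= net for net in self.networks):
                raise ValueError("FS family not nested in a single network")


def build_sibship_graph(
    dyads: Sequence[DyadRelationship],
    population: str,
    min_confidence: float = 0.95,
) -> list[tuple[str, str, str]]:
    """HS/FS edges for one population, thresholded on classification
    confidence (the winning category's likelihood share)."""
    edges = []
    for d in dyads:
        if d.population != population:
            continue
        if d.ml_category in ("HS", "FS") and d.confidence >= min_confidence:
            edges.append((d.pair[0], d.pair[1], d.ml_category))
    return edges


def extended_networks(
    edges: Sequence[tuple[str, str, str]],
    individuals: Sequence[str],
) -> SibshipPartition:
    """Connected components of the HS∪FS graph, with FS-only subcomponents."""
    g = nx.Graph()
    g.add_nodes_from(individuals)
    fs = nx.Graph()
    fs.add_nodes_from(individuals)
    for a, b, label in edges:
        g.add_edge(a, b)
        if label == "FS":
            fs.add_edge(a, b)
    networks = []
    singletons = []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            networks.append(set(comp))
        else:
            singletons.extend(comp)
    fs_families = [set(c) for c in nx.connected_components(fs) if len(c) >= 2]
    order = {ind: i for i, ind in enumerate(individuals)}
    networks.sort(key=lambda s: min(order[i] for i in s))
    singletons.sort(key=lambda i: order[i])
    fs_families.sort(key=lambda s: min(order[i] for i in s))
    part = SibshipPartition(networks, singletons, fs_families)
    part.validate(individuals)
    return part


def network_report(partition: SibshipPartition) -> str:
    """Plain-text summary: network sizes and FS families in k(m) notation.

    Each network line lists its size and, nested beneath it, the number
    of FS families by family size — ``4(2)`` means four full-sib
    families of two individuals each.
    """
    if not partition.networks:
        return "no family structure\n"
    lines = []
    for net in partition.networks:
        fams = [f for f in partition.fs_families if f <= net]
        size_counts: dict[int, int] = {}
        for f in fams:
            size_counts[len(f)] = size_counts.get(len(f), 0) + 1
        fam_txt = (
            "; ".join(f"{k}({m})" for m, k in sorted(size_counts.items()))
            if size_counts
            else "no FS families"
        )
        lines.append(f"network({len(net)}): {fam_txt}")
    lines.append(f"unrelated: {len(partition.singletons)}")
    return "\n".join(lines) + "\n"
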