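"""Threshold-swept co-expression networks and degree hubs.

Because no single correlation cutoff is canonical, co-expression networks
are built at a grid of thresholds (default |r| >= 0.6, 0.7, 0.8, 0.9; edge
sets are nested by construction). In each network the hubs are the nodes
carrying the top-k largest degrees (ties at the k-th degree included;
isolated nodes never qualify), and a gene is a *consensus* hub when it is
flagged in at least a set fraction of the threshold networks. Up- and
down-regulated genes are analyzed as separate networks and never mixed in
one graph.

A parallel evidence line ranks degrees in the protein-protein interaction
subgraph induced on the differentially expressed genes (top-k with tie
inclusion, default k = 9).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ThresholdNetwork",
    "build_threshold_networks",
    "call_hubs_per_network",
    "consensus_hubs",
    "ppi_degree_hubs",
]

DEFAULT_THRESHOLDS = (0.6, 0.7, 0.8, 0.9)


@dataclass
class ThresholdNetwork:
    """Co-expression graph at one |r| cutoff."""

    threshold: float
    nodes: list[str]
    edges: list[tuple[str, str]]

    @property
    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


def build_threshold_networks(
    corr: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    absolute: bool = True,
) -> list[ThresholdNetwork]:
    """One network per threshold; edge iff |r| >= t (or r >= t if signed)."""
    if corr.shape[0] == 0:
        raise ValueError("empty correlation matrix")
    if list(corr.index) != list(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    nodes = list(corr.index)
    values = corr.to_numpy(float)
    strength = np.abs(values) if absolute else values
    nets = []
    for t in thresholds:
        edges = []
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if strength[i, j] >= t:
                    edges.append((nodes[i], nodes[j]))
        nets.append(ThresholdNetwork(threshold=float(t), nodes=nodes, edges=edges))
    return nets


def call_hubs_per_network(net: ThresholdNetwork, top_k: int = 5) -> dict[str, bool]:
    """Hub indicator per node: top-k largest degrees, ties included,
    isolated nodes never hubs."""
    if not net.nodes:
        raise ValueError("network has no nodes")
    degree = net.degree
    positive = sorted((d for d in degree.values() if d > 0), reverse=True)
    if not positive:
        warnings.warn(
            f"all nodes isolated at threshold {net.threshold}; no hubs",
            stacklevel=2,
        )
        return {n: False for n in net.nodes}
    kth = positive[min(top_k, len(positive)) - 1]
    return {n: degree[n] >= kth and degree[n] > 0 for n in net.nodes}


def consensus_hubs(
    nets: Sequence[ThresholdNetwork],
    consensus_fraction: float = 0.5,
    top_k: int = 5,
) -> pd.DataFrame:
    """Frequency-based consensus over the threshold sweep.

    Returns one row per node with the per-threshold hub indicator columns
    (``hub@<t>``), the hub ``frequency`` (mean of indicators) and the
    ``consensus`` flag (frequency >= consensus_fraction).
    """
    if not nets:
        raise ValueError("need at least one network")
    nodes = nets[0].nodes
    report = pd.DataFrame(index=pd.Index(nodes, name="gene"))
    indicators = []
    for net in nets:
        hubs = call_hubs_per_network(net, top_k=top_k)
        col = pd.Series(hubs, name=f"hub@{net.threshold:g}")
        report[col.name] = col
        indicators.append(col)
    freq = pd.concat(indicators, axis=1).mean(axis=1)
    report["frequency"] = freq
    report["consensus"] = freq >= consensus_fraction
    return report


def ppi_degree_hubs(
    edges: pd.DataFrame,
    restrict_to: Iterable[str],
    top_k: int = 9,
) -> pd.DataFrame:
    """Degree ranking in the PPI subgraph induced on ``restrict_to``.

    Returns one row per restricted gene with ``ppi_degree`` and ``ppi_hub``
    (top-k degrees with tie inclusion). An empty induced subgraph yields an
    all-False report with a warning.
    """
    restrict = list(dict.fromkeys(restrict_to))
    graph = nx.Graph()
    graph.add_nodes_from(restrict)
    for _, row in edges.iterrows():
        if row["gene_a"] in graph and row["gene_b"] in graph:
            graph.add_edge(row["gene_a"], row["gene_b"])
    degree = dict(graph.degree())
    report = pd.DataFrame(
        {"ppi_degree": [degree.get(g, 0) for g in restrict]},
        index=pd.Index(restrict, name="gene"),
    )
    positive = sorted((d for d in report["ppi_degree"] if d > 0), reverse=True)
    if not positive:
        warnings.warn("induced PPI subgraph has no edges; no hubs", stacklevel=2)
        report["ppi_hub"] = False
        return report
    kth = positive[min(top_k, len(positive)) - 1]
    report["ppi_hub"] = (report["ppi_degree"] >= kth) & (report["ppi_degree"] > 0)
    return report
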