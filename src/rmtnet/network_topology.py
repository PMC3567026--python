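"""Thresholded edge lists and the topology metrics of the robustness study.

A :class:`Network` is an undirected weighted edge list: every similarity
entry at or above the threshold becomes an edge carrying the signed
correlation, endpoints canonically ordered (lexicographically smaller gene
first), and genes without any edge are excluded, so every node has degree
at least 1. Edge identity ignores the weight — two replicate networks share
an edge when they connect the same unordered gene pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import DegenerateDegrees, EmptyNetwork, InvalidParameter
from .similarity import SimilarityMatrix


@dataclass
class Network:
    """Undirected network as a canonical edge map ``(a, b) -> weight``."""

    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a >= b:
                raise InvalidParameter(f"edge ({a!r}, {b!r}) is not canonically ordered")

    @property
    def nodes(self) -> set[str]:
        return {v for e in self.edges for v in e}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def degrees(self) -> dict[str, int]:
        d: dict[str, int] = {}
        for a, b in self.edges:
            d[a] = d.get(a, 0) + 1
            d[b] = d.get(b, 0) + 1
        return d

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    clustering_coefficient: float
    gamma: float | None


def extract_network(sm: SimilarityMatrix, t: float) -> Network:
    """Edge list of every gene pair with \\|corr\\| >= t (signed weights)."""
    if not 0.0 < t <= 1.0:
        raise InvalidParameter(f"threshold must lie in (0, 1], got {t}")
    A = sm.corr
    iu, ju = np.triu_indices(sm.n_genes, 1)
    hit = np.abs(A[iu, ju]) >= t
    edges: dict[tuple[str, str], float] = {}
    for i, j in zip(iu[hit], ju[hit]):
        a, b = sm.gene_ids[i], sm.gene_ids[j]
        if b < a:
            a, b = b, a
        edges[(a, b)] = float(A[i, j])
    return Network(edges)


def shared_nodes(a: Network, b: Network) -> int:
    return len(a.nodes & b.nodes)


def shared_edges(a: Network, b: Network) -> int:
    return len(a.edge_set() & b.edge_set())


def clustering_coefficient(net: Network) -> float:
    """Average local (Watts-Strogatz) clustering; degree-<2 nodes count as 0."""
    if net.n_nodes == 0:
        raise EmptyNetwork("clustering coefficient of an empty network")
    return float(nx.average_clustering(net.to_networkx(), count_zeros=True))


def fit_powerlaw_gamma(degrees, k_min: int = 1) -> float:
    """Continuous maximum-likelihood exponent of P(k) = c k^-gamma.

    Uses the standard continuous approximation for discrete data,
    ``gamma = 1 + n / sum(ln(k_i / (k_min - 0.5)))`` over degrees >= k_min.
    """
    if k_min < 1:
        raise InvalidParameter(f"k_min must be >= 1, got {k_min}")
    ks = np.asarray([k for k in degrees if k >= k_min], dtype=float)
    if ks.size < 10:
        raise InvalidParameter(
            f"need at least 10 degrees >= k_min={k_min}, got {ks.size}"
        )
    if np.all(ks == k_min):
        raise DegenerateDegrees(f"all degrees equal k_min={k_min}")
    return float(1.0 + ks.size / np.log(ks / (k_min - 0.5)).sum())


def topology_summary(net: Network) -> TopologySummary:
    """Node/edge counts, average degree, clustering, and the degree exponent.

    ``gamma`` is ``None`` when the maximum-likelihood fit is undefined
    (too few or degenerate degrees), as happens for tiny networks.
    """
    if net.n_nodes == 0:
        raise EmptyNetwork("summary of an empty network")
    degs = list(net.degrees().values())
    try:
        gamma = fit_powerlaw_gamma(degs)
    except (InvalidParameter, DegenerateDegrees):
        gamma = None
    return TopologySummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        avg_degree=2.0 * net.n_edges / net.n_nodes,
        clustering_coefficient=clustering_coefficient(net),
        gamma=gamma,
    )


def write_edge_list(net: Network, path) -> None:
    """3-column TSV ``gene_a<TAB>gene_b<TAB>correlation`` sorted by endpoints."""
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), w in sorted(net.edges.items()):
            fh.write(f"{a}\t{b}\t{w:.6f}\n")


def read_edge_list(path) -> Network:
    edges: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            a, b, w = ln.split("\t")
            if b < a:
                a, b = b, a
            edges[(a, b)] = float(w)
    return Network(edges)
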