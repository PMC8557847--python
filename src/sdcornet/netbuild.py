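"""Unweighted networks from correlation matrices.

A correlation matrix C is turned into a simple graph by the hard-threshold
rule: genes i != j are connected iff C[i, j] >= theta.  The full gene set is
always kept as the node set, so isolated genes survive every operation and
networks built at different thresholds are directly comparable.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

__all__ = [
    "UnweightedNetwork",
    "TopologySummary",
    "threshold_network",
    "edge_density",
    "threshold_for_density",
    "topology_summary",
]


@dataclass
class UnweightedNetwork:
    """Simple undirected graph over a fixed, ordered gene set.

    Edges are stored as index pairs ``(i, j)`` with ``i < j`` into
    ``node_ids``; no self-loops, no duplicates.  ``provenance`` records how
    the network was built (correlation method, threshold, ...).
    """

    node_ids: list[str]
    edges: set[tuple[int, int]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_ids = list(map(str, self.node_ids))
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node IDs")
        m = len(self.node_ids)
        clean: set[tuple[int, int]] = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node index {i}")
            if not (0 <= i < m and 0 <= j < m):
                raise ValueError(f"edge ({i}, {j}) outside node range")
            clean.add((i, j) if i < j else (j, i))
        self.edges = clean

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_ids(self) -> Iterator[tuple[str, str]]:
        """Yield edges as unordered ID pairs, lexicographically smaller first."""
        for i, j in self.edges:
            a, b = self.node_ids[i], self.node_ids[j]
            yield (a, b) if a <= b else (b, a)

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=float)
        for i, j in self.edges:
            d[i] += 1.0
            d[j] += 1.0
        return d

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from((self.node_ids[i], self.node_ids[j]) for i, j in self.edges)
        return g

    @classmethod
    def from_id_pairs(
        cls,
        node_ids: Iterable[str],
        pairs: Iterable[tuple[str, str]],
        provenance: dict | None = None,
    ) -> "UnweightedNetwork":
        node_ids = list(node_ids)
        index = {g: k for k, g in enumerate(node_ids)}
        edges = set()
        for a, b in pairs:
            try:
                i, j = index[str(a)], index[str(b)]
            except KeyError as exc:
                raise ValueError(f"edge endpoint {exc.args[0]!r} not in node set") from None
            edges.add((i, j) if i < j else (j, i))
        return cls(node_ids, edges, provenance or {})


@dataclass(frozen=True)
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    lcc_n_vertices: int
    lcc_density: float
    lcc_global_clustering: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "lcc_n_vertices": self.lcc_n_vertices,
            "lcc_density": self.lcc_density,
            "lcc_global_clustering": self.lcc_global_clustering,
        }


def _upper_values(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = values.shape[0]
    r, c = np.triu_indices(m, k=1)
    return values[r, c], r, c


def threshold_network(C, theta: float) -> UnweightedNetwork:
    """Edge (i, j) iff C[i, j] >= theta; the diagonal is ignored.

    ``C`` is a :class:`~sdcornet.correlations.CorrelationMatrix` (anything
    with ``values`` and ``gene_ids``).
    """
    vals, r, c = _upper_values(np.asarray(C.values, dtype=float))
    sel = vals >= theta
    edges = set(zip(r[sel].tolist(), c[sel].tolist()))
    prov = {"method": getattr(C, "method", None), "theta": float(theta)}
    return UnweightedNetwork(list(C.gene_ids), edges, prov)


def edge_density(net: UnweightedNetwork) -> float:
    m = net.n_nodes
    if m < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return net.n_edges / (m * (m - 1) / 2)


def threshold_for_density(C, target_density: float) -> tuple[float, float]:
    """Smallest threshold whose edge count reaches ``target_density``.

    Returns ``(theta, achieved_density)``.  All pairs tied at the cutoff
    value are included, so heavily tied matrices (mutual information) can
    overshoot the target; the overshoot is reported via ``achieved_density``
    and a warning.
    """
    if not (0 < target_density <= 1):
        raise ValueError("target_density must be in (0, 1]")
    vals, _, _ = _upper_values(np.asarray(C.values, dtype=float))
    npairs = vals.size
    k = min(npairs, max(1, math.ceil(target_density * npairs)))
    order = np.sort(vals)[::-1]
    theta = float(order[k - 1])
    achieved_count = int(np.count_nonzero(vals >= theta))
    if achieved_count > k:
        warnings.warn(
            f"ties at threshold {theta:.6g}: {achieved_count} edges instead of "
            f"the {k} requested",
            RuntimeWarning,
            stacklevel=2,
        )
    return theta, achieved_count / npairs


def topology_summary(net: UnweightedNetwork) -> TopologySummary:
    """Edge count/density plus size, density and transitivity of the LCC.

    The global clustering coefficient is transitivity: three times the
    triangle count over the number of connected triples, computed on the
    largest connected component.
    """
    g = net.to_networkx()
    m = net.n_nodes
    density = net.n_edges / (m * (m - 1) / 2) if m >= 2 else 0.0
    if m == 0:
        return TopologySummary(0, 0, 0.0, 0, 0.0, 0.0)
    lcc_nodes = max(nx.connected_components(g), key=len)
    lcc = g.subgraph(lcc_nodes)
    ln = lcc.number_of_nodes()
    lcc_density = (
        lcc.number_of_edges() / (ln * (ln - 1) / 2) if ln >= 2 else 0.0
    )
    clustering = nx.transitivity(lcc) if ln >= 3 else 0.0
    return TopologySummary(m, net.n_edges, density, ln, lcc_density, clustering)
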