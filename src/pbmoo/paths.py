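"""Minimum-cost ligand→signature paths on the bridge.

The objective over the indicator vector x of bridge proteins is

    f(x) = Σ x_i · DES_i + λ Σ x_i,   2 ≤ Σ x_i ≤ 7,

i.e. the sum of node DES costs plus a length penalty; λ = 0 lets paths
freely recruit proteins, larger λ favours short connections.  Solutions
are found by a best-first search over simple-path states ordered by
(cost, length, lexicographic node sequence).  Node costs are
non-negative, so the key is monotone along extensions and source→target
states pop in globally sorted order — the k lowest-cost loopless paths
fall out of the same search.  Orphan genes with no recorded interaction
(such as the signature) are attached through expression-correlation
pseudo-edges before searching.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .bridge import Bridge
from .expression import DESTable, dataset_correlation
from .graph_io import ExpressionDataset

__all__ = [
    "NoFeasiblePathError",
    "PathSolution",
    "PseudoEdge",
    "path_cost",
    "min_cost_path",
    "k_min_cost_paths",
    "attach_orphan",
]

L_MIN_DEFAULT = 2
L_MAX_DEFAULT = 7

NODE_SUM = "node-sum"
EDGE_SUM = "edge-sum"


class NoFeasiblePathError(ValueError):
    """No simple source→target path exists within the length bounds."""


@dataclass(frozen=True)
class PathSolution:
    """An ordered protein path with its objective value."""

    nodes: tuple[str, ...]
    cost: float
    lam: float

    @property
    def length(self) -> int:
        return len(self.nodes)

    def indicator(self, node_order) -> np.ndarray:
        """x over the given bridge-protein ordering (x_i = 1 iff on path)."""
        on = set(self.nodes)
        return np.array([1 if v in on else 0 for v in node_order], dtype=int)

    @property
    def sort_key(self) -> tuple:
        return (self.cost, self.length, self.nodes)


@dataclass(frozen=True)
class PseudoEdge:
    """Correlation-inferred link for a gene with no recorded interaction."""

    orphan: str
    partner: str
    r: float
    provenance: str = "correlation"


def path_cost(nodes, des: DESTable, lam: float = 0.0,
              form: str = NODE_SUM) -> float:
    """Objective value of a node sequence.

    ``node-sum`` (canonical): Σ DES(v) + λ·|nodes|.  ``edge-sum`` instead
    sums DES(u)+DES(v) over consecutive pairs (double-counting interior
    nodes) plus the same λ term; it is kept for comparability with the
    edge-cost reading of the objective.
    """
    nodes = tuple(nodes)
    if not nodes:
        raise ValueError("path is empty")
    if len(set(nodes)) != len(nodes):
        raise ValueError("path repeats a node")
    lam_term = lam * len(nodes)
    if form == NODE_SUM:
        return sum(des.des(v) for v in nodes) + lam_term
    if form == EDGE_SUM:
        return sum(des.des(u) + des.des(v)
                   for u, v in zip(nodes, nodes[1:])) + lam_term
    raise ValueError(f"unknown cost form {form!r}")


def _iter_best_paths(graph: nx.Graph, des: DESTable, source: str,
                     target: str, lam: float, l_min: int, l_max: int,
                     form: str = NODE_SUM, banned=frozenset()):
    """Yield simple source→target paths in (cost, length, lex) order.

    Best-first search on path states; node entry costs DES(v) + λ (plus
    DES(prev) again in edge-sum form) are non-negative, so child keys
    never sort before their parent and popped targets are globally
    ordered.
    """
    if source not in graph or target not in graph:
        raise NoFeasiblePathError(
            f"source {source!r} or target {target!r} not in graph")
    if source == target:
        raise ValueError("source and target must differ")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not (1 <= l_min <= l_max):
        raise ValueError("need 1 <= l_min <= l_max")
    if source in banned or target in banned:
        return
    start_cost = (lam if form == EDGE_SUM else des.des(source) + lam)
    heap = [(start_cost, 1, (source,))]
    while heap:
        cost, length, nodes = heapq.heappop(heap)
        head = nodes[-1]
        if head == target:
            if length >= l_min:
                yield PathSolution(nodes=nodes, cost=cost, lam=lam)
            continue
        if length == l_max:
            continue
        on_path = set(nodes)
        for nxt in graph[head]:
            if nxt in on_path or nxt in banned:
                continue
            step = des.des(nxt) + lam
            if form == EDGE_SUM:
                step += des.des(head)
            heapq.heappush(heap, (cost + step, length + 1, nodes + (nxt,)))


def min_cost_path(graph: nx.Graph, des: DESTable, source: str, target: str,
                  lam: float = 0.0, l_min: int = L_MIN_DEFAULT,
                  l_max: int = L_MAX_DEFAULT,
                  form: str = NODE_SUM) -> PathSolution:
    """Global minimum of f(x) over simple source→target paths with
    l_min ≤ node count ≤ l_max; ties break toward shorter, then
    lexicographically smaller, paths."""
    for sol in _iter_best_paths(graph, des, source, target, lam, l_min,
                                l_max, form=form):
        return sol
    raise NoFeasiblePathError(
        f"no path from {source!r} to {target!r} within {l_max} proteins")


def k_min_cost_paths(graph: nx.Graph, des: DESTable, source: str,
                     target: str, k: int, lam: float = 0.0,
                     l_min: int = L_MIN_DEFAULT, l_max: int = L_MAX_DEFAULT,
                     form: str = NODE_SUM) -> list[PathSolution]:
    """The k lowest-cost distinct simple paths (costs non-decreasing);
    fewer are returned when fewer exist."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out = []
    for sol in _iter_best_paths(graph, des, source, target, lam, l_min,
                                l_max, form=form):
        out.append(sol)
        if len(out) == k:
            break
    if not out:
        raise NoFeasiblePathError(
            f"no path from {source!r} to {target!r} within {l_max} proteins")
    return out


def attach_orphan(bridge: Bridge, orphan: str,
                  datasets: list[ExpressionDataset],
                  r_threshold: float = 0.6, max_partners: int = 10
                  ) -> tuple[nx.Graph, list[PseudoEdge]]:
    """Attach an interaction-less gene to the bridge by co-expression.

    Pseudo-edges run from the orphan to the up-to ``max_partners`` bridge
    proteins with the highest |Pearson r| ≥ ``r_threshold`` (r averaged
    over the datasets measuring both genes).  Real edges are untouched.
    """
    if bridge.subnetwork.number_of_nodes() == 0:
        raise ValueError("bridge is empty")
    if orphan in bridge.subnetwork and bridge.subnetwork.degree(orphan) > 0:
        raise ValueError(
            f"{orphan!r} already has network interactions; use those")
    if not any(orphan in ds for ds in datasets):
        raise ValueError(f"{orphan!r} is not measured in any dataset")
    scored = []
    for node in sorted(bridge.subnetwork.nodes()):
        if node == orphan:
            continue
        rec = dataset_correlation(datasets, orphan, node)
        if rec is not None and abs(rec.r) >= r_threshold:
            scored.append((abs(rec.r), node, rec.r))
    if not scored:
        raise ValueError(
            f"no bridge protein correlates with {orphan!r} at "
            f"|r| >= {r_threshold}; consider lowering r_threshold")
    scored.sort(key=lambda t: (-t[0], t[1]))
    augmented = bridge.subnetwork.copy()
    pseudo = []
    for _, node, r in scored[:max_partners]:
        augmented.add_edge(orphan, node, pseudo=True, r=r)
        pseudo.append(PseudoEdge(orphan=orphan, partner=node, r=r))
    return augmented, pseudo
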