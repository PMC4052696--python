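"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations that share no code path with the
package: subgraph classification by degree sequence, censuses by
all-subsets enumeration, path optima by exhaustive simple-path listing,
enrichment nulls by exhaustive (S1, S2) enumeration, and t-test P-values
by direct numeric integration of the t density.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy.integrate import quad

# (k, n_edges, sorted degree sequence) uniquely identifies each connected
# class on 3 or 4 vertices
SHAPE_BY_DEGREES = {
    (3, (1, 1, 2)): "path3",
    (3, (2, 2, 2)): "triangle",
    (4, (1, 1, 1, 3)): "star",
    (4, (1, 1, 2, 2)): "path4",
    (4, (1, 2, 2, 3)): "triangle-tail",
    (4, (2, 2, 2, 2)): "square",
    (4, (2, 2, 3, 3)): "diamond",
    (4, (3, 3, 3, 3)): "clique4",
}


def classify_subset(graph: nx.Graph, nodes) -> str | None:
    """Shape name of the induced subgraph, or None if disconnected."""
    sub = graph.subgraph(nodes)
    if not nx.is_connected(sub):
        return None
    degs = tuple(sorted(d for _, d in sub.degree()))
    return SHAPE_BY_DEGREES[(len(nodes), degs)]


def brute_census_counts(graph: nx.Graph, k: int) -> dict[str, int]:
    """Per-shape counts by brute force over all C(n, k) vertex subsets."""
    counts = {name: 0 for (kk, _), name in SHAPE_BY_DEGREES.items()
              if kk == k}
    for subset in itertools.combinations(sorted(graph.nodes()), k):
        name = classify_subset(graph, subset)
        if name is not None:
            counts[name] += 1
    return counts


def brute_cycles(graph: nx.Graph) -> tuple[int, int]:
    """(#triangles, #distinct 4-cycles) by checking every vertex subset."""
    nodes = sorted(graph.nodes())
    n_tri = sum(
        1 for s in itertools.combinations(nodes, 3)
        if all(graph.has_edge(a, b) for a, b in itertools.combinations(s, 2))
    )
    n_sq = 0
    for s in itertools.combinations(nodes, 4):
        seen = set()
        for perm in itertools.permutations(s):
            if perm[0] != min(perm):
                continue
            ring = list(zip(perm, perm[1:] + perm[:1]))
            if all(graph.has_edge(a, b) for a, b in ring):
                seen.add(frozenset(frozenset(e) for e in ring))
        n_sq += len(seen)
    return n_tri, n_sq


def all_paths_sorted(graph: nx.Graph, des, source, target, lam=0.0,
                     l_min=2, l_max=7):
    """Every simple source→target path with l_min<=nodes<=l_max, sorted by
    (cost, length, node sequence).  Returns (cost, nodes) tuples."""
    out = []
    for nodes in nx.all_simple_paths(graph, source, target, cutoff=l_max - 1):
        if len(nodes) < l_min:
            continue
        cost = sum(des.des(v) for v in nodes) + lam * len(nodes)
        out.append((cost, len(nodes), tuple(nodes)))
    out.sort()
    return [(c, nodes) for c, _, nodes in out]


def exact_enrichment_null(universe, cluster_members, n1, n2, s):
    """Exact distribution of the bridging count n' over all (S1, S2) with
    |S1|=n1, |S2|=n2, |S1∩S2|=s, as {n': probability}."""
    universe = sorted(universe)
    dist: dict[int, int] = {}
    total = 0
    for shared in itertools.combinations(universe, s):
        rest1 = [u for u in universe if u not in shared]
        for extra1 in itertools.combinations(rest1, n1 - s):
            s1 = set(shared) | set(extra1)
            rest2 = [u for u in rest1 if u not in s1]
            for extra2 in itertools.combinations(rest2, n2 - s):
                s2 = set(shared) | set(extra2)
                nprime = sum(bool(m & s1) and bool(m & s2)
                             for m in cluster_members)
                dist[nprime] = dist.get(nprime, 0) + 1
                total += 1
    return {k: v / total for k, v in dist.items()}


def t_p_by_integration(x, y) -> float:
    """Two-sided equal-variance t-test P-value from first principles:
    hand-computed statistic and numeric integration of the t density."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx_, ny = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (
        nx_ + ny - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx_ + 1 / ny))
    df = nx_ + ny - 2

    def pdf(u):
        return (math.gamma((df + 1) / 2)
                / (math.sqrt(df * math.pi) * math.gamma(df / 2))
                * (1 + u * u / df) ** (-(df + 1) / 2))

    tail, _ = quad(pdf, abs(t), math.inf)
    return 2 * tail
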