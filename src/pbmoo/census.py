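"""Connected 3- and 4-vertex subgraph census with a randomized-network null.

Undirected network motifs: each connected induced k-subgraph is assigned a
permutation-invariant canonical class (minimum over vertex relabelings of
the upper-triangle adjacency bitstring).  Enumeration is exact (ESU) or
probabilistic (RAND-ESU, per-depth retention probabilities with inverse
inclusion-probability weighting).  Significance per class comes from
degree-preserving double-edge-swap randomizations: frequency, mean and sd
of the randomized frequency, Z-score, and the one-sided empirical P-value
(fraction of randomized networks whose class count reaches the original's).
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "CanonicalClass",
    "ClassStats",
    "MotifCensusResult",
    "canonical_class",
    "connected_classes",
    "loop_motif_classes",
    "enumerate_connected_subgraphs",
    "sample_subgraphs",
    "randomize",
    "census",
]


@dataclass(frozen=True, order=True)
class CanonicalClass:
    """A connected undirected k-vertex subgraph shape (k in {3, 4})."""

    k: int
    canon_id: int
    is_loop: bool
    name: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name or self.canon_id}(k={self.k})"


# Human names for the 2 connected 3-vertex and 6 connected 4-vertex shapes,
# keyed by (k, number of edges, max degree) which separates them all.
_SHAPE_NAMES = {
    (3, 2, 2): "path3",
    (3, 3, 2): "triangle",
    (4, 3, 3): "star",
    (4, 3, 2): "path4",
    (4, 4, 3): "triangle-tail",
    (4, 4, 2): "square",
    (4, 5, 3): "diamond",
    (4, 6, 3): "clique4",
}

# edge index order for the upper-triangle bitstring, row-major
_PAIRS = {k: list(itertools.combinations(range(k), 2)) for k in (3, 4)}
_PERMS = {k: list(itertools.permutations(range(k))) for k in (3, 4)}


def _mask_of_edges(k: int, edges: set[tuple[int, int]]) -> int:
    mask = 0
    for bit, (i, j) in enumerate(_PAIRS[k]):
        if (i, j) in edges or (j, i) in edges:
            mask |= 1 << bit
    return mask


def _canonical_id_of_mask(k: int, mask: int) -> int:
    pairs = _PAIRS[k]
    adj = {(i, j) for bit, (i, j) in enumerate(pairs) if mask >> bit & 1}
    best = None
    for perm in _PERMS[k]:
        m = 0
        for bit, (i, j) in enumerate(pairs):
            a, b = perm[i], perm[j]
            if (min(a, b), max(a, b)) in adj:
                m |= 1 << bit
        if best is None or m < best:
            best = m
    return best


def _connected_mask(k: int, mask: int) -> bool:
    adj = [[] for _ in range(k)]
    for bit, (i, j) in enumerate(_PAIRS[k]):
        if mask >> bit & 1:
            adj[i].append(j)
            adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for u in adj[stack.pop()]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == k


def _build_tables() -> tuple[dict[int, dict[int, CanonicalClass]],
                             dict[tuple[int, int], CanonicalClass]]:
    """Lookup tables: mask -> class (per k), and (k, canon_id) -> class."""
    by_mask: dict[int, dict[int, CanonicalClass]] = {3: {}, 4: {}}
    by_id: dict[tuple[int, int], CanonicalClass] = {}
    for k in (3, 4):
        for mask in range(1 << len(_PAIRS[k])):
            if not _connected_mask(k, mask):
                continue
            cid = _canonical_id_of_mask(k, mask)
            key = (k, cid)
            if key not in by_id:
                n_edges = bin(cid).count("1")
                deg = [0] * k
                for bit, (i, j) in enumerate(_PAIRS[k]):
                    if cid >> bit & 1:
                        deg[i] += 1
                        deg[j] += 1
                name = _SHAPE_NAMES[(k, n_edges, max(deg))]
                is_loop = n_edges == k and max(deg) == 2
                by_id[key] = CanonicalClass(k=k, canon_id=cid,
                                            is_loop=is_loop, name=name)
            by_mask[k][mask] = by_id[key]
    return by_mask, by_id


_CLASS_BY_MASK, _CLASS_BY_ID = _build_tables()


def connected_classes(k: int) -> list[CanonicalClass]:
    """All connected k-vertex shapes (2 for k=3, 6 for k=4), sorted."""
    _check_k(k)
    return sorted(c for (kk, _), c in _CLASS_BY_ID.items() if kk == k)


def loop_motif_classes() -> set[CanonicalClass]:
    """The loop-shaped motif classes on <=4 vertices: triangle and square."""
    return {c for c in _CLASS_BY_ID.values() if c.is_loop}


def _check_k(k: int) -> None:
    if k not in (3, 4):
        raise ValueError(f"k must be 3 or 4, got {k}")


def canonical_class(adjacency) -> CanonicalClass:
    """Classify a k x k 0/1 adjacency matrix (k in {3,4}) up to relabeling.

    Raises ``ValueError`` for non-symmetric input, nonzero diagonal, or a
    disconnected induced graph.
    """
    adj = np.asarray(adjacency, dtype=int)
    k = adj.shape[0]
    _check_k(k)
    if adj.shape != (k, k) or not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be square and symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    mask = _mask_of_edges(k, {(i, j) for i, j in _PAIRS[k] if adj[i, j]})
    cls = _CLASS_BY_MASK[k].get(mask)
    if cls is None:
        raise ValueError("induced graph is disconnected")
    return cls


def _subgraph_class(graph: nx.Graph, nodes: tuple) -> CanonicalClass:
    k = len(nodes)
    edges = {
        (i, j)
        for i, j in _PAIRS[k]
        if graph.has_edge(nodes[i], nodes[j])
    }
    return _CLASS_BY_MASK[k][_mask_of_edges(k, edges)]


def _esu(graph: nx.Graph, k: int):
    """Yield every connected induced k-subgraph exactly once (ESU).

    Nodes are visited in a fixed integer order; extensions are restricted
    to exclusive neighbours with larger order, which guarantees uniqueness.
    """
    order = {v: i for i, v in enumerate(sorted(graph.nodes()))}
    for v in sorted(graph.nodes(), key=order.__getitem__):
        ext = {u for u in graph[v] if order[u] > order[v]}
        yield from _extend(graph, order, v, [v], ext, k)


def _extend(graph, order, root, sub, extension, k):
    if len(sub) == k:
        yield tuple(sub)
        return
    ext = sorted(extension, key=order.__getitem__)
    while ext:
        w = ext.pop(0)
        # exclusive neighbourhood: neighbours of w not adjacent to sub
        new_ext = set(ext)
        sub_and_nbrs = set(sub)
        for s in sub:
            sub_and_nbrs.update(graph[s])
        for u in graph[w]:
            if order[u] > order[root] and u not in sub_and_nbrs:
                new_ext.add(u)
        yield from _extend(graph, order, root, sub + [w], new_ext, k)


def enumerate_connected_subgraphs(graph: nx.Graph, k: int
                                  ) -> dict[CanonicalClass, int]:
    """Exact per-class counts of connected induced k-subgraphs."""
    _check_k(k)
    counts = {cls: 0 for cls in connected_classes(k)}
    for nodes in _esu(graph, k):
        counts[_subgraph_class(graph, nodes)] += 1
    return counts


def sample_subgraphs(graph: nx.Graph, k: int, tree_probs, seed: int
                     ) -> dict[CanonicalClass, float]:
    """RAND-ESU: unbiased per-class count estimates.

    ``tree_probs`` holds one retention probability per ESU tree depth
    (length k, each in (0, 1]).  Each branch at depth d survives with
    probability ``tree_probs[d]``; surviving leaves are weighted by the
    inverse of their inclusion probability.  With all probabilities 1 the
    result equals :func:`enumerate_connected_subgraphs` exactly.
    """
    _check_k(k)
    probs = [float(p) for p in tree_probs]
    if len(probs) != k:
        raise ValueError(f"tree_probs must have length {k}")
    if any(p <= 0 or p > 1 for p in probs):
        raise ValueError("tree probabilities must be in (0, 1]")
    rng = random.Random(seed)
    weight = 1.0 / math.prod(probs)
    counts = {cls: 0.0 for cls in connected_classes(k)}
    order = {v: i for i, v in enumerate(sorted(graph.nodes()))}

    def rand_extend(root, sub, extension, depth):
        if len(sub) == k:
            counts[_subgraph_class(graph, sub)] += weight
            return
        ext = sorted(extension, key=order.__getitem__)
        while ext:
            w = ext.pop(0)
            new_ext = set(ext)
            sub_and_nbrs = set(sub)
            for s in sub:
                sub_and_nbrs.update(graph[s])
            for u in graph[w]:
                if order[u] > order[root] and u not in sub_and_nbrs:
                    new_ext.add(u)
            if probs[depth] >= 1.0 or rng.random() < probs[depth]:
                rand_extend(root, tuple(sub) + (w,), new_ext, depth + 1)

    for v in sorted(graph.nodes(), key=order.__getitem__):
        if probs[0] >= 1.0 or rng.random() < probs[0]:
            ext = {u for u in graph[v] if order[u] > order[v]}
            rand_extend(v, (v,), ext, 1)
    return counts


def randomize(graph: nx.Graph, n_swaps: int, seed: int) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Picks two random edges (a,b),(c,d) and rewires to (a,d),(c,b) when the
    result stays a simple graph.  Rejected attempts count toward the
    attempt budget (20x n_swaps) but not toward ``n_swaps``, so graphs with
    no valid swap (e.g. a triangle) are returned unchanged.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    out = graph.copy()
    if n_swaps == 0 or out.number_of_edges() < 2:
        return out
    rng = random.Random(seed)
    edges = [tuple(sorted(e)) for e in sorted(out.edges())]
    done = 0
    max_attempts = 20 * n_swaps
    for _ in range(max_attempts):
        if done >= n_swaps:
            break
        i, j = rng.sample(range(len(edges)), 2)
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed new edges (a,d) and (c,b)
        if len({a, b, c, d}) < 4:
            continue
        if out.has_edge(a, d) or out.has_edge(c, b):
            continue
        out.remove_edge(a, b)
        out.remove_edge(c, d)
        out.add_edge(a, d)
        out.add_edge(c, b)
        edges[i] = tuple(sorted((a, d)))
        edges[j] = tuple(sorted((c, b)))
        done += 1
    return out


@dataclass(frozen=True)
class ClassStats:
    """Census statistics for one canonical class."""

    count_original: int
    frequency: float
    mean_freq: float
    sd: float
    z_score: float
    p_value: float


@dataclass(frozen=True)
class MotifCensusResult:
    """Per-class census of one network against its randomized null."""

    k: int
    stats: dict[CanonicalClass, ClassStats]
    n_random: int
    seed: int

    def to_rows(self) -> list[dict]:
        rows = []
        for cls in sorted(self.stats):
            s = self.stats[cls]
            rows.append({
                "class_id": cls.canon_id,
                "shape_name": cls.name,
                "count": s.count_original,
                "frequency": s.frequency,
                "mean_freq": s.mean_freq,
                "sd": s.sd,
                "z_score": s.z_score,
                "p_value": s.p_value,
            })
        return rows


def _frequencies(counts: dict[CanonicalClass, float]) -> dict[CanonicalClass, float]:
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in counts}
    return {c: n / total for c, n in counts.items()}


def census(graph: nx.Graph, k: int = 4, n_random: int = 100,
           swaps_per_edge: int = 10, seed: int = 0) -> MotifCensusResult:
    """Exact census of the network versus ``n_random`` degree-preserving
    randomizations.

    Per class: ``z = (freq_original - mean_random_freq) / sd`` (0 when
    sd = 0) and the one-sided empirical
    ``p = #(randomized count >= original count) / n_random``.
    """
    _check_k(k)
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    classes = connected_classes(k)
    counts0 = enumerate_connected_subgraphs(graph, k)
    freq0 = _frequencies(counts0)
    n_swaps = swaps_per_edge * graph.number_of_edges()
    rand_counts = {c: np.empty(n_random) for c in classes}
    rand_freqs = {c: np.empty(n_random) for c in classes}
    root = random.Random(seed)
    for r in range(n_random):
        rnet = randomize(graph, n_swaps, seed=root.randrange(2**31))
        counts_r = enumerate_connected_subgraphs(rnet, k)
        freqs_r = _frequencies(counts_r)
        for c in classes:
            rand_counts[c][r] = counts_r[c]
            rand_freqs[c][r] = freqs_r[c]
    stats = {}
    for c in classes:
        mean = float(np.mean(rand_freqs[c]))
        sd = float(np.std(rand_freqs[c]))  # population sd over the null draws
        z = 0.0 if sd == 0 else (freq0[c] - mean) / sd
        p = float(np.count_nonzero(rand_counts[c] >= counts0[c])) / n_random
        stats[c] = ClassStats(count_original=counts0[c], frequency=freq0[c],
                              mean_freq=mean, sd=sd, z_score=z, p_value=p)
    return MotifCensusResult(k=k, stats=stats, n_random=n_random, seed=seed)
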