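"""Loop-motif clustering and the pathway bridge.

Triangles and 4-cycles ("squares") are the only loop-shaped motifs on at
most four vertices.  Instances sharing a protein merge transitively into
Motif Clusters; proteins on two or more instances of a cluster are its
Center Points.  A cluster "bridges" two pathway gene sets when it has a
member in each; whether a pathway pair has significantly many bridging
clusters is judged by constrained resampling of protein sets of matched
sizes and intersection from the whole network, p = #(n' > n)/n_samples.
The union of bridging clusters across significant pairs, with the edges
the full network induces on it, is the bridge — the restricted search
space for path prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_io import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "LoopInstance",
    "MotifCluster",
    "EnrichmentResult",
    "Bridge",
    "find_loop_instances",
    "cluster_motifs",
    "count_bridging_clusters",
    "enrichment_p",
    "build_bridge",
]

TRIANGLE = "triangle"
SQUARE = "square"


def _canonical_cycle(nodes: list) -> tuple:
    """Rotation/reflection-invariant representative of a cycle."""
    n = len(nodes)
    best = None
    seq = list(nodes)
    for cand_seq in (seq, seq[::-1]):
        for s in range(n):
            rot = tuple(cand_seq[s:] + cand_seq[:s])
            if best is None or rot < best:
                best = rot
    return best


@dataclass(frozen=True)
class LoopInstance:
    """One triangle or one distinct 4-cycle (chorded squares count)."""

    cycle: tuple  # canonical vertex order around the cycle
    shape: str

    @property
    def vertices(self) -> frozenset:
        return frozenset(self.cycle)

    def __post_init__(self) -> None:
        want = 3 if self.shape == TRIANGLE else 4
        if self.shape not in (TRIANGLE, SQUARE) or len(self.cycle) != want:
            raise ValueError(f"bad loop instance {self.cycle}/{self.shape}")


def find_loop_instances(graph: nx.Graph) -> list[LoopInstance]:
    """All triangles and all distinct 4-cycles of the network.

    A 4-vertex subset contributes one instance per distinct 4-cycle it
    carries (a diamond has one, K4 has three): the square is read as the
    cycle pattern, not the chordless induced subgraph.
    """
    out = []
    for cyc in nx.simple_cycles(graph, length_bound=4):
        shape = TRIANGLE if len(cyc) == 3 else SQUARE
        out.append(LoopInstance(cycle=_canonical_cycle(cyc), shape=shape))
    return sorted(out, key=lambda li: (li.shape, li.cycle))


@dataclass(frozen=True)
class MotifCluster:
    """Loop instances merged transitively by shared proteins."""

    instances: frozenset[LoopInstance]
    members: frozenset[str]
    center_points: frozenset[str]
    cluster_id: str

    @classmethod
    def from_instances(cls, instances) -> "MotifCluster":
        inst = frozenset(instances)
        members = frozenset().union(*(i.vertices for i in inst))
        counts: dict[str, int] = {}
        for i in inst:
            for v in i.vertices:
                counts[v] = counts.get(v, 0) + 1
        centers = frozenset(v for v, c in counts.items() if c >= 2)
        cluster_id = min(centers) if centers else min(members)
        return cls(instances=inst, members=members, center_points=centers,
                   cluster_id=cluster_id)


def cluster_motifs(instances: list[LoopInstance]) -> list[MotifCluster]:
    """Connected components of the instance-overlap graph (shared >=1
    vertex), including singleton clusters with empty center point sets."""
    parent = list(range(len(instances)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_vertex: dict[str, int] = {}
    for idx, inst in enumerate(instances):
        for v in inst.vertices:
            if v in by_vertex:
                ra, rb = find(by_vertex[v]), find(idx)
                if ra != rb:
                    parent[rb] = ra
            else:
                by_vertex[v] = idx
    groups: dict[int, list[LoopInstance]] = {}
    for idx, inst in enumerate(instances):
        groups.setdefault(find(idx), []).append(inst)
    clusters = [MotifCluster.from_instances(g) for g in groups.values()]
    return sorted(clusters, key=lambda c: c.cluster_id)


def _bridges(cluster: MotifCluster, p1: frozenset, p2: frozenset) -> bool:
    """A cluster lies between two gene sets when it touches both."""
    return bool(cluster.members & p1) and bool(cluster.members & p2)


def count_bridging_clusters(clusters: list[MotifCluster], p1: GeneSet,
                            p2: GeneSet) -> int:
    m1 = frozenset(p1.members)
    m2 = frozenset(p2.members)
    return sum(_bridges(c, m1, m2) for c in clusters)


@dataclass(frozen=True)
class EnrichmentResult:
    pair: tuple[str, str]
    n: int
    samples: tuple[int, ...]
    p_value: float
    n_samples: int
    seed: int


def enrichment_p(universe, clusters: list[MotifCluster], p1: GeneSet,
                 p2: GeneSet, n_samples: int = 1000,
                 seed: int = 0) -> EnrichmentResult:
    """Resampling P-value for the bridging-cluster count between p1, p2.

    Each draw picks random protein sets S1, S2 from the universe with
    |S1| = |p1|, |S2| = |p2| and |S1 ∩ S2| = |p1 ∩ p2| (shared block first,
    then disjoint remainders, uniformly without replacement);
    p = #(n' > n) / n_samples, ties favouring enrichment.
    """
    pool = sorted(universe)
    m1, m2 = frozenset(p1.members), frozenset(p2.members)
    s_shared = len(m1 & m2)
    n1, n2 = len(m1), len(m2)
    if n1 > len(pool) or n2 > len(pool) or n1 + n2 - s_shared > len(pool):
        raise ValueError("gene sets do not fit in the protein universe "
                         "under the intersection constraint")
    n_obs = count_bridging_clusters(clusters, p1, p2)
    member_sets = [c.members for c in clusters]
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool, dtype=object)
    samples = np.empty(n_samples, dtype=int)
    for t in range(n_samples):
        draw = rng.choice(len(pool_arr), size=n1 + n2 - s_shared,
                          replace=False)
        shared = set(pool_arr[draw[:s_shared]])
        s1 = shared | set(pool_arr[draw[s_shared:n1]])
        s2 = shared | set(pool_arr[draw[n1:]])
        samples[t] = sum(bool(ms & s1) and bool(ms & s2)
                         for ms in member_sets)
    p = float(np.count_nonzero(samples > n_obs)) / n_samples
    return EnrichmentResult(pair=(p1.name, p2.name), n=n_obs,
                            samples=tuple(int(x) for x in samples),
                            p_value=p, n_samples=n_samples, seed=seed)


@dataclass
class Bridge:
    """The enriched-cluster subnetwork searched for lurking paths."""

    subnetwork: nx.Graph
    source_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    enrichment: list[EnrichmentResult] = field(default_factory=list)

    @property
    def nodes(self) -> set:
        return set(self.subnetwork.nodes())


def build_bridge(graph: nx.Graph, clusters: list[MotifCluster],
                 pathway_pairs: list[tuple[GeneSet, GeneSet]],
                 alpha: float = 0.01, n_samples: int = 1000,
                 seed: int = 0) -> Bridge:
    """Union of bridging clusters over all pathway pairs with p < alpha,
    with edges induced from the full network.  Empty when no pair passes
    (logged as a warning)."""
    if not pathway_pairs:
        raise ValueError("at least one pathway pair is required")
    universe = sorted(graph.nodes())
    rng = np.random.default_rng(seed)
    members: set[str] = set()
    source_pairs = []
    results = []
    for p1, p2 in pathway_pairs:
        res = enrichment_p(universe, clusters, p1, p2, n_samples=n_samples,
                           seed=int(rng.integers(2**31)))
        results.append(res)
        source_pairs.append((p1.name, p2.name, res.p_value))
        if res.p_value < alpha:
            m1, m2 = frozenset(p1.members), frozenset(p2.members)
            for c in clusters:
                if _bridges(c, m1, m2):
                    members |= c.members
    if not members:
        logger.warning("no pathway pair passed enrichment at alpha=%g; "
                       "bridge is empty", alpha)
    sub = graph.subgraph(members).copy()
    return Bridge(subnetwork=sub, source_pairs=source_pairs,
                  enrichment=results)
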