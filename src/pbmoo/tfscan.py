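"""Transcription-factor scan for the signature gene.

Each candidate TF is forced, one by one, to be the direct upstream of the
signature: the best ligand→…→TF→signature paths under the DES + λ
objective (total length ≤ 7) are computed with the TF pinned as the
penultimate node.  TFs absent from the graph, not adjacent to the
signature (by a real or pseudo-edge), or unreachable from the ligand are
marked infeasible.  Pooling the per-TF paths and ranking by cost gives
occurrence frequencies: how often a protein is the TF slot (penultimate
node) and how often it appears anywhere in the top paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .expression import DESTable
from .paths import (L_MAX_DEFAULT, L_MIN_DEFAULT, PathSolution,
                    _iter_best_paths)

__all__ = ["TFScanEntry", "TFScanResult", "scan_tfs", "tf_frequency"]


@dataclass(frozen=True)
class TFScanEntry:
    tf: str
    feasible: bool
    paths: tuple[PathSolution, ...] = ()
    reason: str = ""

    @property
    def best(self) -> PathSolution | None:
        return self.paths[0] if self.paths else None

    @property
    def cost(self) -> float | None:
        return self.paths[0].cost if self.paths else None


@dataclass
class TFScanResult:
    ligand: str
    signature: str
    entries: dict[str, TFScanEntry] = field(default_factory=dict)

    @property
    def feasible(self) -> list[TFScanEntry]:
        return [e for e in self.entries.values() if e.feasible]

    def ranked(self) -> list[TFScanEntry]:
        """Feasible TFs ordered by best-path cost (ties: shorter, lex)."""
        return sorted(self.feasible, key=lambda e: e.best.sort_key)

    def pooled_paths(self) -> list[PathSolution]:
        pool = [p for e in self.feasible for p in e.paths]
        return sorted(pool, key=lambda p: p.sort_key)

    def to_rows(self) -> list[dict]:
        rows = []
        for rank, e in enumerate(self.ranked(), start=1):
            rows.append({"tf": e.tf, "rank": rank, "cost": e.cost,
                         "path": ">".join(e.best.nodes)})
        for tf in sorted(self.entries):
            e = self.entries[tf]
            if not e.feasible:
                rows.append({"tf": tf, "rank": None, "cost": None,
                             "path": f"infeasible: {e.reason}"})
        return rows


def scan_tfs(graph: nx.Graph, des: DESTable, ligand: str, signature: str,
             tf_list: list[str], lam: float = 0.0, paths_per_tf: int = 1,
             l_min: int = L_MIN_DEFAULT,
             l_max: int = L_MAX_DEFAULT) -> TFScanResult:
    """Best ligand→…→TF→signature paths for every TF in the list.

    The TF→signature step may ride a pseudo-edge created by orphan
    attachment.  The search runs ligand→TF on the graph minus the
    signature (so the signature appears exactly once, at the end) and then
    appends the signature, keeping total length within [l_min, l_max].
    """
    if not tf_list:
        raise ValueError("tf_list is empty")
    if ligand not in graph or signature not in graph:
        raise ValueError("ligand and signature must be in the graph")
    result = TFScanResult(ligand=ligand, signature=signature)
    sig_cost = des.des(signature) + lam
    for tf in tf_list:
        if tf == signature:
            result.entries[tf] = TFScanEntry(tf, False,
                                             reason="tf is the signature")
            continue
        if tf not in graph:
            result.entries[tf] = TFScanEntry(tf, False,
                                             reason="not in graph")
            continue
        if not graph.has_edge(tf, signature):
            result.entries[tf] = TFScanEntry(
                tf, False, reason="not adjacent to signature")
            continue
        if tf == ligand:
            # direct ligand→signature link
            if l_min <= 2 <= l_max:
                cost = des.des(ligand) + des.des(signature) + 2 * lam
                sol = PathSolution(nodes=(ligand, signature), cost=cost,
                                   lam=lam)
                result.entries[tf] = TFScanEntry(tf, True, paths=(sol,))
            else:
                result.entries[tf] = TFScanEntry(
                    tf, False, reason="direct link outside length bounds")
            continue
        paths = []
        for sub in _iter_best_paths(graph, des, ligand, tf, lam,
                                    max(1, l_min - 1), l_max - 1,
                                    banned=frozenset({signature})):
            paths.append(PathSolution(nodes=sub.nodes + (signature,),
                                      cost=sub.cost + sig_cost, lam=lam))
            if len(paths) == paths_per_tf:
                break
        if paths:
            result.entries[tf] = TFScanEntry(tf, True, paths=tuple(paths))
        else:
            result.entries[tf] = TFScanEntry(
                tf, False, reason="no route from ligand within length bound")
    if not result.entries:
        raise ValueError("tf_list is empty")
    return result


def tf_frequency(result: TFScanResult, top_k: int = 50) -> pd.DataFrame:
    """Occurrence counts over the ``top_k`` lowest-cost pooled paths.

    ``as_tf_count``: times the protein is the penultimate node (the TF
    slot); ``as_node_count``: times it appears anywhere on a counted path.
    Sorted by as_tf_count, then as_node_count, descending.
    """
    pool = result.pooled_paths()[:top_k]
    if not pool:
        raise ValueError("no feasible paths to summarize")
    as_tf: dict[str, int] = {}
    as_node: dict[str, int] = {}
    for sol in pool:
        for v in sol.nodes:
            as_node[v] = as_node.get(v, 0) + 1
        penult = sol.nodes[-2]
        as_tf[penult] = as_tf.get(penult, 0) + 1
    rows = [{"protein": v, "as_tf_count": as_tf.get(v, 0),
             "as_node_count": c} for v, c in as_node.items()]
    df = pd.DataFrame(rows)
    return df.sort_values(["as_tf_count", "as_node_count", "protein"],
                          ascending=[False, False, True],
                          ignore_index=True)
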