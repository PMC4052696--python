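"""Synthetic study-condition generator.

Emulates the input families the pipeline consumes, with a known planted
truth so recovery can be scored:

* a PPI-style network holding a 5-protein corridor (the planted route),
  each corridor edge reinforced into a triangle so corridor proteins sit
  on loop motifs, plus vertex-disjoint planted loops that span the two
  pathway gene sets, plus Erdős–Rényi background;
* two pathway gene sets P1 (ligand end) and P2 (TF end) that the corridor
  and every planted loop bridge;
* two-condition expression where the planted-route genes carry a mean
  shift (default 5 sigma with 10+10 samples) and every other network gene
  is null, so planted genes score tiny t-test P-values and the rest are
  Uniform(0,1);
* a signature gene absent from the network whose expression is a noisy
  copy of the planted transcription factor, giving one overwhelming
  correlation partner for orphan attachment;
* a TF list containing the planted TF and decoys.

The scenario records every parameter in a manifest so runs replay.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import bridge as bridge_mod
from . import paths as paths_mod
from .expression import build_des_table
from .graph_io import (CASE, CONTROL, ExpressionDataset, GeneSet,
                       write_expression, write_network)

__all__ = ["Scenario", "gen_network", "gen_expression", "gen_scenario",
           "recover_planted_path", "PRESETS"]

CORRIDOR_LEN = 5  # corridor proteins; +1 signature = 6-protein planted path
SIGNATURE = "SIG"

PRESETS = {
    # name: (n_planted_loops, n_background, m_background, pathway_padding,
    #        n_datasets)
    "tiny": dict(n_planted_loops=6, n_background=20, m_background=25,
                 padding=2, n_datasets=1),
    "small": dict(n_planted_loops=8, n_background=40, m_background=60,
                  padding=3, n_datasets=2),
    "medium": dict(n_planted_loops=10, n_background=80, m_background=120,
                   padding=4, n_datasets=2),
}


def corridor_nodes() -> list[str]:
    return [f"PATH{i}" for i in range(1, CORRIDOR_LEN + 1)]


def _support_nodes() -> list[str]:
    return [f"TRI{i}" for i in range(1, CORRIDOR_LEN)]


def _loop_nodes(i: int) -> list[str]:
    size = 3 if i % 2 == 0 else 4  # alternate triangles and squares
    return [f"LP{i:02d}{c}" for c in "ABCD"[:size]]


def gen_network(n_background: int, m_background: int, n_planted_loops: int,
                seed: int) -> nx.Graph:
    """Corridor + planted loops + Erdős–Rényi background.

    The corridor PATH1..PATH5 is a chain whose every edge belongs to a
    triangle (via TRIi support nodes); planted loops LPxx* are
    vertex-disjoint cycles.  Background edges are sampled uniformly
    without replacement from all remaining unordered pairs except those
    internal to the corridor block or to a single loop (which would add
    chords or corridor shortcuts the construction must not contain).
    """
    graph = nx.Graph()
    corridor = corridor_nodes()
    supports = _support_nodes()
    for a, b, t in zip(corridor, corridor[1:], supports):
        graph.add_edge(a, b)
        graph.add_edge(a, t)
        graph.add_edge(t, b)
    loop_groups = []
    for i in range(1, n_planted_loops + 1):
        nodes = _loop_nodes(i)
        loop_groups.append(nodes)
        for a, b in zip(nodes, nodes[1:] + nodes[:1]):
            graph.add_edge(a, b)
    bg = [f"BG{i:03d}" for i in range(1, n_background + 1)]
    graph.add_nodes_from(bg)

    protected = set(corridor) | set(supports)
    same_loop = {frozenset(p) for nodes in loop_groups
                 for p in itertools.combinations(nodes, 2)}
    candidates = [
        (a, b)
        for a, b in itertools.combinations(sorted(graph.nodes()), 2)
        if not graph.has_edge(a, b)
        and not (a in protected and b in protected)
        and frozenset((a, b)) not in same_loop
    ]
    if m_background > len(candidates):
        raise ValueError(
            f"m_background={m_background} exceeds the {len(candidates)} "
            "available node pairs")
    rng = np.random.default_rng(seed)
    for idx in rng.choice(len(candidates), size=m_background, replace=False):
        graph.add_edge(*candidates[idx])
    return graph


def gen_expression(genes, n_case: int, n_control: int, planted_genes,
                   effect_size: float, sigma: float, seed: int, *,
                   direction: dict[str, int] | None = None,
                   signature_gene: str | None = None,
                   tf_gene: str | None = None,
                   signature_noise: float = 0.05,
                   name: str = "synth") -> ExpressionDataset:
    """Two-condition expression with planted differential genes.

    Background genes are i.i.d. Normal(0, sigma^2) in both conditions;
    planted genes get a ``direction``-signed mean shift of ``effect_size``
    in case samples.  When given, the signature gene is rewritten as the
    TF gene's values plus Normal(0, (signature_noise*sigma)^2) noise,
    inducing a near-unit Pearson correlation with the TF.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0; use `direction` for sign")
    if n_case < 2 or n_control < 2:
        raise ValueError("each condition needs at least 2 samples")
    genes = list(genes)
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    values = rng.normal(0.0, sigma, size=(len(genes), n))
    for g in planted_genes:
        d = (direction or {}).get(g, 1)
        values[index[g], :n_case] += d * effect_size
    if signature_gene is not None:
        if tf_gene is None:
            raise ValueError("signature_gene requires tf_gene")
        values[index[signature_gene]] = (
            values[index[tf_gene]]
            + rng.normal(0.0, signature_noise * sigma, size=n)
        )
    samples = [f"S{i:02d}" for i in range(1, n + 1)]
    condition = [CASE] * n_case + [CONTROL] * n_control
    return ExpressionDataset(genes=genes, samples=samples, values=values,
                             condition=condition, name=name)


@dataclass
class Scenario:
    """A complete synthetic study with its planted truth."""

    network: nx.Graph
    p1: GeneSet
    p2: GeneSet
    datasets: list[ExpressionDataset]
    ligand: str
    signature: str
    planted_tf: str
    planted_path: tuple[str, ...]
    tf_list: list[str]
    seed: int
    params: dict = field(default_factory=dict)
    # orphan-attachment study configuration: the generative model has a
    # single direct regulator of the signature, so only the strongest
    # correlation partner is attached
    r_threshold: float = 0.6
    max_partners: int = 1

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "ligand": self.ligand,
            "signature": self.signature,
            "planted_tf": self.planted_tf,
            "planted_path": list(self.planted_path),
            "p1": sorted(self.p1.members),
            "p2": sorted(self.p2.members),
            "tf_list": self.tf_list,
            "r_threshold": self.r_threshold,
            "max_partners": self.max_partners,
            "params": self.params,
        }


def gen_scenario(size_preset: str = "tiny", seed: int = 0,
                 out_dir: str | Path | None = None,
                 effect_size: float = 5.0, sigma: float = 1.0,
                 n_case: int = 10, n_control: int = 10) -> Scenario:
    """Generate an internally consistent scenario (optionally on disk).

    The planted path is PATH1..PATH5 followed by the signature: five
    network proteins plus the orphan signature reachable only through the
    correlation pseudo-edge to PATH5 (the planted TF).
    """
    if size_preset not in PRESETS:
        raise ValueError(f"unknown preset {size_preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    cfg = PRESETS[size_preset]
    rng = np.random.default_rng(seed)
    graph = gen_network(cfg["n_background"], cfg["m_background"],
                        cfg["n_planted_loops"],
                        seed=int(rng.integers(2**31)))
    corridor = corridor_nodes()
    ligand, planted_tf = corridor[0], corridor[-1]
    planted_path = tuple(corridor) + (SIGNATURE,)

    bg = sorted(n for n in graph.nodes() if n.startswith("BG"))
    pad = cfg["padding"]
    pad1 = list(np.array(bg, dtype=object)[
        rng.choice(len(bg), size=2 * pad, replace=False)])
    members1 = {corridor[0], corridor[1], "TRI1"}
    members2 = {corridor[-2], corridor[-1], f"TRI{CORRIDOR_LEN - 1}"}
    for i in range(1, cfg["n_planted_loops"] + 1):
        nodes = _loop_nodes(i)
        members1.add(nodes[0])
        members2.add(nodes[1])
    members1 |= set(pad1[:pad])
    members2 |= set(pad1[pad:])
    p1 = GeneSet(name="P1_ligand_side", members=frozenset(members1))
    p2 = GeneSet(name="P2_tf_side", members=frozenset(members2))

    genes = sorted(graph.nodes()) + [SIGNATURE]
    datasets = [
        gen_expression(genes, n_case, n_control, planted_genes=corridor,
                       effect_size=effect_size, sigma=sigma,
                       seed=int(rng.integers(2**31)),
                       signature_gene=SIGNATURE, tf_gene=planted_tf,
                       name=f"ds{d + 1}")
        for d in range(cfg["n_datasets"])
    ]
    decoys = list(np.array(bg, dtype=object)[
        rng.choice(len(bg), size=4, replace=False)])
    tf_list = [planted_tf] + decoys
    params = dict(cfg) | {
        "preset": size_preset, "effect_size": effect_size, "sigma": sigma,
        "n_case": n_case, "n_control": n_control,
    }
    scenario = Scenario(network=graph, p1=p1, p2=p2, datasets=datasets,
                        ligand=ligand, signature=SIGNATURE,
                        planted_tf=planted_tf, planted_path=planted_path,
                        tf_list=tf_list, seed=seed, params=params)
    if out_dir is not None:
        _write_scenario(scenario, Path(out_dir))
    return scenario


def _write_scenario(scenario: Scenario, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "network.tsv").write_text(write_network(scenario.network))
    gmt = ""
    for gs in (scenario.p1, scenario.p2):
        gmt += "\t".join([gs.name, "synthetic"] + sorted(gs.members)) + "\n"
    (out_dir / "pathways.gmt").write_text(gmt)
    (out_dir / "pairs.tsv").write_text(
        f"{scenario.p1.name}\t{scenario.p2.name}\n")
    for i, ds in enumerate(scenario.datasets, start=1):
        matrix, cond = write_expression(ds)
        (out_dir / f"expr{i}.tsv").write_text(matrix)
        (out_dir / f"cond{i}.tsv").write_text(cond)
    (out_dir / "tfs.txt").write_text(
        "\n".join(scenario.tf_list) + "\n")
    (out_dir / "manifest.json").write_text(
        json.dumps(scenario.manifest(), indent=2, sort_keys=True) + "\n")


def recover_planted_path(scenario: Scenario, n_samples: int = 1000,
                         alpha: float = 0.01, lam: float = 0.0,
                         seed: int | None = None):
    """Run the full inference pipeline on a scenario.

    Loop census → clustering → enrichment-gated bridge → orphan
    attachment of the signature → minimum-cost ligand→signature path.
    Returns (best PathSolution, Bridge, pseudo-edges).
    """
    instances = bridge_mod.find_loop_instances(scenario.network)
    clusters = bridge_mod.cluster_motifs(instances)
    br = bridge_mod.build_bridge(
        scenario.network, clusters, [(scenario.p1, scenario.p2)],
        alpha=alpha, n_samples=n_samples,
        seed=scenario.seed if seed is None else seed)
    augmented, pseudo = paths_mod.attach_orphan(
        br, scenario.signature, scenario.datasets,
        r_threshold=scenario.r_threshold,
        max_partners=scenario.max_partners)
    des = build_des_table(scenario.datasets)
    sol = paths_mod.min_cost_path(augmented, des, scenario.ligand,
                                  scenario.signature, lam=lam)
    return sol, br, pseudo
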