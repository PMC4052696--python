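"""Readers and writers for the plain-text input formats.

Protein-protein interaction networks arrive as 2+ column edge lists
(SIF-compatible), pathway gene sets as GMT lines, expression data as a
TSV matrix plus a two-column sample->condition map, and transcription
factors as one symbol per line.  Symbols are whitespace-trimmed and
matched exactly (case-preserving); no alias resolution is attempted.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: pattern for a SIF interaction-type token (lowercase, e.g. "pp", "pd")
_SIF_TYPE = re.compile(r"^[a-z_-]{1,4}$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GeneSet:
    """A named pathway gene set (one GMT line)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")


@dataclass
class ExpressionDataset:
    """A gene x sample expression matrix with a two-condition design."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    condition: list[str]
    name: str = "expr"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.condition) != len(self.samples):
            raise FormatError("condition labels do not match samples")
        bad = set(self.condition) - {CASE, CONTROL}
        if bad:
            raise FormatError(f"unknown condition labels: {sorted(bad)}")
        for label in (CASE, CONTROL):
            if label not in self.condition:
                raise FormatError(f"no {label!r} samples in dataset {self.name!r}")
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)
            raise FormatError(
                f"duplicate gene symbols: {sorted(dupes[dupes.duplicated()])}"
            )
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def case_columns(self) -> np.ndarray:
        return np.array([c == CASE for c in self.condition])

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def expression(self, gene: str) -> np.ndarray:
        """All sample values for one gene (case columns first is NOT implied)."""
        return self.values[self._index[gene]]

    def case_control(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        row = self.values[self._index[gene]]
        mask = self.case_columns
        return row[mask], row[~mask]


def _content_lines(text: str) -> list[tuple[int, str]]:
    """(1-based line number, stripped line) for non-blank, non-comment lines."""
    out = []
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        out.append((i, line))
    return out


def parse_network(text: str) -> nx.Graph:
    """Parse an edge-list into a simple undirected graph.

    Lines hold 2+ whitespace-separated fields.  Three-column lines whose
    middle field looks like a SIF interaction type ("A pp B") are read as
    SIF; otherwise the first two fields are the endpoints and the rest is
    ignored.  Duplicate edges (in either orientation) collapse; self-loop
    lines are dropped with a warning.
    """
    lines = _content_lines(text)
    if not lines:
        raise FormatError("network file is empty")
    three_col = [f for _, ln in lines if len(f := ln.split()) == 3]
    sif = bool(three_col) and all(_SIF_TYPE.match(f[1]) for f in three_col)

    graph = nx.Graph()
    n_self = 0
    for lineno, line in lines:
        fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: expected at least 2 fields")
        if sif and len(fields) == 3:
            a, b = fields[0], fields[2]
        else:
            a, b = fields[0], fields[1]
        if a == b:
            n_self += 1
            continue
        graph.add_edge(a, b)
    if n_self:
        logger.warning("dropped %d self-loop line(s)", n_self)
    if graph.number_of_edges() == 0:
        raise FormatError("network has no valid edges")
    return graph


def write_network(graph: nx.Graph) -> str:
    """Serialize a graph as a sorted two-column edge list (round-trips)."""
    lines = sorted("\t".join(sorted(e)) for e in graph.edges())
    return "\n".join(lines) + "\n"


def parse_gene_sets(text: str) -> list[GeneSet]:
    """Parse GMT content: name, description, then >=1 member per line."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in _content_lines(text):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"line {lineno}: GMT line needs name, description and >=1 member"
            )
        name = fields[0].strip()
        if name in seen:
            raise FormatError(f"line {lineno}: duplicate gene set name {name!r}")
        seen.add(name)
        members = frozenset(m.strip() for m in fields[2:] if m.strip())
        if not members:
            raise FormatError(f"line {lineno}: gene set {name!r} has no members")
        sets.append(GeneSet(name=name, members=members))
    if not sets:
        raise FormatError("GMT file is empty")
    return sets


def parse_condition_map(text: str) -> dict[str, str]:
    """Two-column TSV: sample ID, condition in {case, control}."""
    mapping: dict[str, str] = {}
    for lineno, line in _content_lines(text):
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"line {lineno}: expected 'sample<TAB>condition'")
        sample, label = fields
        if label not in (CASE, CONTROL):
            raise FormatError(
                f"line {lineno}: condition must be '{CASE}' or '{CONTROL}', "
                f"got {label!r}"
            )
        mapping[sample] = label
    if not mapping:
        raise FormatError("condition file is empty")
    return mapping


def parse_expression(matrix_text: str, condition_text: str,
                     name: str = "expr") -> ExpressionDataset:
    """Parse a TSV matrix (header = sample IDs, one gene per row) and a
    condition map into an :class:`ExpressionDataset`."""
    try:
        df = pd.read_csv(io.StringIO(matrix_text), sep="\t", index_col=0,
                         comment="#", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot read expression matrix: {exc}") from exc
    if df.empty:
        raise FormatError("expression matrix is empty")
    genes = [str(g).strip() for g in df.index]
    samples = [str(s).strip() for s in df.columns]
    if len(set(genes)) != len(genes):
        idx = pd.Index(genes)
        raise FormatError(
            f"duplicate gene symbol(s): {sorted(set(idx[idx.duplicated()]))}"
        )
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric value {cell!r} at gene {genes[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None
    cond_map = parse_condition_map(condition_text)
    missing = [s for s in samples if s not in cond_map]
    if missing:
        raise FormatError(f"samples missing from condition map: {missing}")
    condition = [cond_map[s] for s in samples]
    return ExpressionDataset(genes=genes, samples=samples, values=values,
                             condition=condition, name=name)


def write_expression(dataset: ExpressionDataset) -> tuple[str, str]:
    """Inverse of :func:`parse_expression` (matrix text, condition text)."""
    df = pd.DataFrame(dataset.values, index=dataset.genes,
                      columns=dataset.samples)
    matrix = df.to_csv(sep="\t", index_label="gene")
    cond = "".join(f"{s}\t{c}\n" for s, c in zip(dataset.samples,
                                                 dataset.condition))
    return matrix, cond


def parse_tf_list(text: str) -> list[str]:
    """One transcription-factor symbol per line; order kept, dedup kept-first."""
    seen: set[str] = set()
    tfs: list[str] = []
    for _, line in _content_lines(text):
        symbol = line.split()[0]
        if symbol not in seen:
            seen.add(symbol)
            tfs.append(symbol)
    if not tfs:
        raise FormatError("transcription-factor list is empty")
    return tfs
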