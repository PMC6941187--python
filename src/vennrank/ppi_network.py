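"""STRING-style PPI edge lists and the induced DEG subnetwork.

The network is instantiated on the DEG union only: nodes are gene symbols,
and an (unweighted, undirected) edge exists where the source interaction
network connects the two genes with combined score strictly above the
high-confidence cutoff (700 on STRING's 0–1000 scale).  Isolated DEGs are
kept as nodes so every DEG is rankable.  Column normalization of the binary
adjacency yields the transition matrix of the random walk; an isolated
node's zero column first receives a self-loop so the matrix stays
column-stochastic and probability mass is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence, TextIO

import numpy as np

from .errors import InputError

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 700


class EdgeRecord(NamedTuple):
    node_a: str
    node_b: str
    combined_score: int


def _read_text(stream: TextIO | str | Path) -> str:
    if isinstance(stream, Path):
        return stream.read_text(encoding="utf-8")
    if isinstance(stream, str):
        if stream and "\n" not in stream and Path(stream).is_file():
            return Path(stream).read_text(encoding="utf-8")
        return stream
    return stream.read()


def load_edges(
    stream: TextIO | str | Path,
    threshold: int = DEFAULT_THRESHOLD,
) -> list[EdgeRecord]:
    """Parse a whitespace- or tab-delimited scored edge list.

    Keeps only edges with combined_score strictly greater than ``threshold``;
    collapses duplicate unordered pairs (STRING link files list both
    directions) and drops self-loops.  A leading ``protein1 protein2
    combined_score`` header is auto-detected.
    """
    text = _read_text(stream)
    kept: dict[frozenset[str], EdgeRecord] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        cells = line.split("\t") if "\t" in line else line.split()
        cells = [c.strip() for c in cells]
        if lineno == 1 and len(cells) >= 3 and not _is_int(cells[2]):
            continue  # header line
        if len(cells) < 3:
            raise InputError(
                f"edge list line {lineno}: expected 3 columns "
                "(node_a, node_b, combined_score)"
            )
        if not _is_int(cells[2]):
            raise InputError(
                f"edge list line {lineno}: unparsable combined_score {cells[2]!r}"
            )
        a, b, score = cells[0], cells[1], int(cells[2])
        if not 0 <= score <= 1000:
            raise InputError(
                f"edge list line {lineno}: combined_score {score} outside [0, 1000]"
            )
        if a == b:
            continue
        if score <= threshold:
            continue
        key = frozenset((a, b))
        if key not in kept:
            kept[key] = EdgeRecord(a, b, score)
    return list(kept.values())


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def load_alias(stream: TextIO | str | Path) -> dict[str, str]:
    """Read a 2-column (identifier, gene_symbol) alias table."""
    text = _read_text(stream)
    alias: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t") if "\t" in line else line.split()
        if len(cells) < 2:
            raise InputError(
                f"alias table line {lineno}: expected 2 columns (identifier, symbol)"
            )
        alias[cells[0].strip()] = cells[1].strip()
    return alias


def apply_alias(
    edges: Sequence[EdgeRecord],
    alias: Mapping[str, str],
) -> tuple[list[EdgeRecord], int]:
    """Translate edge endpoints through ``alias``.

    An empty alias is the identity.  Edges with an endpoint missing from a
    non-empty alias are dropped; returns ``(edges, n_dropped)``.
    """
    if not alias:
        return list(edges), 0
    out: list[EdgeRecord] = []
    dropped = 0
    for e in edges:
        a = alias.get(e.node_a)
        b = alias.get(e.node_b)
        if a is None or b is None:
            dropped += 1
            continue
        out.append(EdgeRecord(a, b, e.combined_score))
    if dropped:
        log.warning("dropped %d edges with unmapped endpoints", dropped)
    return out, dropped


@dataclass
class PpiGraph:
    """Induced unweighted subgraph on the DEG union, fixed node ordering.

    ``nodes`` is sorted lexicographically so matrices and output files are
    reproducible byte-for-byte; ``adjacency`` is the symmetric 0/1 matrix
    over that ordering with a zero diagonal.
    """

    nodes: list[str]
    adjacency: np.ndarray

    @property
    def index(self) -> dict[str, int]:
        if not hasattr(self, "_cached_index"):
            self._cached_index = {g: i for i, g in enumerate(self.nodes)}
        return self._cached_index

    def degree(self, gene: str) -> int:
        return int(self.adjacency[:, self.index[gene]].sum())

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class TransitionMatrix:
    """Column-stochastic walk matrix A' over the same node ordering."""

    nodes: list[str]
    matrix: np.ndarray


def induce_subgraph(
    edges: Sequence[EdgeRecord],
    deg_union: set[str],
) -> PpiGraph:
    """Induce the binary adjacency on ``deg_union``, keeping isolates."""
    if not deg_union:
        raise InputError("cannot induce a network on an empty DEG union")
    nodes = sorted(deg_union)
    idx = {g: i for i, g in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=float)
    for e in edges:
        ia = idx.get(e.node_a)
        ib = idx.get(e.node_b)
        if ia is None or ib is None or ia == ib:
            continue
        A[ia, ib] = 1.0
        A[ib, ia] = 1.0
    return PpiGraph(nodes=nodes, adjacency=A)


def column_normalize(graph: PpiGraph) -> TransitionMatrix:
    """Column-normalize the adjacency into the walk's transition matrix.

    Zero columns (isolated nodes) receive a self-loop first, so every
    column of the result sums to exactly 1 and the walk conserves mass.
    """
    A = graph.adjacency.astype(float).copy()
    col_sums = A.sum(axis=0)
    isolates = col_sums == 0
    if isolates.any():
        ii = np.where(isolates)[0]
        A[ii, ii] = 1.0
        col_sums = A.sum(axis=0)
    return TransitionMatrix(nodes=list(graph.nodes), matrix=A / col_sums)
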