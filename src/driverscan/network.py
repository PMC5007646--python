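"""Protein-interaction network container and edge-list input.

The network substrate is an undirected graph over gene symbols with
confidence-weighted edges.  Edges are filtered at construction by a
confidence threshold (strictly greater than); the adjacency used for
propagation is *binary* — confidence scores only decide which edges
survive, they never weight the walk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "TransitionMatrix",
    "EdgeListError",
    "read_edge_list",
    "neighbors",
    "column_normalize",
]


class EdgeListError(ValueError):
    """Malformed or unusable edge-list input."""


@dataclass(frozen=True)
class Network:
    """An undirected interaction network with a stable gene index.

    Attributes
    ----------
    genes
        Sorted tuple of unique gene symbols; defines row/column order of
        the adjacency matrix.
    graph
        The underlying :class:`networkx.Graph`; edge attribute ``score``
        holds the confidence in [0, 1].
    score_threshold
        The construction threshold every retained edge strictly exceeds.
    """

    genes: tuple[str, ...]
    graph: nx.Graph
    score_threshold: float = 0.0
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self._index:
            object.__setattr__(
                self, "_index", {g: i for i, g in enumerate(self.genes)}
            )

    @property
    def n(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} is not in the network") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency with zero diagonal (CSR, float64)."""
        a = nx.to_scipy_sparse_array(
            self.graph, nodelist=list(self.genes), weight=None, format="csr"
        )
        return sp.csr_matrix(a, dtype=np.float64)

    def degrees(self) -> np.ndarray:
        return np.asarray([self.graph.degree(g) for g in self.genes])

    def fingerprint(self) -> tuple[int, int]:
        """Cheap identity check used to refuse mixing results across networks."""
        return (self.n, self.graph.number_of_edges())


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic walk matrix sharing the source network's gene index."""

    matrix: sp.csr_matrix
    genes: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.genes)


def _parse_row(line: str, lineno: int) -> tuple[str, str, float]:
    parts = line.split()
    if len(parts) < 3:
        raise EdgeListError(
            f"line {lineno}: expected >=3 whitespace-separated columns, got {len(parts)}"
        )
    a, b, raw = parts[0], parts[1], parts[2]
    try:
        score = float(raw)
    except ValueError:
        raise EdgeListError(f"line {lineno}: non-numeric score {raw!r}") from None
    return a, b, score


def read_edge_list(
    path,
    score_threshold: float = 0.9,
    score_scale: str = "unit",
    strip_taxon_prefix: bool = False,
) -> Network:
    """Read a 3+ column (gene_a, gene_b, score) edge list into a :class:`Network`.

    Parameters
    ----------
    path
        Tab- or whitespace-separated file.  Lines starting with ``#`` are
        ignored; a first line whose third column is non-numeric is treated
        as a header (the STRING "protein links" dialect carries one).
    score_threshold
        Edges are kept only when score is strictly greater than this, on
        the unit [0, 1] scale.
    score_scale
        ``"unit"`` for scores already in [0, 1]; ``"per_mille"`` for raw
        STRING-style 0-1000 integers (divided by 1000 before comparison).
    strip_taxon_prefix
        Drop a leading ``"<taxon>."`` (e.g. ``9606.``) from identifiers.

    Notes
    -----
    Self-loops are discarded, duplicate pairs collapsed, and genes left
    with no surviving edge dropped (and logged), so the resulting network
    has no isolated nodes.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError("score_threshold must be in [0, 1]")
    if score_scale not in ("unit", "per_mille"):
        raise ValueError(f"unknown score_scale {score_scale!r}")

    g = nx.Graph()
    seen_any_row = False
    n_dup = n_self = n_below = 0
    try:
        fh = open(path, "rt", encoding="utf-8")
    except OSError as exc:
        raise EdgeListError(f"cannot read edge list {path}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not seen_any_row:
                # allow a single header row (third field non-numeric)
                parts = line.split()
                if len(parts) >= 3:
                    try:
                        float(parts[2])
                    except ValueError:
                        seen_any_row = True
                        continue
            a, b, score = _parse_row(line, lineno)
            seen_any_row = True
            if score_scale == "per_mille":
                score /= 1000.0
            if strip_taxon_prefix:
                a = a.split(".", 1)[-1]
                b = b.split(".", 1)[-1]
            if a == b:
                n_self += 1
                continue
            if score <= score_threshold:
                n_below += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                g[a][b]["score"] = max(g[a][b]["score"], score)
            else:
                g.add_edge(a, b, score=score)

    if g.number_of_edges() == 0:
        raise EdgeListError(
            f"no edges survive threshold {score_threshold} in {path}"
        )
    logger.info(
        "edge list %s: %d genes, %d edges kept (%d below threshold, "
        "%d self-loops, %d duplicates collapsed)",
        path, g.number_of_nodes(), g.number_of_edges(), n_below, n_self, n_dup,
    )
    genes = tuple(sorted(g.nodes))
    return Network(genes=genes, graph=g, score_threshold=score_threshold)


def neighbors(net: Network, gene: str) -> set[str]:
    """All genes adjacent to ``gene`` (never including ``gene`` itself)."""
    if gene not in net:
        raise KeyError(f"gene {gene!r} is not in the network")
    return set(net.graph.neighbors(gene))


def column_normalize(net: Network) -> TransitionMatrix:
    """Column-normalized binary adjacency: entry (i, j) = A_ij / degree(j).

    Every column of the result sums to one, so repeated application
    conserves probability mass.  A zero-degree column cannot occur for a
    properly constructed :class:`Network` and raises.
    """
    adj = net.adjacency()
    deg = np.asarray(adj.sum(axis=0)).ravel()
    if np.any(deg == 0):
        bad = [net.genes[i] for i in np.flatnonzero(deg == 0)]
        raise ValueError(f"zero-degree genes cannot be normalized: {bad[:5]}")
    t = adj @ sp.diags(1.0 / deg)
    return TransitionMatrix(matrix=sp.csr_matrix(t), genes=net.genes)
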