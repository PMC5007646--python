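"""Random walk with restart (RWR) over the interaction network.

The walker starts on the seed genes and at every step either moves to a
uniformly chosen interaction partner (probability 1 - r) or restarts at
the seed distribution (probability r).  The stationary distribution of

    p_{t+1} = (1 - r) T p_t + r p_0

scores every network gene by its proximity to the seed set; r = 0.7 is
the conventional default for disease-gene prioritization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import Network, TransitionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NodeScores",
    "ConvergenceError",
    "initial_state",
    "random_walk_restart",
    "rank_genes",
]


class ConvergenceError(RuntimeError):
    """The walk failed to reach steady state within the iteration budget."""

    def __init__(self, iterations: int, residual: float):
        super().__init__(
            f"RWR did not converge after {iterations} iterations "
            f"(last L1 step difference {residual:.3e})"
        )
        self.iterations = iterations
        self.residual = residual


@dataclass(frozen=True)
class NodeScores:
    """Steady-state visiting probabilities aligned to the gene index."""

    probabilities: np.ndarray
    genes: tuple[str, ...]
    seeds: frozenset[str]
    restart: float
    iterations: int
    converged: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.genes, self.probabilities))


def initial_state(net: Network, seeds) -> np.ndarray:
    """Uniform probability 1/m on the m seeds that map onto the network.

    Seeds absent from the network are dropped with a warning (seed lists
    routinely contain symbols the network does not carry); if none map,
    this is an error listing the unmatched symbols.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    mapped = sorted(s for s in seeds if s in net)
    missing = sorted(seeds - set(mapped))
    if not mapped:
        raise ValueError(f"no seed maps onto the network: {missing}")
    if missing:
        logger.warning(
            "%d of %d seeds not on the network, dropped: %s",
            len(missing), len(seeds), missing,
        )
    p0 = np.zeros(net.n)
    for s in mapped:
        p0[net.index_of(s)] = 1.0 / len(mapped)
    return p0


def random_walk_restart(
    T: TransitionMatrix,
    p0: np.ndarray,
    restart: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> NodeScores:
    """Iterate p <- (1 - r) T p + r p0 to steady state.

    Convergence is declared when the L1 difference between successive
    iterates drops below ``tol``.  Because T is column-stochastic every
    iterate remains a probability vector.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    if p0.shape != (T.n,):
        raise ValueError(f"p0 has shape {p0.shape}, expected ({T.n},)")
    if not np.isclose(p0.sum(), 1.0, atol=1e-9):
        raise ValueError("p0 must sum to 1")
    if not 0.0 < restart <= 1.0:
        raise ValueError("restart probability must be in (0, 1]")

    m = T.matrix
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - restart) * (m @ p) + restart * p0
        diff = float(np.abs(p_next - p).sum())
        p = p_next
        if diff < tol:
            seeds = frozenset(T.genes[i] for i in np.flatnonzero(p0 > 0))
            return NodeScores(
                probabilities=p,
                genes=T.genes,
                seeds=seeds,
                restart=restart,
                iterations=it,
                converged=True,
            )
    raise ConvergenceError(max_iter, diff)


def rank_genes(scores: NodeScores, exclude=frozenset()) -> list[tuple[str, float]]:
    """Genes sorted by visiting probability, highest first.

    ``exclude`` (typically the expanding disease's own seeds) is removed
    from the ranking.  Ties are broken by lexicographic symbol order so
    the ranking is fully deterministic.
    """
    exclude = set(exclude)
    unknown = exclude - set(scores.genes)
    if unknown:
        raise KeyError(f"excluded genes not on the network: {sorted(unknown)[:5]}")
    pairs = [
        (g, float(p))
        for g, p in zip(scores.genes, scores.probabilities)
        if g not in exclude
    ]
    pairs.sort(key=lambda gp: (-gp[1], gp[0]))
    return pairs
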