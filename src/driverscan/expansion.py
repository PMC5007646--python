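"""Expansion cutoff via a GSEA-like running sum, and expansion overlap.

After propagation, every network gene carries a proximity score to one
disease's seeds.  Walking the ranked list from top to bottom, the running
sum gains sqrt((N - G)/G) at each gene belonging to the positive set and
loses sqrt(G/(N - G)) otherwise (the unweighted Kolmogorov-Smirnov
increments; N = network size, G = positive-set size), so it returns to
zero at the end of a full scan.  The peak of the curve marks where the
ranked expansion is maximally enriched for the positive set and defines
the cutoff: genes ranked at or above the peak are the disease's expanded
(predicted) gene list.  By default the positive set is the *other*
disease's seed genes, so the cutoff captures the cross-disease signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import Network
from .rwr import initial_state, random_walk_restart, rank_genes
from .network import column_normalize

__all__ = [
    "RunningSumCurve",
    "ExpansionResult",
    "running_sum",
    "expand_seed_set",
    "common_genes",
]


@dataclass(frozen=True)
class RunningSumCurve:
    """Running-sum statistic over a ranked gene list."""

    symbols: tuple[str, ...]
    is_positive: np.ndarray        # bool per ranked position
    increments: np.ndarray
    cumulative: np.ndarray
    peak_index: int                # 1-based rank of the first maximum
    peak_value: float
    N: int                         # all network genes
    G: int                         # positive-set size

    @property
    def degenerate(self) -> bool:
        """True when the curve never rises above zero (positives rank low)."""
        return self.peak_value <= 0.0


@dataclass(frozen=True)
class ExpansionResult:
    """One disease's expanded gene list with its defining curve."""

    seeds: frozenset[str]
    predicted: tuple[str, ...]     # ranked at or above the peak; seeds excluded
    cutoff_rank: int
    curve: RunningSumCurve
    network_fingerprint: tuple[int, int]


def running_sum(ranked, positives, N: int) -> RunningSumCurve:
    """Scan a ranked gene list and accumulate the enrichment running sum.

    Parameters
    ----------
    ranked
        Gene symbols ordered best-first (seeds of the expanding disease
        already removed).
    positives
        The positive gene set (membership checked per ranked position).
    N
        Total number of network genes — the normalization population,
        which may exceed ``len(ranked)``.
    """
    ranked = tuple(ranked)
    positives = set(positives)
    if N < len(ranked):
        raise ValueError(f"N={N} smaller than ranked list ({len(ranked)})")
    G = len(positives)
    if G == 0 or G >= N:
        raise ValueError(f"degenerate increments: G={G}, N={N}")

    up = math.sqrt((N - G) / G)
    down = -math.sqrt(G / (N - G))
    flags = np.fromiter((g in positives for g in ranked), dtype=bool, count=len(ranked))
    inc = np.where(flags, up, down)
    cum = np.cumsum(inc)
    if len(cum) == 0:
        raise ValueError("ranked list is empty")
    peak_pos = int(np.argmax(cum))  # argmax returns the first maximum
    return RunningSumCurve(
        symbols=ranked,
        is_positive=flags,
        increments=inc,
        cumulative=cum,
        peak_index=peak_pos + 1,
        peak_value=float(cum[peak_pos]),
        N=N,
        G=G,
    )


def expand_seed_set(
    net: Network,
    seeds_a,
    positives_b,
    restart: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 10000,
    positives_mode: str = "cross",
) -> ExpansionResult:
    """Expand a seed set on the network and cut at the running-sum peak.

    Composes initial state -> random walk with restart -> ranking (own
    seeds excluded) -> running sum against the positive set, and returns
    the genes ranked at or above the peak as the predicted expansion.

    ``positives_mode`` selects the positive set for the curve: ``"cross"``
    (default) uses ``positives_b``, the other disease's seeds, and ranks
    only non-seed genes; ``"self"`` labels the expanding seeds themselves
    as positives, keeping them in the ranked list so the curve can rise
    through them (they are still removed from the predicted set).
    """
    if positives_mode not in ("cross", "self"):
        raise ValueError(f"unknown positives_mode {positives_mode!r}")
    p0 = initial_state(net, seeds_a)
    mapped_seeds = frozenset(s for s in seeds_a if s in net)
    T = column_normalize(net)
    scores = random_walk_restart(T, p0, restart=restart, tol=tol, max_iter=max_iter)
    if positives_mode == "self":
        ranked = rank_genes(scores)
        pos = set(mapped_seeds)
    else:
        ranked = rank_genes(scores, exclude=mapped_seeds)
        pos = {g for g in positives_b if g in net}
    curve = running_sum([g for g, _ in ranked], pos, N=net.n)
    predicted = tuple(
        g for g, _ in ranked[: curve.peak_index] if g not in mapped_seeds
    )
    return ExpansionResult(
        seeds=mapped_seeds,
        predicted=predicted,
        cutoff_rank=curve.peak_index,
        curve=curve,
        network_fingerprint=net.fingerprint(),
    )


def common_genes(
    a: ExpansionResult, b: ExpansionResult, include_seeds: bool = True
) -> set[str]:
    """Overlap of two expansions computed on the same network.

    With ``include_seeds`` each disease's list is its predicted genes
    plus its own seeds, so a gene predicted for one disease and seeding
    the other counts as common.
    """
    if a.network_fingerprint != b.network_fingerprint:
        raise ValueError("expansion results come from different networks")
    set_a = set(a.predicted) | (set(a.seeds) if include_seeds else set())
    set_b = set(b.predicted) | (set(b.seeds) if include_seeds else set())
    return set_a & set_b
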