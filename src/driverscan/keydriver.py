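"""Key-driver scoring: hypergeometric neighborhood enrichment with BH-FDR.

A key driver is a network gene whose interaction neighbors are
significantly enriched for the common (both-disease) gene set.  For a
gene with n neighbors of which m are common genes, on a network of N
genes containing M common genes, the score is the hypergeometric upper
tail P(X >= m).  Every network gene is tested and the family of N
p-values is Benjamini-Hochberg adjusted; genes below the FDR threshold
(default 1e-8) are flagged as drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import Network

__all__ = [
    "KeyDriverRecord",
    "hypergeom_upper_tail",
    "bh_adjust",
    "identify_key_drivers",
]


@dataclass(frozen=True)
class KeyDriverRecord:
    gene: str
    n_neighbors: int
    m_common: int
    p_raw: float
    p_fdr: float
    is_driver: bool


def hypergeom_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n).

    N population size, M marked items, n draws, m observed marked draws.
    Computed through the survival function (numerically stable in the
    far tail); m = 0 returns exactly 1.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N}, M={M}, n={n}")
    if not 0 <= m <= min(n, M):
        raise ValueError(f"m={m} outside [0, min(n={n}, M={M})]")
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def identify_key_drivers(
    net: Network, common, driver_alpha: float = 1e-8
) -> list[KeyDriverRecord]:
    """Score every network gene for common-gene enrichment of its neighbors.

    Returns one record per network gene, sorted by adjusted p-value then
    symbol.  Genes belonging to the common set are themselves eligible.
    """
    common = set(common)
    if not common:
        raise ValueError("common gene set is empty")
    unknown = common - set(net.genes)
    if unknown:
        raise ValueError(f"common genes not on the network: {sorted(unknown)[:5]}")

    N, M = net.n, len(common)
    rows = []
    for gene in net.genes:
        nbrs = set(net.graph.neighbors(gene))
        n, m = len(nbrs), len(nbrs & common)
        rows.append((gene, n, m, hypergeom_upper_tail(N, M, n, m)))

    p_fdr = bh_adjust([r[3] for r in rows])
    records = [
        KeyDriverRecord(
            gene=g,
            n_neighbors=n,
            m_common=m,
            p_raw=p,
            p_fdr=float(q),
            is_driver=bool(q < driver_alpha),
        )
        for (g, n, m, p), q in zip(rows, p_fdr)
    ]
    records.sort(key=lambda r: (r.p_fdr, r.gene))
    return records
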