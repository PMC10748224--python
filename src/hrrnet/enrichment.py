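"""Hypergeometric over-representation tests per cluster with BH-FDR.

Each cluster is tested against every annotation term it intersects: with
a universe of N genes of which K carry the term, and a cluster of n genes
of which k carry it, the p-value is the hypergeometric upper tail
P(X >= k).  P-values are BH-adjusted within the cluster's own term family
and a term counts as significantly enriched when its FDR clears the
cutoff and at least ``min_genes`` cluster genes carry it.  Raw-p tiers
(significant / highly / very highly) are retained purely as report
labels; the filtering verdict uses the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import AnnotationMap

__all__ = [
    "EnrichmentResult",
    "hypergeom_test",
    "bh_fdr",
    "enrich_cluster",
    "tier_from_p",
    "results_frame",
]

TIERS = (
    (0.001, "very_highly"),
    (0.01, "highly"),
    (0.05, "significant"),
)


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_id: int
    term_id: str
    description: str
    k: int  # cluster genes carrying the term
    n: int  # cluster size
    K: int  # universe genes carrying the term
    N: int  # universe size
    p_value: float
    fdr: float
    tier: str
    significant: bool


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), X ~ Hypergeom(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid universe: n={n}, K={K}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tier_from_p(p: float) -> str:
    for cut, label in TIERS:
        if p < cut:
            return label
    return "ns"


def enrich_cluster(
    cluster_id: int,
    cluster_genes: Iterable[str],
    annot: AnnotationMap,
    min_genes: int = 2,
    fdr_cut: float = 0.05,
) -> tuple[list[EnrichmentResult], bool]:
    """Test every term overlapping the cluster; return results and verdict.

    The verdict is True iff some term has FDR < ``fdr_cut`` and at least
    ``min_genes`` cluster genes carrying it.  A cluster disjoint from the
    universe yields an empty result and a False verdict.
    """
    members = set(cluster_genes) & annot.universe
    n = len(members)
    N = len(annot.universe)
    if n == 0:
        return [], False
    rows = []
    for term in sorted(annot.terms):
        term_genes = annot.terms[term]
        k = len(members & term_genes)
        if k == 0:
            continue
        p = hypergeom_test(k, n, len(term_genes), N)
        rows.append((term, k, len(term_genes), p))
    if not rows:
        return [], False
    fdrs = bh_fdr([p for *_, p in rows])
    results = []
    verdict = False
    for (term, k, K, p), fdr in zip(rows, fdrs):
        sig = bool(fdr < fdr_cut and k >= min_genes)
        verdict = verdict or sig
        results.append(
            EnrichmentResult(
                cluster_id=cluster_id,
                term_id=term,
                description=annot.descriptions.get(term, ""),
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=p,
                fdr=float(fdr),
                tier=tier_from_p(p),
                significant=sig,
            )
        )
    results.sort(key=lambda res: (res.p_value, res.term_id))
    return results, verdict


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per cluster x term)."""
    cols = [
        "cluster_id",
        "term_id",
        "description",
        "k",
        "n",
        "K",
        "N",
        "p_value",
        "fdr",
        "tier",
        "significant",
    ]
    return pd.DataFrame([vars(r) for r in results], columns=cols)
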