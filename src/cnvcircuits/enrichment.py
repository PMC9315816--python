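"""Hypergeometric gene-set over-representation analysis.

For a query of ``n`` genes drawn from a background of ``N`` genes, the
probability that it overlaps a ``K``-gene pathway at least ``k`` times
under random sampling without replacement is the upper tail
``P(X >= k)`` of ``Hypergeometric(N, K, n)``.  A pathway is significant
when its (optionally BH-adjusted) p-value is at or below alpha;
the union of the significant pathways' overlap genes feeds the next
pipeline stage.  Only over-representation is tested — depletion is out
of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneSetCollection, ValidationError, canon_set

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Over-representation of one pathway in a query gene list."""

    pathway: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    adjusted_p: float | None = None
    overlap_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValidationError(
                f"{self.pathway}: k={self.k} outside [0, min(K={self.K}, n={self.n})]"
            )
        if not 0 < self.p_value <= 1:
            raise ValidationError(f"{self.pathway}: p-value {self.p_value} outside (0, 1]")
        if len(self.overlap_genes) != self.k:
            raise ValidationError(
                f"{self.pathway}: overlap gene list size {len(self.overlap_genes)} != k={self.k}"
            )


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    Evaluated through the survival function, which works in log space and
    stays stable for genome-scale ``N``.
    """
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValidationError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    # the true tail is positive whenever k is attainable; guard underflow
    return max(p, 5e-324)


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.001,
    mtc: str = "none",
) -> list[EnrichmentResult]:
    """Test every pathway in ``collection`` for over-representation in ``query``.

    The query is intersected with the background before testing; genes
    absent from the background are dropped (with a logged count), the way
    web enrichment tools treat unrecognised identifiers.  Results are
    sorted by ascending p (ties broken by pathway name).
    """
    if mtc not in ("none", "bh"):
        raise ValidationError(f"mtc must be 'none' or 'bh', got {mtc!r}")
    background = collection.effective_background()
    if not background:
        raise ValidationError("empty background: collection has no sets and no background")
    query_set = canon_set(query)
    dropped = len(query_set - background)
    if dropped:
        logger.info("dropped %d query genes absent from the background", dropped)
    query_in_bg = query_set & background
    N, n = len(background), len(query_in_bg)

    results: list[EnrichmentResult] = []
    for pathway, genes in collection.sets.items():
        genes_in_bg = genes & background
        overlap = frozenset(genes_in_bg & query_in_bg)
        K, k = len(genes_in_bg), len(overlap)
        results.append(
            EnrichmentResult(
                pathway=pathway, N=N, K=K, n=n, k=k,
                p_value=hypergeom_upper_tail(N, K, n, k),
                overlap_genes=overlap,
            )
        )
    if mtc == "bh" and results:
        _, adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def is_significant(result: EnrichmentResult, alpha: float) -> bool:
    """Significance at level alpha, inclusive; uses adjusted p when present."""
    p = result.adjusted_p if result.adjusted_p is not None else result.p_value
    return p <= alpha


def significant_gene_union(
    results: Sequence[EnrichmentResult], alpha: float
) -> set[str]:
    """Union of overlap genes over significant pathways (deduplicated).

    In the clinical analysis this step turns the pathway table into the
    gene list carried to the interaction filters (the 61-pathway /
    659-gene analogue).
    """
    out: set[str] = set()
    for r in results:
        if is_significant(r, alpha):
            out |= r.overlap_genes
    return out


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "N": [r.N for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "k": [r.k for r in results],
            "p": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "overlap_genes": [",".join(sorted(r.overlap_genes)) for r in results],
        }
    )


def write_results(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
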