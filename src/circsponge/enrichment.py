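"""Hypergeometric over-representation analysis of a gene set.

Given a query gene set (here: the miRNA-targeted, upregulated DE genes of
the sponge network), a collection of annotated gene sets (GMT) and a gene
universe, each term is tested for enrichment with the one-sided
hypergeometric (Fisher exact) upper tail:

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the universe size, K the term size within the universe, n the
query size within the universe and k the observed overlap.  p-values are
Benjamini-Hochberg adjusted across the collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

__all__ = ["GeneSet", "EnrichmentResult", "hypergeom_enrich"]


@dataclass(frozen=True)
class GeneSet:
    """One annotated gene set (a GMT line)."""

    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.term_id!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    k: int  # overlap count
    K: int  # term size in universe
    n: int  # query size in universe
    N: int  # universe size
    p: float
    adj_p: float


def hypergeom_enrich(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Test every term in ``collection`` for over-representation of ``query``.

    Query genes outside the universe are dropped with a warning.  Results
    are sorted by p ascending, ties broken by term_id.
    """
    from .diffexp import bh_adjust  # local import avoids a cycle at import time

    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query_set = frozenset(query)
    outside = query_set - universe_set
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
    query_set &= universe_set

    N = len(universe_set)
    n = len(query_set)
    rows: list[tuple[str, str, int, int, float]] = []
    for gs in collection:
        term_in_universe = gs.genes & universe_set
        K = len(term_in_universe)
        k = len(term_in_universe & query_set)
        # upper tail P(X >= k); sf is P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((gs.term_id, gs.name, k, K, min(1.0, p)))

    adj = bh_adjust([r[4] for r in rows]) if rows else []
    results = [
        EnrichmentResult(term_id=t, name=nm, k=k, K=K, n=n, N=N, p=p, adj_p=a)
        for (t, nm, k, K, p), a in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
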