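"""One-sided Fisher's-exact (hypergeometric) overrepresentation testing.

For a query gene list of effective size n drawn against a background of N
genes, a term with K background members and k query hits has

    p = sum_{i=k}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n),

the upper tail of the hypergeometric distribution -- the probability of
seeing at least k term members in the query under random sampling without
replacement.  Underrepresentation is out of scope.  Multiple-testing
correction (Benjamini-Hochberg by default, Bonferroni or none on request)
is applied within each ontology category separately, and ranking takes the
top N terms per category by ascending p with ties broken by term id.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap, GoCategory

__all__ = [
    "Correction",
    "EnrichmentResult",
    "fisher_overrepresentation",
    "enrich_all",
    "top_terms",
]

logger = logging.getLogger(__name__)


class Correction(enum.Enum):
    BH = "bh"
    BONFERRONI = "bonferroni"
    NONE = "none"


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    category: GoCategory
    k: int  # query hits in term
    n: int  # effective query size
    K: int  # background hits in term
    N: int  # background size
    expected: float  # n * K / N
    fold_enrichment: float  # (k/n) / (K/N); inf-free because K >= 1 is enforced
    p_value: float
    fdr: float


def fisher_overrepresentation(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value for overrepresentation.

    Requires 0 <= k <= n <= N and k <= K <= N.  Evaluated through scipy's
    log-space survival function; k = 0 and K = N both force p = 1.
    """
    if not (0 <= k <= n <= N):
        raise ValueError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (k <= K <= N):
        raise ValueError(f"need k <= K <= N, got k={k}, K={K}, N={N}")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def enrich_all(
    query: Iterable[str],
    annotation: AnnotationMap,
    background: Iterable[str],
    correction: Correction | str = Correction.BH,
    aliases: Optional[dict[str, str]] = None,
) -> list[EnrichmentResult]:
    """Test every annotation term with >=1 background member against the query.

    Query genes outside the background are dropped (with a logged count)
    before counting; k, n, K, N are all computed on the background-restricted
    universe.  Gene identity is case-sensitive exact match; ``aliases`` (e.g.
    from :func:`baitcall.io.read_alias_map`) translates query and background
    identifiers into the annotation's namespace first.  The FDR column is
    corrected within each ontology category separately.  Results come back in
    annotation order; use :func:`top_terms` for ranking.
    """
    correction = Correction(correction) if isinstance(correction, str) else correction
    if aliases:
        query = {aliases.get(g, g) for g in query}
        background = {aliases.get(g, g) for g in background}
    bg = frozenset(background)
    if not bg:
        raise ValueError("background must be non-empty")
    query_set = frozenset(query)
    effective = query_set & bg
    dropped = len(query_set) - len(effective)
    if dropped:
        logger.info("dropped %d query genes absent from the background", dropped)
    if not effective:
        raise ValueError("no query genes remain after background restriction")
    n, N = len(effective), len(bg)

    results: list[EnrichmentResult] = []
    for term in annotation:
        members = term.members & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & effective)
        expected = n * K / N
        results.append(
            EnrichmentResult(
                term_id=term.term_id,
                term_name=term.name,
                category=term.category,
                k=k,
                n=n,
                K=K,
                N=N,
                expected=expected,
                fold_enrichment=(k / expected) if expected else 0.0,
                p_value=fisher_overrepresentation(k, n, K, N),
                fdr=1.0,  # filled below
            )
        )
    return _apply_correction(results, correction)


def _apply_correction(
    results: list[EnrichmentResult], correction: Correction
) -> list[EnrichmentResult]:
    corrected: dict[str, float] = {}
    for category in GoCategory:
        in_cat = [r for r in results if r.category is category]
        if not in_cat:
            continue
        pvals = [r.p_value for r in in_cat]
        if correction is Correction.NONE:
            adjusted = pvals
        else:
            method = "fdr_bh" if correction is Correction.BH else "bonferroni"
            adjusted = list(multipletests(pvals, method=method)[1])
        for r, fdr in zip(in_cat, adjusted):
            corrected[r.term_id] = float(fdr)
    return [
        EnrichmentResult(**{**r.__dict__, "fdr": corrected[r.term_id]})
        for r in results
    ]


def top_terms(
    results: Sequence[EnrichmentResult],
    n: int = 10,
    category: Optional[GoCategory] = None,
) -> list[EnrichmentResult]:
    """Top ``n`` results of a category by ascending p, ties by term id.

    Fewer than ``n`` results are returned when fewer exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = [r for r in results if category is None or r.category is category]
    pool.sort(key=lambda r: (r.p_value, r.term_id))
    return pool[:n]
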