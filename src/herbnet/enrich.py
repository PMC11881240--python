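"""Functional-term enrichment: upper-tail hypergeometric tests with BH control.

Given a query gene set, a term -> gene-set annotation map and a background
universe, each term is tested for over-representation with the hypergeometric
distribution (P(X >= k) with N = background size, K = term size, n = query
size, k = query hits in the term) and the p-values are adjusted across terms
with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int          # query hits in the term
    K: int          # term size within the background
    n: int          # query size
    N: int          # background size
    p_value: float
    p_adjusted: float


def overlap(set_a: set, set_b: set) -> set:
    """Intersection of two id sets (e.g. disease targets vs prescription targets)."""
    return set(set_a) & set(set_b)


def hypergeom_enrich(
    query: set[str],
    term_map: dict[str, set[str]],
    background: set[str] | None = None,
    min_term_size: int = 2,
) -> list[EnrichmentResult]:
    """Per-term upper-tail hypergeometric enrichment with BH adjustment.

    ``background`` defaults to the union of all term-annotated ids. The query
    must be a subset of the background. Terms with fewer than
    ``min_term_size`` background members are untestable and skipped. Results
    are sorted by p-value. With k = 0 the upper tail P(X >= 0) is exactly 1.
    """
    if background is None:
        background = set().union(*term_map.values()) if term_map else set()
    background = set(background)
    query = set(query)
    stray = query - background
    if stray:
        raise ValueError(
            "query ids missing from background: " + ", ".join(sorted(stray)[:10])
        )
    n_bg, n_q = len(background), len(query)

    rows = []
    for term_id in sorted(term_map):
        members = set(term_map[term_id]) & background
        big_k = len(members)
        if big_k < min_term_size:
            logger.info("term %s skipped (size %d < %d)", term_id, big_k, min_term_size)
            continue
        k = len(members & query)
        # upper tail P(X >= k) = survival function at k - 1
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_q))
        rows.append((term_id, k, big_k, p))

    if not rows:
        return []
    _, p_adj, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    results = [
        EnrichmentResult(term_id, k, big_k, n_q, n_bg, p, float(pa))
        for (term_id, k, big_k, p), pa in zip(rows, p_adj)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.term_id))
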