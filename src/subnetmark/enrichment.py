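"""Gene-set over-representation with the fold-enrichment statistic.

For a query gene set against annotation terms drawn from a background of N
genes: expected = |query| * |term| / N under proportional sampling, fold
enrichment FE = observed / expected, and the p-value is the hypergeometric
upper tail P(X >= observed). One-sided over-representation only; BH-adjusted
p-values are reported alongside the raw ones as multiple-testing hygiene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from subnetmark.data_io import AnnotationSets, ValidationError
from subnetmark.diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    term_id: str
    observed: int
    expected: float
    fold_enrichment: float
    p_value: float
    adj_p: float | None = None


def enrich(query: set[str], sets: AnnotationSets) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each annotation term.

    Query genes outside the background are dropped with a warning. Results
    are sorted by raw p ascending (ties by term id). An observed count of 0
    gives FE = 0 and p = 1.
    """
    background = sets.effective_background()
    if not background or not sets.sets:
        raise ValidationError("background and term sets must be non-empty")
    outside = query - background
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the background were dropped"
        )
    query = query & background
    if not query:
        raise ValidationError("no query gene inside the background")

    n_bg = len(background)
    n_query = len(query)
    results = []
    for term, genes in sets.sets.items():
        term_in_bg = genes & background
        observed = len(query & term_in_bg)
        expected = n_query * len(term_in_bg) / n_bg
        fe = observed / expected if expected > 0 else 0.0
        # upper tail P(X >= observed), hypergeom(M=N, n=|term|, N=|query|)
        p = 1.0 if observed == 0 else float(
            stats.hypergeom.sf(observed - 1, n_bg, len(term_in_bg), n_query)
        )
        results.append(
            EnrichmentResult(
                term_id=term,
                observed=observed,
                expected=expected,
                fold_enrichment=fe,
                p_value=min(p, 1.0),
            )
        )
    adjusted = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adjusted):
        r.adj_p = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term_id for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "fold_enrichment": [r.fold_enrichment for r in results],
            "p_value": [r.p_value for r in results],
            "adj_p": [r.adj_p for r in results],
        }
    ).set_index("term")
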