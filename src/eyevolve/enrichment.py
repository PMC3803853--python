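"""Homology transfer of GO annotations and term over-representation tests.

Contigs inherit the union of GO terms of every reference protein they hit at
or below the annotation e-value cutoff (1e-10, the study's transfer
threshold).  Over-representation between the two species' up-regulated
contig sets is then tested per term with a one-sided Fisher's exact test
(hypergeometric tail) on the 2x2 table

    a = test contigs with the term        b = reference contigs with the term
    c = test contigs without the term     d = reference contigs without it

and corrected with Benjamini-Hochberg FDR.  Annotations are used flat: no
GO-graph ancestor propagation is performed.  A two-tailed variant is kept
behind a switch since tools differ on this point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import logger


def transfer_annotations(hits: pd.DataFrame, go_map: pd.DataFrame,
                         e_cutoff: float = 1e-10) -> dict[str, set[str]]:
    """contig id -> set of GO ids inherited from qualifying hits."""
    protein_terms: dict[str, set[str]] = {}
    for pid, sub in go_map.groupby("protein_id"):
        protein_terms[pid] = set(sub.go_id)
    out: dict[str, set[str]] = {}
    qualifying = hits[hits.evalue <= e_cutoff]
    for row in qualifying.itertuples():
        terms = protein_terms.get(row.subject_id)
        if terms:
            out.setdefault(row.contig_id, set()).update(terms)
    return out


def fisher_term(a: int, b: int, c: int, d: int, two_tailed: bool = False) -> float:
    """P-value for over-representation of a term in the test set.

    One-sided: the hypergeometric tail ``P[X >= a]`` with all margins fixed
    (``scipy.stats.fisher_exact`` with ``alternative='greater'``).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b + c + d == 0:
        return 1.0
    alternative = "two-sided" if two_tailed else "greater"
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, clipped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    go_id: str
    a: int
    b: int
    c: int
    d: int
    direction: str        # "over": enriched in test set; "under": in reference
    p_value: float
    q_value: float
    significant: bool


def enrich(test_set: Iterable[str], reference_set: Iterable[str],
           contig_go: Mapping[str, set[str]], alpha: float = 0.05,
           two_tailed: bool = False) -> list[EnrichmentResult]:
    """Test every GO term seen in either set; BH-significant at ``alpha``.

    Only annotated contigs enter the 2x2 tables.  Results are ordered by
    q-value then go id; swapping the two sets flips each ``direction``.
    """
    test = set(test_set)
    ref = set(reference_set)
    if test & ref:
        raise ValueError("test and reference sets must be disjoint")
    test_annotated = [c for c in sorted(test) if contig_go.get(c)]
    ref_annotated = [c for c in sorted(ref) if contig_go.get(c)]
    if not test_annotated or not ref_annotated:
        logger.warning("a set has no annotated contigs; no enrichment computed")
        return []
    terms = sorted({t for c in test_annotated + ref_annotated
                    for t in contig_go[c]})
    rows = []
    for term in terms:
        a = sum(1 for c in test_annotated if term in contig_go[c])
        b = sum(1 for c in ref_annotated if term in contig_go[c])
        c_ = len(test_annotated) - a
        d = len(ref_annotated) - b
        if two_tailed:
            p = fisher_term(a, b, c_, d, two_tailed=True)
            direction = "over" if a * (b + d) >= b * (a + c_) else "under"
        else:
            p_over = fisher_term(a, b, c_, d)
            p_under = fisher_term(b, a, d, c_)
            direction, p = (("over", p_over) if p_over <= p_under
                            else ("under", p_under))
        rows.append((term, a, b, c_, d, direction, p))
    q = bh_fdr([r[6] for r in rows])
    results = [
        EnrichmentResult(term, a, b, c_, d, direction, p, float(qv),
                         bool(qv <= alpha))
        for (term, a, b, c_, d, direction, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.q_value, r.go_id))
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"go_id": r.go_id, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
          "direction": r.direction, "p": r.p_value, "q": r.q_value,
          "significant": r.significant} for r in results],
        columns=["go_id", "a", "b", "c", "d", "direction", "p", "q",
                 "significant"])
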