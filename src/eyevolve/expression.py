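"""Normalized average coverage and selection of up-regulated contigs.

Expression of a contig is its average per-base coverage
(``aligned_bases / contig_length``), rescaled so the two samples are
comparable despite different sequencing depth: each sample's coverages are
multiplied by ``mean(sample totals) / total(sample)``, which preserves the
total normalized mass.  A contig is called up-regulated in sample A iff its
normalized coverage there is at least ``min_cov`` (10, non-strict) and
*more than* ``fold`` (2, strict) times its coverage in the other sample —
the strict/non-strict reading mirrors the study's wording exactly.
"""

from __future__ import annotations

import pandas as pd

from .io import logger


def normalized_coverage(coverage: pd.DataFrame) -> pd.DataFrame:
    """Add a ``normalized_coverage`` column to a coverage table.

    Requires both samples present with nonzero total aligned bases.
    Contigs absent from one sample are treated as coverage 0 there (they
    simply have no row).
    """
    required = {"contig_id", "sample", "aligned_bases", "contig_length"}
    if not required.issubset(coverage.columns):
        raise ValueError(f"coverage table needs columns {sorted(required)}")
    samples = sorted(coverage["sample"].unique())
    if len(samples) != 2:
        raise ValueError(f"need exactly two samples, got {samples}")
    totals = coverage.groupby("sample")["aligned_bases"].sum()
    if (totals <= 0).any():
        raise ValueError("a sample has zero total aligned bases")
    mean_total = totals.mean()
    out = coverage.copy()
    raw = out["aligned_bases"] / out["contig_length"]
    out["normalized_coverage"] = raw * out["sample"].map(mean_total / totals)
    return out


def select_candidates(normalized: pd.DataFrame, min_cov: float = 10.0,
                      fold: float = 2.0) -> dict[str, set[str]]:
    """Per-sample sets of adequately expressed, up-regulated contigs.

    The two sets are disjoint for any input (strict fold requirement).
    """
    if "normalized_coverage" not in normalized.columns:
        raise ValueError("run normalized_coverage() first")
    wide = normalized.pivot_table(index="contig_id", columns="sample",
                                  values="normalized_coverage",
                                  fill_value=0.0, aggfunc="sum")
    a, b = sorted(wide.columns)
    up: dict[str, set[str]] = {}
    up[a] = set(wide.index[(wide[a] >= min_cov) & (wide[a] > fold * wide[b])])
    up[b] = set(wide.index[(wide[b] >= min_cov) & (wide[b] > fold * wide[a])])
    assert not (up[a] & up[b])
    logger.debug("up-regulated: %s=%d, %s=%d", a, len(up[a]), b, len(up[b]))
    return up
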