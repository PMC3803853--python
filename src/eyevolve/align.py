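"""Protein and nucleotide pairwise alignment.

The pipeline needs three alignment flavours:

* Smith-Waterman local alignment of a translated contig segment against a
  reference protein (the unit step of the blastx-style search);
* global alignment of the human/fly homologue pair, to put hit intervals on
  a common coordinate frame and to measure window conservation;
* global nucleotide alignment of two contigs with free end gaps, for the
  <95% similarity criterion of duplication calls (contigs are fragments of
  unequal length, so terminal gaps are not evidence of divergence).

All three are computed with :class:`Bio.Align.PairwiseAligner` under one
affine gap model: a gap of length g costs ``gap_open + (g - 1) * gap_extend``
(the opening residue pays ``gap_open``).  The scoring constants live in
:class:`ScoringScheme` so they are configurable and appear in run reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import NamedTuple

from Bio import Align
from Bio.Align import substitution_matrices

#: number of co-optimal alignments examined when applying the deterministic
#: tie-break (smallest subject start, then smallest query start)
_MAX_OPTIMAL = 64


@dataclass(frozen=True)
class ScoringScheme:
    """BLOSUM62 affine-gap scoring plus gapped Karlin-Altschul constants.

    The defaults (open 11, extend 1, lambda 0.267, K 0.041) are the standard
    gapped BLASTP constants for BLOSUM62.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open < self.gap_extend or self.gap_extend < 1:
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


class LocalAlignment(NamedTuple):
    """Optimal local alignment: raw score, 1-based inclusive intervals, identity.

    ``query_interval``/``subject_interval`` are ``None`` when no
    positive-scoring alignment exists (``raw_score`` 0).  ``identity`` is the
    fraction of alignment columns (gap columns included) with equal residues.
    """

    raw_score: int
    query_interval: tuple[int, int] | None
    subject_interval: tuple[int, int] | None
    identity: float


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int, mode: str,
             free_end_gaps: bool = False) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = _load_matrix(matrix_name)
    a.open_gap_score = -float(gap_open)
    a.extend_gap_score = -float(gap_extend)
    a.mode = mode
    if free_end_gaps:
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    return a


def _alignment_stats(alignment) -> tuple[tuple[int, int], tuple[int, int], float]:
    """Intervals (1-based inclusive, query then subject) and identity."""
    blocks_t, blocks_q = alignment.aligned  # target == first sequence passed
    q0, q1 = int(blocks_t[0][0]), int(blocks_t[-1][1])
    s0, s1 = int(blocks_q[0][0]), int(blocks_q[-1][1])
    target, query = str(alignment.target), str(alignment.query)
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        aligned_cols += te - ts
        matches += sum(
            1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b
        )
    # columns = substitution columns + internal gap columns
    columns = aligned_cols + (q1 - q0 - aligned_cols) + (s1 - s0 - aligned_cols)
    identity = matches / columns if columns else 0.0
    return (q0 + 1, q1), (s0 + 1, s1), identity


def local_align(query: str, subject: str, scheme: ScoringScheme | None = None) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment under ``scheme``.

    Returns score 0 (and ``None`` intervals) when no positive-scoring local
    alignment exists.  Among co-optimal alignments the one with the smallest
    subject start, then the smallest query start, is reported.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend, "local")
    score = aligner.score(query, subject)
    if score <= 0:
        return LocalAlignment(0, None, None, 0.0)
    best = None
    for alignment in itertools.islice(aligner.align(query, subject), _MAX_OPTIMAL):
        qiv, siv, ident = _alignment_stats(alignment)
        key = (siv[0], qiv[0])
        if best is None or key < best[0]:
            best = (key, qiv, siv, ident)
    assert best is not None
    return LocalAlignment(int(score), best[1], best[2], best[3])


def local_score(query: str, subject: str, scheme: ScoringScheme | None = None) -> int:
    """Score-only variant of :func:`local_align` (no traceback)."""
    scheme = scheme or ScoringScheme()
    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend, "local")
    return max(0, int(aligner.score(query, subject)))


def global_align(a: str, b: str, scheme: ScoringScheme | None = None) -> tuple[str, str]:
    """Global (Needleman-Wunsch) alignment; returns the two gapped rows."""
    scheme = scheme or ScoringScheme()
    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend, "global")
    alignment = next(iter(aligner.align(a, b)))
    return _gapped_rows(alignment)


def _gapped_rows(alignment) -> tuple[str, str]:
    blocks_t, blocks_q = alignment.aligned
    target, query = str(alignment.target), str(alignment.query)
    out_t: list[str] = []
    out_q: list[str] = []
    pt = pq = 0
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if ts > pt:
            out_t.append(target[pt:ts])
            out_q.append("-" * (ts - pt))
        if qs > pq:
            out_t.append("-" * (qs - pq))
            out_q.append(query[pq:qs])
        out_t.append(target[ts:te])
        out_q.append(query[qs:qe])
        pt, pq = te, qe
    if pt < len(target):
        out_t.append(target[pt:])
        out_q.append("-" * (len(target) - pt))
    if pq < len(query):
        out_t.append("-" * (len(query) - pq))
        out_q.append(query[pq:])
    rt, rq = "".join(out_t), "".join(out_q)
    assert len(rt) == len(rq)
    return rt, rq


#: simple DNA scoring for contig-contig comparisons (match/mismatch model)
_DNA_MATCH, _DNA_MISMATCH = 2.0, -3.0
_DNA_OPEN, _DNA_EXTEND = 5.0, 2.0


@lru_cache(maxsize=2)
def _dna_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.match_score = _DNA_MATCH
    a.mismatch_score = _DNA_MISMATCH
    a.open_gap_score = -_DNA_OPEN
    a.extend_gap_score = -_DNA_EXTEND
    a.mode = "global"
    a.end_insertion_score = 0.0
    a.end_deletion_score = 0.0
    return a


def dna_global_identity(a: str, b: str) -> float:
    """Nucleotide identity of two contigs from a free-end-gap global alignment.

    Identity = matched columns / length of the shorter contig.  Terminal
    gaps are free in the alignment (contigs are fragments of unequal
    length), but the denominator is the shorter sequence, not the aligned
    overlap: otherwise two unrelated contigs sharing a short perfect
    overlap would score as near-identical.  This is the statistic tested
    against the 95% duplication-similarity criterion.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignment = next(iter(_dna_aligner().align(a, b)))
    rt, rq = _gapped_rows(alignment)
    matches = sum(1 for x, y in zip(rt, rq) if x == y and x != "-")
    return matches / min(len(a), len(b))
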