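"""Blastx-style translated homology search and best-hit selection.

A contig is translated in six frames, segments are aligned locally against
every reference protein, and the best alignment per contig x protein pair is
scored with Karlin-Altschul statistics.  Two engines produce the same
tabular contract (``HIT_SCHEMA`` in :mod:`eyevolve.io`):

``native``
    The package's own exact engine: :func:`eyevolve.translate.six_frame_translate`
    plus Smith-Waterman alignment of every segment against every subject.
    An exact composition bound (sum of each residue's best matrix score)
    prunes segments that cannot reach the e-value cutoff; scores are never
    approximated.  Intended for small inputs and for validating the scale
    engine.

``blastx``
    The NCBI BLAST+ command-line tools (``makeblastdb``/``blastx``), run
    single-threaded with composition-based statistics and low-complexity
    filtering disabled so results are deterministic and matrix-driven.
    This is the engine the pipeline uses at transcriptome scale.

Best-hit selection is total and deterministic: highest bit score, then
lowest e-value, then lexicographically smallest subject id.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import ScoringScheme, local_align, local_score
from .io import HIT_SCHEMA, SequenceRecord, logger, write_fasta
from .translate import six_frame_translate

HIT_COLUMNS = list(HIT_SCHEMA)


def bit_score_evalue(raw_score: float, query_len: int, db_len: int,
                     scheme: ScoringScheme | None = None) -> tuple[float, float]:
    """Karlin-Altschul normalized score and expectation.

    ``bit = (lambda * raw - ln K) / ln 2`` and ``e = m * n * 2**(-bit)``
    with the plain search space ``m * n`` (no length corrections; e-values
    are used for thresholding and ranking only).
    """
    if query_len <= 0 or db_len <= 0:
        raise ValueError("search-space dimensions must be positive")
    scheme = scheme or ScoringScheme()
    bits = (scheme.ka_lambda * raw_score - math.log(scheme.ka_k)) / math.log(2.0)
    evalue = query_len * db_len * 2.0 ** (-bits)
    return bits, evalue


def _min_raw_score(query_len: int, db_len: int, e_cutoff: float,
                   scheme: ScoringScheme) -> int:
    """Smallest integer raw score whose e-value passes ``e_cutoff`` (exact)."""
    if e_cutoff <= 0:
        return np.iinfo(np.int32).max
    bits_needed = math.log2(query_len * db_len / e_cutoff)
    raw = (bits_needed * math.log(2.0) + math.log(scheme.ka_k)) / scheme.ka_lambda
    return max(0, math.ceil(raw - 1e-9))


def _max_row_scores(scheme: ScoringScheme) -> dict[str, float]:
    m = scheme.matrix
    return {aa: max(m[aa, bb] for bb in m.alphabet) for aa in m.alphabet}


def search_native(contigs: Sequence[SequenceRecord],
                  proteomes: Mapping[str, Sequence[SequenceRecord]],
                  scheme: ScoringScheme | None = None,
                  e_cutoff: float = 1e-3,
                  min_contig_len: int = 100) -> pd.DataFrame:
    """Exact all-vs-all translated search (see module docstring)."""
    scheme = scheme or ScoringScheme()
    subjects = [(org, rec) for org, recs in proteomes.items() for rec in recs]
    db_len = sum(len(rec.sequence) for _, rec in subjects)
    if db_len == 0:
        logger.warning("empty proteome: search returns no hits")
        return pd.DataFrame(columns=HIT_COLUMNS)
    maxrow = _max_row_scores(scheme)
    rows: list[dict] = []
    for contig in contigs:
        m = len(contig.sequence)
        if m <= min_contig_len:
            continue
        segments = six_frame_translate(contig.sequence)
        raw_min = _min_raw_score(m, db_len, e_cutoff, scheme)
        seg_bounds = [sum(maxrow.get(aa, 0.0) for aa in s.sequence) for s in segments]
        candidates = [s for s, b in zip(segments, seg_bounds) if b >= raw_min]
        if not candidates:
            continue
        for org, subject in subjects:
            best = None  # (raw, segment, alignment)
            for seg in candidates:
                raw = local_score(seg.sequence, subject.sequence, scheme)
                if best is None or raw > best[0]:
                    best = (raw, seg)
            if best is None or best[0] < raw_min:
                continue
            raw, seg = best
            aln = local_align(seg.sequence, subject.sequence, scheme)
            bits, evalue = bit_score_evalue(raw, m, db_len, scheme)
            if evalue > e_cutoff:
                continue
            qiv = seg.nt_interval(aln.query_interval[0], aln.query_interval[1], m)
            rows.append(dict(
                contig_id=contig.id, subject_id=subject.id, organism=org,
                frame=seg.frame, qstart=qiv[0], qend=qiv[1],
                sstart=aln.subject_interval[0], send=aln.subject_interval[1],
                raw=float(raw), bits=bits, evalue=evalue, identity=aln.identity,
            ))
    return _finalize(pd.DataFrame(rows, columns=HIT_COLUMNS))


_BLAST_FIELDS = ("qseqid sseqid qstart qend sstart send score bitscore "
                 "evalue pident length qframe")


def search_blastx(contigs: Sequence[SequenceRecord],
                  proteomes: Mapping[str, Sequence[SequenceRecord]],
                  scheme: ScoringScheme | None = None,
                  e_cutoff: float = 1e-3,
                  min_contig_len: int = 100,
                  workdir: str | Path | None = None) -> pd.DataFrame:
    """Translated search through the NCBI BLAST+ CLI (same contract as native)."""
    scheme = scheme or ScoringScheme()
    if shutil.which("blastx") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("NCBI BLAST+ (blastx/makeblastdb) not found on PATH")
    organism_of = {rec.id: org for org, recs in proteomes.items() for rec in recs}
    subjects = [rec for recs in proteomes.values() for rec in recs]
    kept = [c for c in contigs if len(c.sequence) > min_contig_len]
    if not subjects:
        logger.warning("empty proteome: search returns no hits")
        return pd.DataFrame(columns=HIT_COLUMNS)
    if not kept:
        return pd.DataFrame(columns=HIT_COLUMNS)
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        qpath, spath = tmp / "query.fasta", tmp / "db.fasta"
        write_fasta(kept, qpath)
        write_fasta(subjects, spath)
        subprocess.run(
            ["makeblastdb", "-in", str(spath), "-dbtype", "prot",
             "-out", str(tmp / "db")],
            check=True, capture_output=True,
        )
        out = tmp / "hits.tsv"
        subprocess.run(
            ["blastx", "-query", str(qpath), "-db", str(tmp / "db"),
             "-outfmt", f"6 {_BLAST_FIELDS}",
             "-evalue", str(e_cutoff), "-max_target_seqs", "10000",
             "-num_threads", "1", "-seg", "no", "-comp_based_stats", "0",
             "-matrix", scheme.matrix_name,
             "-gapopen", str(scheme.gap_open), "-gapextend", str(scheme.gap_extend),
             "-out", str(out)],
            check=True, capture_output=True,
        )
        raw = pd.read_csv(out, sep="\t", names=_BLAST_FIELDS.split(),
                          dtype={"qseqid": str, "sseqid": str})
    if raw.empty:
        return pd.DataFrame(columns=HIT_COLUMNS)
    qlo = raw[["qstart", "qend"]].min(axis=1)
    qhi = raw[["qstart", "qend"]].max(axis=1)
    df = pd.DataFrame({
        "contig_id": raw.qseqid,
        "subject_id": raw.sseqid,
        "organism": raw.sseqid.map(organism_of),
        "frame": raw.qframe.astype(int),
        "qstart": qlo.astype(int), "qend": qhi.astype(int),
        "sstart": raw.sstart.astype(int), "send": raw.send.astype(int),
        "raw": raw.score.astype(float), "bits": raw.bitscore.astype(float),
        "evalue": raw.evalue.astype(float),
        "identity": raw.pident.astype(float) / 100.0,
    })
    # one HSP per contig x subject: highest raw score, then lowest e-value,
    # then smallest subject start
    df = df.sort_values(
        ["contig_id", "subject_id", "raw", "evalue", "sstart", "qstart"],
        ascending=[True, True, False, True, True, True], kind="mergesort")
    df = df.drop_duplicates(["contig_id", "subject_id"], keep="first")
    return _finalize(df)


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df.reindex(columns=HIT_COLUMNS)
    df = df.sort_values(["contig_id", "bits", "subject_id"],
                        ascending=[True, False, True], kind="mergesort")
    return df.reset_index(drop=True)[HIT_COLUMNS]


def search(contigs: Sequence[SequenceRecord],
           proteomes: Mapping[str, Sequence[SequenceRecord]],
           scheme: ScoringScheme | None = None,
           e_cutoff: float = 1e-3,
           min_contig_len: int = 100,
           engine: str = "native",
           workdir: str | Path | None = None) -> pd.DataFrame:
    """Run the translated search with the selected engine."""
    if engine == "native":
        return search_native(contigs, proteomes, scheme, e_cutoff, min_contig_len)
    if engine == "blastx":
        return search_blastx(contigs, proteomes, scheme, e_cutoff,
                             min_contig_len, workdir)
    raise ValueError(f"unknown search engine {engine!r}")


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One winning hit per contig (bit score, then e-value, then subject id)."""
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(["contig_id", "bits", "evalue", "subject_id"],
                               ascending=[True, False, True, True],
                               kind="mergesort")
    return ordered.drop_duplicates("contig_id", keep="first").reset_index(drop=True)


def best_hit(hits: pd.DataFrame, contig_id: str) -> pd.Series | None:
    """The winning hit for one contig, or ``None`` (reported, not fatal)."""
    sub = hits[hits.contig_id == contig_id]
    if sub.empty:
        logger.warning("contig %s has no hits; no assignment", contig_id)
        return None
    return best_hits(sub).iloc[0]
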