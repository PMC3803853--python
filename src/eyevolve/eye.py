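"""Eye-related contig extraction with whole-proteome best-hit QC.

The workflow mirrors the study's scheme: select the reference proteins whose
GO annotations are eye-related, collect every contig with a qualifying hit
to one of them (the *raw* eye contigs), then keep only contigs whose
whole-proteome best hit is itself eye-related (quality control).  The
surviving record carries the whole-proteome best hit and its origin label
(human-best vs fly-best).

"Eye-related" is decided by the explicit eye flag when the annotation table
carries one (synthetic data), and otherwise by case-insensitive substring
match of the configured keyword list against term names (the study searched
UniProt for "eye", "lens", "retina", "photoreceptor", "R1/R6", "R2/R5",
"R3/R4", "R7", "R8").
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .io import logger
from .search import best_hits

EYE_TERMS = ("eye", "lens", "retina", "photoreceptor",
             "r1/r6", "r2/r5", "r3/r4", "r7", "r8")

ASSIGNMENT_COLUMNS = ["contig_id", "species", "subject_id", "origin", "bits",
                      "evalue", "sstart", "send", "eye_related", "qc_pass"]


def select_eye_proteins(go_map: pd.DataFrame,
                        organism_of: Mapping[str, str],
                        terms: Iterable[str] = EYE_TERMS) -> dict[str, set[str]]:
    """Per-organism sets of eye-related reference proteins.

    A protein qualifies iff one of its terms carries the eye flag (when the
    table has any flags set) or its term name contains one of ``terms``.
    """
    terms = [t.lower() for t in terms]
    if not terms:
        raise ValueError("empty eye term list")
    use_flag = "eye_flag" in go_map.columns and (go_map.eye_flag.astype(int) > 0).any()
    if use_flag:
        eye_rows = go_map[go_map.eye_flag.astype(int) > 0]
    else:
        names = go_map.go_name.str.lower()
        eye_rows = go_map[names.apply(lambda n: any(t in n for t in terms))]
    out: dict[str, set[str]] = {}
    for pid in eye_rows.protein_id.unique():
        org = organism_of.get(pid)
        if org is None:
            logger.warning("eye protein %s has no organism assignment", pid)
            continue
        out.setdefault(org, set()).add(pid)
    return out


def raw_eye_contigs(hits: pd.DataFrame, eye_sets: Mapping[str, set[str]],
                    e_cutoff: float) -> set[str]:
    """Contigs with at least one qualifying hit to an eye protein."""
    if not any(eye_sets.values()):
        raise ValueError("eye protein sets are empty")
    eye_proteins = set().union(*eye_sets.values())
    qualifying = hits[(hits.evalue <= e_cutoff)
                      & hits.subject_id.isin(eye_proteins)]
    return set(qualifying.contig_id)


def qc_best_hits(raw_set: Iterable[str], hits: pd.DataFrame,
                 eye_sets: Mapping[str, set[str]], species: str,
                 strict: bool = False) -> pd.DataFrame:
    """Assignment records for raw eye contigs, QC'd against best hits.

    A contig passes QC iff its whole-proteome best hit is eye-related
    (``strict=False``, the default reading) or is exactly its best
    eye-subset hit (``strict=True``).  The final set is always a subset of
    the raw set.
    """
    eye_proteins = set().union(*eye_sets.values()) if eye_sets else set()
    winners = best_hits(hits)
    by_contig = {r.contig_id: r for r in winners.itertuples()}
    eye_winners = best_hits(hits[hits.subject_id.isin(eye_proteins)])
    eye_best = {r.contig_id: r.subject_id for r in eye_winners.itertuples()}
    rows = []
    for cid in sorted(set(raw_set)):
        best = by_contig.get(cid)
        if best is None:
            logger.warning("raw eye contig %s has no whole-proteome hit", cid)
            continue
        if strict:
            qc = best.subject_id == eye_best.get(cid)
        else:
            qc = best.subject_id in eye_proteins
        rows.append({
            "contig_id": cid, "species": species, "subject_id": best.subject_id,
            "origin": best.organism, "bits": best.bits, "evalue": best.evalue,
            "sstart": best.sstart, "send": best.send,
            "eye_related": True, "qc_pass": bool(qc),
        })
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
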