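"""Readers and writers for the plain-text formats the pipeline exchanges.

All sequence and tabular traffic goes through this module so that validation
(unique ids, declared alphabets, typed columns) happens in one place.  FASTA
parsing is delegated to :mod:`Bio.SeqIO`; tables to :mod:`pandas`.

Coordinate convention used throughout the package: intervals are 1-based and
inclusive, on protein residues for subjects and on nucleotides for contigs
(the BLAST convention).  Sequence ids are the FASTA header token before the
first whitespace.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger("eyevolve")

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

#: canonical column -> dtype schemas for the pipeline's TSV contracts
COVERAGE_SCHEMA = {
    "contig_id": str,
    "sample": str,
    "aligned_bases": float,
    "contig_length": int,
}
GO_SCHEMA = {"protein_id": str, "go_id": str, "go_name": str, "eye_flag": int}
HOMOLOGUE_SCHEMA = {"human_protein_id": str, "fly_protein_id": str, "family_id": str}
HIT_SCHEMA = {
    "contig_id": str,
    "subject_id": str,
    "organism": str,
    "frame": int,
    "qstart": int,
    "qend": int,
    "sstart": int,
    "send": int,
    "raw": float,
    "bits": float,
    "evalue": float,
    "identity": float,
}


def configure_logging(verbose: bool = False) -> None:
    """Send pipeline logs to stderr; ``verbose`` switches DEBUG on."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


@dataclass
class SequenceRecord:
    """One FASTA record: whitespace-free id, free-text description, sequence."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


class FormatError(ValueError):
    """Raised for malformed external input (FASTA or TSV)."""


def _validate_sequence(rec: SequenceRecord, alphabet: frozenset) -> None:
    if not rec.sequence:
        raise FormatError(f"record {rec.id!r}: empty sequence")
    bad = set(rec.sequence) - alphabet
    if bad:
        raise FormatError(
            f"record {rec.id!r}: illegal character(s) {sorted(bad)} for declared alphabet"
        )


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file, enforcing the declared alphabet.

    Parameters
    ----------
    alphabet:
        ``"dna"`` (ACGTN) or ``"protein"`` (20 residues + X + *).

    Order is preserved, multi-line sequences are joined and case-folded to
    upper.  Duplicate ids, illegal characters and empty files each raise
    :class:`FormatError`.
    """
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        rec = SequenceRecord(
            id=bio.id, sequence=str(bio.seq).upper(), description=bio.description
        )
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        _validate_sequence(rec, allowed)
        records.append(rec)
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a header-ed TSV and coerce it to ``schema``.

    Missing columns and unparseable numeric cells are reported (the latter
    with the offending row number).  A header-only file yields an empty,
    correctly-typed frame.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = {}
    for col, typ in schema.items():
        if typ is str:
            out[col] = df[col].astype(str)
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: unparseable value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} (file row {row})"
            )
        out[col] = converted.astype(typ)
    return pd.DataFrame(out, columns=list(schema))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
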