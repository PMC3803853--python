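"""Six-frame translation with coordinate bookkeeping.

Frames are numbered the BLAST way: +1/+2/+3 read the forward strand starting
at offsets 0/1/2; -1/-2/-3 read the reverse complement likewise.  Each frame
translation is split into segments at stop codons, because the downstream
aligner never extends an alignment across a stop (a conservative emulation
of BLASTX behaviour).  Segment offsets are retained so any residue maps back
to its nucleotide interval on the forward strand of the contig.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class FrameSegment:
    """A stop-free run of residues from one reading frame.

    ``codon_offset`` is the segment's 0-based codon index within its frame's
    full translation (stop codons counted), so nucleotide coordinates can be
    reconstructed exactly.
    """

    frame: int
    codon_offset: int
    sequence: str

    def nt_interval(self, aa_lo: int, aa_hi: int, contig_len: int) -> tuple[int, int]:
        """Forward-strand 1-based nt interval for segment residues [aa_lo, aa_hi].

        ``aa_lo``/``aa_hi`` are 1-based positions within this segment.
        For minus frames the interval is reported as (min, max); the frame
        sign carries the strand.
        """
        if not 1 <= aa_lo <= aa_hi <= len(self.sequence):
            raise ValueError("residue positions outside segment")
        off = abs(self.frame) - 1
        lo0 = off + 3 * (self.codon_offset + aa_lo - 1)       # 0-based nt start
        hi0 = off + 3 * (self.codon_offset + aa_hi - 1) + 2   # 0-based nt end
        if self.frame > 0:
            return lo0 + 1, hi0 + 1
        # positions were on the reverse complement; map back
        return contig_len - hi0, contig_len - lo0


def six_frame_translate(dna: str) -> list[FrameSegment]:
    """Translate all six frames of ``dna`` and split segments at stops.

    Standard genetic code (translation table 1); codons containing N
    translate to X.  Frames shorter than one codon yield no segments.
    """
    dna = dna.upper()
    if set(dna) - set("ACGTN"):
        raise ValueError("DNA sequence must be over ACGTN")
    segments: list[FrameSegment] = []
    rc = str(Seq(dna).reverse_complement())
    for frame in FRAMES:
        strand_seq = dna if frame > 0 else rc
        off = abs(frame) - 1
        usable = len(strand_seq) - off
        if usable < 3:
            continue
        trimmed = strand_seq[off : off + (usable // 3) * 3]
        protein = str(Seq(trimmed).translate(table=1))
        codon = 0
        for part in protein.split("*"):
            if part:
                segments.append(FrameSegment(frame, codon, part))
            codon += len(part) + 1  # +1 for the stop that ended this part
    return segments


def translate_frame_interval(dna: str, frame: int, qstart: int, qend: int) -> str:
    """Translate the codons of ``frame`` covered by forward-strand interval
    [qstart, qend] (1-based inclusive).  The interval must be codon-aligned
    in that frame, as hit intervals produced by the search are."""
    dna = dna.upper()
    length = len(dna)
    if frame > 0:
        lo0, hi0 = qstart - 1, qend - 1
        off = frame - 1
    else:
        # convert to reverse-complement coordinates
        lo0, hi0 = length - qend, length - qstart
        off = -frame - 1
        dna = str(Seq(dna).reverse_complement())
    if (lo0 - off) % 3 or (hi0 - lo0 + 1) % 3:
        raise ValueError("interval is not codon-aligned in the given frame")
    return str(Seq(dna[lo0 : hi0 + 1]).translate(table=1))
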