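"""Gene-duplication and differential-selection detection.

Duplication: two or more contigs of one species whose best hits fall in the
same homologue family, each longer than the contig length filter, with
every within-group pairwise nucleotide identity below 95% (fragments of one
transcript would be near-identical).  When the members' origin labels
differ — one copy best-matching the human homologue and one the fly
homologue — the candidate is *dual-origin* (the NF1-style pattern), and the
same-region test on a common coordinate frame distinguishes a true
duplication from assembly fragmentation.

Differential selection: a homologue family with exactly one qualifying
contig per focal species whose origin labels differ (nautilus tracks one
reference lineage, squid the other).  The pair is a candidate only if the
two hits fall in the same region of the common frame AND that shared window
is *not* conserved between the human and fly homologues (window identity
below ``conservation_max_identity``); a conserved window cannot tell the
two origins apart and is discarded, as the study did for PPP2CA/mts.

The common coordinate frame is the human protein: intervals on the fly
homologue are mapped through the global alignment of the homologue pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .align import ScoringScheme, dna_global_identity, global_align
from .config import PipelineConfig
from .io import logger

Interval = tuple[int, int]


def _check_interval(iv: Interval, name: str = "interval") -> None:
    if iv[0] > iv[1] or iv[0] < 1:
        raise ValueError(f"degenerate {name} {iv}")


def same_region(a: Interval, b: Interval, min_overlap: float = 0.4) -> bool:
    """True iff the overlap covers >= ``min_overlap`` of the shorter interval."""
    _check_interval(a)
    _check_interval(b)
    overlap = min(a[1], b[1]) - max(a[0], b[0]) + 1
    shorter = min(a[1] - a[0], b[1] - b[0]) + 1
    return overlap > 0 and overlap >= min_overlap * shorter


def overlap_fraction(a: Interval, b: Interval) -> float:
    """Overlap length as a fraction of the shorter interval (0 if disjoint)."""
    _check_interval(a)
    _check_interval(b)
    overlap = min(a[1], b[1]) - max(a[0], b[0]) + 1
    shorter = min(a[1] - a[0], b[1] - b[0]) + 1
    return max(0, overlap) / shorter


def map_to_common_frame(interval: Interval, human_aligned: str,
                        fly_aligned: str) -> Interval | None:
    """Map a 1-based interval on the fly homologue onto human coordinates.

    Each fly position maps to the human residue aligned in its column;
    positions opposite gaps slide inward to the nearest aligned column.
    Returns ``None`` when the interval lies entirely opposite gaps.
    """
    _check_interval(interval)
    if len(human_aligned) != len(fly_aligned):
        raise ValueError("aligned rows must have equal length")
    lo, hi = interval
    hpos = fpos = 0
    mapped: list[int] = []
    for hc, fc in zip(human_aligned, fly_aligned):
        if hc != "-":
            hpos += 1
        if fc != "-":
            fpos += 1
            if lo <= fpos <= hi and hc != "-":
                mapped.append(hpos)
        if fpos > hi:
            break
    if not mapped:
        return None
    return (mapped[0], mapped[-1])


def window_conservation(human_prot: str, fly_prot: str, interval: Interval,
                        scheme: ScoringScheme | None = None,
                        alignment: tuple[str, str] | None = None) -> float:
    """Identity between the homologues over a window of human coordinates.

    Computed over global-alignment columns whose human position falls in
    the interval; columns where the fly row is gapped count as mismatches.
    """
    _check_interval(interval, "window")
    if interval[1] > len(human_prot):
        raise ValueError("window exceeds the human homologue")
    ha, fa = alignment if alignment else global_align(human_prot, fly_prot, scheme)
    lo, hi = interval
    hpos = matches = cols = 0
    for hc, fc in zip(ha, fa):
        if hc == "-":
            continue
        hpos += 1
        if lo <= hpos <= hi:
            cols += 1
            if hc == fc:
                matches += 1
    if cols == 0:
        raise ValueError("empty conservation window")
    return matches / cols


@dataclass
class FamilyFrame:
    """Cached global alignment of one homologue pair (the common frame)."""

    family_id: str
    human_id: str
    fly_id: str
    human_seq: str
    fly_seq: str
    alignment: tuple[str, str]

    def to_common(self, interval: Interval, origin: str) -> Interval | None:
        if origin == "human":
            return interval
        return map_to_common_frame(interval, *self.alignment)


class FrameCache:
    """Lazily computed common frames, keyed by family id."""

    def __init__(self, homologue_map: pd.DataFrame,
                 proteins: Mapping[str, str],
                 scheme: ScoringScheme | None = None):
        self._rows = {r.family_id: r for r in homologue_map.itertuples()}
        self._by_subject = {}
        for r in homologue_map.itertuples():
            self._by_subject[r.human_protein_id] = r.family_id
            self._by_subject[r.fly_protein_id] = r.family_id
        self._proteins = proteins
        self._scheme = scheme or ScoringScheme()
        self._cache: dict[str, FamilyFrame] = {}

    def family_of(self, subject_id: str) -> str | None:
        return self._by_subject.get(subject_id)

    def get(self, family_id: str) -> FamilyFrame:
        if family_id not in self._cache:
            row = self._rows[family_id]
            hseq = self._proteins[row.human_protein_id]
            fseq = self._proteins[row.fly_protein_id]
            self._cache[family_id] = FamilyFrame(
                family_id, row.human_protein_id, row.fly_protein_id,
                hseq, fseq, global_align(hseq, fseq, self._scheme))
        return self._cache[family_id]


@dataclass
class DuplicationCandidate:
    species: str
    family_id: str
    contig_ids: list[str]
    subject_ids: list[str]
    origins: list[str]
    subject_intervals: list[Interval]        # on each contig's own subject
    common_intervals: list[Interval | None]  # on the human frame
    min_pairwise_identity: float
    max_pairwise_identity: float
    same_region: bool
    dual_origin: bool


@dataclass
class SelectionCandidate:
    family_id: str
    nautilus_contig: str
    squid_contig: str
    human_protein_id: str
    fly_protein_id: str
    nautilus_origin: str
    squid_origin: str
    nautilus_interval: Interval              # common (human) frame
    squid_interval: Interval
    overlap_fraction: float
    window: Interval                         # intersection of the two hits
    window_identity: float                   # human/fly identity in window
    nj_distance: float | None = None         # filled by the tree stage


def _qualifying(records: pd.DataFrame, contig_len: Mapping[str, int],
                min_len: int) -> pd.DataFrame:
    keep = records[records.qc_pass.astype(bool)].copy()
    keep = keep[keep.contig_id.map(contig_len).fillna(0) > min_len]
    return keep


def detect_duplications(records: pd.DataFrame, species: str,
                        contigs: Mapping[str, str], frames: FrameCache,
                        config: PipelineConfig) -> list[DuplicationCandidate]:
    """Duplication candidates for one species (see module docstring).

    ``records`` are assignment records (one best hit per contig);
    ``contigs`` maps contig id to nucleotide sequence.
    """
    lengths = {cid: len(seq) for cid, seq in contigs.items()}
    keep = _qualifying(records, lengths, config.min_contig_len)
    out: list[DuplicationCandidate] = []
    keep = keep.assign(family=keep.subject_id.map(frames.family_of))
    for family_id, group in keep.groupby("family", sort=True):
        if family_id is None or len(group) < 2:
            continue
        group = group.sort_values("contig_id")
        ids = list(group.contig_id)
        idents = [
            dna_global_identity(contigs[x], contigs[y])
            for i, x in enumerate(ids) for y in ids[i + 1:]
        ]
        if max(idents) >= config.duplication_identity_max:
            logger.debug("family %s: contig identity %.3f >= %.2f, not a "
                         "duplication", family_id, max(idents),
                         config.duplication_identity_max)
            continue
        frame = frames.get(family_id)
        common = [
            frame.to_common((int(r.sstart), int(r.send)), r.origin)
            for r in group.itertuples()
        ]
        pairs_ok = all(
            a is not None and b is not None
            and same_region(a, b, config.same_region_min_overlap)
            for i, a in enumerate(common) for b in common[i + 1:]
        )
        origins = list(group.origin)
        out.append(DuplicationCandidate(
            species=species, family_id=family_id, contig_ids=ids,
            subject_ids=list(group.subject_id), origins=origins,
            subject_intervals=[(int(r.sstart), int(r.send))
                               for r in group.itertuples()],
            common_intervals=common,
            min_pairwise_identity=min(idents),
            max_pairwise_identity=max(idents),
            same_region=pairs_ok,
            dual_origin=len(set(origins)) > 1,
        ))
    return out


def detect_selection_pairs(nautilus_records: pd.DataFrame,
                           squid_records: pd.DataFrame,
                           contigs: Mapping[str, str], frames: FrameCache,
                           config: PipelineConfig) -> list[SelectionCandidate]:
    """Differential-selection candidates (see module docstring).

    Families contributing more than one qualifying contig in either species
    are duplication material and are excluded from pairing.
    """
    lengths = {cid: len(seq) for cid, seq in contigs.items()}
    per_species = {}
    for species, records in (("nautilus", nautilus_records),
                             ("squid", squid_records)):
        keep = _qualifying(records, lengths, config.min_contig_len)
        keep = keep.assign(family=keep.subject_id.map(frames.family_of))
        per_species[species] = keep
    out: list[SelectionCandidate] = []
    families = sorted(
        set(per_species["nautilus"].family.dropna())
        & set(per_species["squid"].family.dropna())
    )
    for family_id in families:
        naut = per_species["nautilus"][per_species["nautilus"].family == family_id]
        squid = per_species["squid"][per_species["squid"].family == family_id]
        if len(naut) != 1 or len(squid) != 1:
            continue
        nrow, srow = naut.iloc[0], squid.iloc[0]
        if nrow.origin == srow.origin:
            continue
        frame = frames.get(family_id)
        niv = frame.to_common((int(nrow.sstart), int(nrow.send)), nrow.origin)
        siv = frame.to_common((int(srow.sstart), int(srow.send)), srow.origin)
        if niv is None or siv is None:
            logger.warning("family %s: hit interval unmappable to the common "
                           "frame; candidate skipped", family_id)
            continue
        if not same_region(niv, siv, config.same_region_min_overlap):
            continue
        window = (max(niv[0], siv[0]), min(niv[1], siv[1]))
        ident = window_conservation(frame.human_seq, frame.fly_seq, window,
                                    alignment=frame.alignment)
        if ident >= config.conservation_max_identity:
            logger.debug("family %s: window identity %.2f is conserved; "
                         "candidate discarded", family_id, ident)
            continue
        out.append(SelectionCandidate(
            family_id=family_id,
            nautilus_contig=nrow.contig_id, squid_contig=srow.contig_id,
            human_protein_id=frame.human_id, fly_protein_id=frame.fly_id,
            nautilus_origin=nrow.origin, squid_origin=srow.origin,
            nautilus_interval=niv, squid_interval=siv,
            overlap_fraction=overlap_fraction(niv, siv),
            window=window, window_identity=ident,
        ))
    return out


def duplication_table(candidates: Sequence[DuplicationCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"species": c.species, "family_id": c.family_id,
          "contig_ids": ";".join(c.contig_ids),
          "subject_ids": ";".join(c.subject_ids),
          "origins": ";".join(c.origins),
          "min_identity": c.min_pairwise_identity,
          "max_identity": c.max_pairwise_identity,
          "same_region": c.same_region, "dual_origin": c.dual_origin}
         for c in candidates],
        columns=["species", "family_id", "contig_ids", "subject_ids",
                 "origins", "min_identity", "max_identity", "same_region",
                 "dual_origin"])


def selection_table(candidates: Sequence[SelectionCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"family_id": c.family_id, "nautilus_contig": c.nautilus_contig,
          "squid_contig": c.squid_contig,
          "nautilus_origin": c.nautilus_origin, "squid_origin": c.squid_origin,
          "window_start": c.window[0], "window_end": c.window[1],
          "overlap_fraction": c.overlap_fraction,
          "window_identity": c.window_identity,
          "nj_distance": c.nj_distance}
         for c in candidates],
        columns=["family_id", "nautilus_contig", "squid_contig",
                 "nautilus_origin", "squid_origin", "window_start",
                 "window_end", "overlap_fraction", "window_identity",
                 "nj_distance"])
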