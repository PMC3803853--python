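"""Four-lineage synthetic transcriptome generator with a truth ledger.

The generator emulates the data the comparative pipeline consumes: a human
and a fly reference proteome related family-by-family (a HomoloGene-style
map), nucleotide contigs for two focal molluscs (nautilus and squid), GO
annotations shared across each family's four lineage copies, and per-sample
coverage values.  Into this background it plants three kinds of recoverable
events, each recorded in a machine-readable :class:`TruthRecord`:

* **duplications** — two same-species copies of one family with pairwise
  identity inside a configured band (below the 95% similarity criterion,
  clearly homologous);
* **dual-origin duplications** — one copy seeded from the human homologue
  and one from the fly homologue over the same region (the NF1-style
  pattern);
* **differential-selection events** — the human/fly homologues are given a
  mutually non-conserved window, the squid copy tracks one reference inside
  that window and the nautilus copy the other (or mirrored), so each focal
  species best-matches a different reference lineage.

Substitutions are i.i.d. per site with a uniformly chosen different residue;
the detectors depend only on identity levels, not on realistic
exchangeabilities, and there are no indels.  Coverage is generated directly
as aligned bases per contig (read simulation is out of scope).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import SequenceRecord, logger, write_fasta, write_table

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA)}

#: synonymous codons per residue (standard code, stops excluded), sorted so
#: codon choice is a pure function of the RNG stream
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    CODONS_BY_AA.setdefault(aa, []).append(codon)
for _codons in CODONS_BY_AA.values():
    _codons.sort()

SPECIES = ("nautilus", "squid")
ORGANISMS = ("human", "fly")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_families: int = 200
    family_length_range: tuple[int, int] = (80, 400)   # residues
    p_global: float = 0.5       # per-site divergence between human and fly
    p_focal: float = 0.15       # nearest reference -> focal contig
    n_duplications: int = 10
    n_dual_origin_duplications: int = 3
    n_selection_events: int = 10
    window_frac: float = 0.3
    p_window_bias: float = 0.05  # noise on the "near" copy inside a window
    duplication_identity_range: tuple[float, float] = (0.70, 0.90)
    coverage_lognormal_params: tuple[float, float] = (math.log(50.0), 0.2)
    frac_differential: float = 0.4
    differential_factor_range: tuple[float, float] = (2.5, 6.0)
    n_go_terms: int = 32
    n_eye_terms: int = 8
    eye_family_frac: float = 0.35
    planted_term_rate: float = 0.7    # planted GO term in up-direction families
    baseline_term_rate: float = 0.14  # ... and elsewhere (5x contrast)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        probs = (self.p_global, self.p_focal, self.window_frac,
                 self.p_window_bias, self.frac_differential,
                 self.planted_term_rate, self.baseline_term_rate)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if self.n_families < self.n_duplications + self.n_selection_events:
            raise ValueError("n_families must cover all planted events")
        if self.n_dual_origin_duplications > self.n_duplications:
            raise ValueError("dual-origin duplications are a subset of duplications")
        if self.family_length_range[0] < 40:
            raise ValueError("family_length_range min must be >= 40 residues")
        if self.differential_factor_range[0] < 2.5:
            raise ValueError("planted differential factor must be >= 2.5")
        if self.n_eye_terms > self.n_go_terms or self.n_eye_terms < 6:
            raise ValueError("need >= 6 eye terms within the vocabulary")
        return self


@dataclass
class TruthRecord:
    """Ledger entry for one family and the event planted in it (if any)."""

    family_id: str
    event_kind: str                      # ortholog | duplication |
    #                                      dual_origin_duplication | selection
    contig_ids: list[str]
    expected_origin: dict[str, str]      # contig id -> human | fly
    window: tuple[int, int] | None       # protein coords, 1-based inclusive
    expected_differential: dict[str, bool]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window) if self.window else None
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TruthRecord":
        return cls(
            family_id=d["family_id"], event_kind=d["event_kind"],
            contig_ids=list(d["contig_ids"]),
            expected_origin=dict(d["expected_origin"]),
            window=tuple(d["window"]) if d.get("window") else None,
            expected_differential={k: bool(v) for k, v in
                                   d["expected_differential"].items()},
        )


# ---------------------------------------------------------------------------
# sequence-level operations


def _check_protein(seq: str) -> None:
    bad = set(seq) - set(AA)
    if not seq or bad:
        raise ValueError(f"protein must be non-empty over the 20-letter "
                         f"alphabet (offending: {sorted(bad)})")


def random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, 20, size=length)
    return "".join(AA[i] for i in idx)


def evolve_protein(seq: str, p_sub: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``p_sub``.

    Replacements are uniform over the 19 other residues; length is preserved.
    """
    _check_protein(seq)
    if not 0.0 <= p_sub <= 1.0:
        raise ValueError("p_sub must be in [0, 1]")
    idx = np.array([_AA_INDEX[a] for a in seq], dtype=np.int64)
    hit = rng.random(len(seq)) < p_sub
    repl = rng.integers(0, 19, size=len(seq))
    # shift so the replacement is never the current residue
    repl = np.where(repl >= idx, repl + 1, repl)
    out = np.where(hit, repl, idx)
    return "".join(AA[i] for i in out)


def sitewise_identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        raise ValueError("sequences must be non-empty and equal length")
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """DNA encoding ``protein`` with codons uniform among synonymous choices."""
    _check_protein(protein)
    parts = []
    for aa in protein:
        codons = CODONS_BY_AA[aa]
        parts.append(codons[int(rng.integers(0, len(codons)))])
    return "".join(parts)


def plant_selection_event(human_prot: str, fly_prot: str,
                          config: SimulationConfig, rng: np.random.Generator
                          ) -> tuple[str, str, str, str, dict]:
    """Plant a differential-selection window into one family.

    Returns ``(human, fly, nautilus, squid, info)``: the reference
    homologues with their window regenerated independently (window identity
    <= 0.30), and the two focal copies that each track a different reference
    inside the window (assignment recorded in ``info['origins']``).  Outside
    the window the focal copies derive from a common mosaic intermediate at
    ``p_focal``.
    """
    L = len(human_prot)
    if len(fly_prot) != L:
        raise ValueError("homologues must have equal length")
    wlen = max(1, round(config.window_frac * L))
    if wlen > L:
        raise ValueError("window longer than family")
    ws = int(rng.integers(0, L - wlen + 1))
    window = (ws + 1, ws + wlen)
    while True:  # independent regeneration; enforce the <=30% guarantee
        hw = random_protein(wlen, rng)
        fw = random_protein(wlen, rng)
        if sitewise_identity(hw, fw) <= 0.30:
            break
    human = human_prot[:ws] + hw + human_prot[ws + wlen:]
    fly = fly_prot[:ws] + fw + fly_prot[ws + wlen:]
    mirrored = bool(rng.integers(0, 2))
    # default orientation: squid tracks the human window, nautilus the fly one
    squid_base, naut_base = (fw, hw) if mirrored else (hw, fw)
    origins = ({"squid": "fly", "nautilus": "human"} if mirrored
               else {"squid": "human", "nautilus": "fly"})
    mosaic = rng.random(L) < 0.5
    intermediate = "".join(h if m else f for h, f, m in zip(human, fly, mosaic))
    naut = evolve_protein(intermediate, config.p_focal, rng)
    squid = evolve_protein(intermediate, config.p_focal, rng)
    naut = naut[:ws] + evolve_protein(naut_base, config.p_window_bias, rng) + naut[ws + wlen:]
    squid = squid[:ws] + evolve_protein(squid_base, config.p_window_bias, rng) + squid[ws + wlen:]
    info = {"window": window, "origins": origins}
    return human, fly, naut, squid, info


def plant_duplication(ref_prot: str, config: SimulationConfig,
                      rng: np.random.Generator, dual_origin: bool = False,
                      fly_prot: str | None = None) -> tuple[str, str]:
    """Two same-species copies of one family.

    Non-dual copies both derive from ``ref_prot`` and are resampled until
    their pairwise identity falls in ``duplication_identity_range``.  Dual
    copies are seeded from the human (``ref_prot``) and fly homologues over
    the full (hence overlapping) interval.
    """
    if dual_origin:
        if fly_prot is None:
            raise ValueError("dual-origin duplication needs the fly homologue")
        a = evolve_protein(ref_prot, config.p_focal, rng)
        b = evolve_protein(fly_prot, config.p_focal, rng)
        return a, b
    lo, hi = config.duplication_identity_range
    for _ in range(200):
        pa, pb = rng.uniform(0.05, 0.18, size=2)
        a = evolve_protein(ref_prot, pa, rng)
        b = evolve_protein(ref_prot, pb, rng)
        if lo <= sitewise_identity(a, b) <= hi:
            return a, b
    raise RuntimeError("could not place duplication identity in band")


# ---------------------------------------------------------------------------
# GO vocabulary

_EYE_TERM_NAMES = [
    "compound eye morphogenesis",
    "lens fiber cell differentiation",
    "retina layer formation",
    "photoreceptor outer segment organization",
    "R7 cell fate specification",
    "R1/R6 rhabdomere assembly",
    "eye pigment granule transport",
    "lens crystallin aggregation",
]
_BACKGROUND_TERM_NAMES = [
    "ribosome biogenesis", "proteolysis", "glycolytic process",
    "actin filament organization", "DNA replication initiation",
    "tRNA aminoacylation", "vesicle docking", "chitin metabolic process",
    "oxidative phosphorylation", "mRNA splicing", "cell adhesion",
    "microtubule nucleation", "ion transmembrane transport",
    "protein folding", "lipid catabolic process", "histone modification",
    "axon guidance", "apoptotic signaling", "cilium assembly variant",
    "nucleotide salvage", "heme biosynthesis", "muscle contraction",
    "innate immune response", "synaptic vesicle cycle",
]
PLANTED_TERM_NAME = "synaptic vesicle cycle"


def build_go_vocabulary(config: SimulationConfig) -> pd.DataFrame:
    """Invented GO-like vocabulary; >= 6 terms carry the eye flag."""
    n_bg = config.n_go_terms - config.n_eye_terms
    names = (_EYE_TERM_NAMES * math.ceil(config.n_eye_terms / len(_EYE_TERM_NAMES)))[
        : config.n_eye_terms
    ] + (_BACKGROUND_TERM_NAMES * math.ceil(n_bg / len(_BACKGROUND_TERM_NAMES)))[:n_bg]
    rows = [
        {"go_id": f"GO:S{i + 1:06d}", "go_name": name,
         "eye_flag": 1 if i < config.n_eye_terms else 0}
        for i, name in enumerate(names)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage(contigs: Sequence[SequenceRecord],
                      species_of: Mapping[str, str],
                      differential: Mapping[str, bool],
                      config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Aligned-bases table, contig x sample, with planted >=2.5-fold boosts.

    Base coverage is log-normal per contig and sample; a contig flagged
    differential is boosted in its own species' sample by a factor drawn
    from ``differential_factor_range``.
    """
    mu, sigma = config.coverage_lognormal_params
    flo, fhi = config.differential_factor_range
    rows = []
    for rec in contigs:
        for sample in SPECIES:
            cov = float(rng.lognormal(mean=mu, sigma=sigma))
            if differential.get(rec.id, False) and sample == species_of[rec.id]:
                cov *= float(rng.uniform(flo, fhi))
            rows.append({
                "contig_id": rec.id, "sample": sample,
                "aligned_bases": round(cov * len(rec.sequence), 3),
                "contig_length": len(rec.sequence),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-dataset generation


@dataclass
class DatasetBundle:
    """Everything one simulated study emits, in memory plus on disk."""

    config: SimulationConfig
    outdir: Path
    paths: dict[str, Path]
    human_proteins: list[SequenceRecord]
    fly_proteins: list[SequenceRecord]
    contigs: dict[str, list[SequenceRecord]]      # species -> records
    homologue_map: pd.DataFrame
    go_annotations: pd.DataFrame
    coverage: pd.DataFrame
    truth: list[TruthRecord]
    planted_term: str


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> DatasetBundle:
    """Generate and write one complete synthetic dataset (deterministic)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n = config.n_families
    fams = [f"fam{i:04d}" for i in range(n)]
    perm = rng.permutation(n)
    sel_set = set(perm[: config.n_selection_events])
    dup_list = list(perm[config.n_selection_events:
                         config.n_selection_events + config.n_duplications])
    dup_set = set(dup_list)
    dual_set = set(dup_list[: config.n_dual_origin_duplications])

    # differential flags and direction are drawn before annotation so the
    # planted enrichment term can follow them
    diff_flag = rng.random(n) < config.frac_differential
    diff_dir = np.where(rng.integers(0, 2, size=n) == 0, "nautilus", "squid")

    vocab = build_go_vocabulary(config)
    planted_term = vocab.loc[vocab.go_name == PLANTED_TERM_NAME, "go_id"].iloc[0]
    eye_terms = vocab[vocab.eye_flag == 1]
    bg_terms = vocab[(vocab.eye_flag == 0) & (vocab.go_id != planted_term)]

    event_fams = sel_set | dup_set
    n_eye = max(len(event_fams), round(config.eye_family_frac * n))
    non_event = [i for i in range(n) if i not in event_fams]
    extra = rng.choice(non_event, size=max(0, n_eye - len(event_fams)),
                       replace=False)
    eye_fams = event_fams | set(int(i) for i in extra)

    human_prots: list[SequenceRecord] = []
    fly_prots: list[SequenceRecord] = []
    contigs: dict[str, list[SequenceRecord]] = {s: [] for s in SPECIES}
    truth: list[TruthRecord] = []
    anno_rows: list[dict] = []
    homo_rows: list[dict] = []
    lo_len, hi_len = config.family_length_range

    for i, fam in enumerate(fams):
        L = int(rng.integers(lo_len, hi_len + 1))
        human = random_protein(L, rng)
        fly = evolve_protein(human, config.p_global, rng)
        origin = "human" if rng.integers(0, 2) == 0 else "fly"
        window = None
        fam_contigs: dict[str, str] = {}   # contig id -> protein
        origins: dict[str, str] = {}

        if i in sel_set:
            human, fly, naut_p, squid_p, info = plant_selection_event(
                human, fly, config, rng)
            window = info["window"]
            ids = {"nautilus": f"naut_{fam}", "squid": f"squid_{fam}"}
            fam_contigs[ids["nautilus"]] = naut_p
            fam_contigs[ids["squid"]] = squid_p
            origins[ids["nautilus"]] = info["origins"]["nautilus"]
            origins[ids["squid"]] = info["origins"]["squid"]
            kind = "selection"
            event_ids = [ids["nautilus"], ids["squid"]]
        elif i in dup_set:
            dual = i in dual_set
            dup_species = "nautilus" if rng.integers(0, 2) == 0 else "squid"
            other = "squid" if dup_species == "nautilus" else "nautilus"
            ref = human if (dual or origin == "human") else fly
            a, b = plant_duplication(ref, config, rng, dual_origin=dual,
                                     fly_prot=fly if dual else None)
            p = "naut" if dup_species == "nautilus" else "squid"
            po = "naut" if other == "nautilus" else "squid"
            id_a, id_b = f"{p}_{fam}_d1", f"{p}_{fam}_d2"
            fam_contigs[id_a], fam_contigs[id_b] = a, b
            origins[id_a] = "human" if dual else origin
            origins[id_b] = "fly" if dual else origin
            oid = f"{po}_{fam}"
            fam_contigs[oid] = evolve_protein(
                human if origin == "human" else fly, config.p_focal, rng)
            origins[oid] = origin
            kind = "dual_origin_duplication" if dual else "duplication"
            event_ids = [id_a, id_b]
        else:
            ref = human if origin == "human" else fly
            for species, p in (("nautilus", "naut"), ("squid", "squid")):
                cid = f"{p}_{fam}"
                fam_contigs[cid] = evolve_protein(ref, config.p_focal, rng)
                origins[cid] = origin
            kind = "ortholog"
            event_ids = sorted(fam_contigs)

        hid, fid = f"human_{fam}", f"fly_{fam}"
        human_prots.append(SequenceRecord(hid, human))
        fly_prots.append(SequenceRecord(fid, fly))
        homo_rows.append({"human_protein_id": hid, "fly_protein_id": fid,
                          "family_id": fam})

        for cid, prot in fam_contigs.items():
            species = "nautilus" if cid.startswith("naut_") else "squid"
            contigs[species].append(
                SequenceRecord(cid, reverse_translate(prot, rng)))

        differential: dict[str, bool] = {}
        for cid in fam_contigs:
            species = "nautilus" if cid.startswith("naut_") else "squid"
            differential[cid] = bool(diff_flag[i]) and species == diff_dir[i]

        # annotation: 1-3 terms per family, shared across the four lineage
        # copies; eye families carry at least one eye-flagged term
        n_terms = int(rng.integers(1, 4))
        chosen: list[int] = []
        if i in eye_fams:
            chosen.append(int(rng.choice(eye_terms.index)))
        while len(chosen) < n_terms:
            t = int(rng.choice(bg_terms.index))
            if t not in chosen:
                chosen.append(t)
        rate = (config.planted_term_rate
                if diff_flag[i] and diff_dir[i] == "nautilus"
                else config.baseline_term_rate)
        planted_idx = int(vocab.index[vocab.go_id == planted_term][0])
        if rng.random() < rate:
            chosen.append(planted_idx)
        for pid in (hid, fid):
            for t in chosen:
                anno_rows.append({
                    "protein_id": pid, "go_id": vocab.go_id[t],
                    "go_name": vocab.go_name[t],
                    "eye_flag": int(vocab.eye_flag[t]),
                })

        truth.append(TruthRecord(
            family_id=fam, event_kind=kind, contig_ids=event_ids,
            expected_origin=origins, window=window,
            expected_differential=differential,
        ))

    all_contigs = [c for s in SPECIES for c in contigs[s]]
    species_of = {c.id: s for s in SPECIES for c in contigs[s]}
    differential_all = {
        cid: flag for rec in truth for cid, flag in rec.expected_differential.items()
    }
    coverage = simulate_coverage(all_contigs, species_of, differential_all,
                                 config, rng)

    paths = {
        "human_proteins": outdir / "human_proteins.fasta",
        "fly_proteins": outdir / "fly_proteins.fasta",
        "nautilus_contigs": outdir / "nautilus_contigs.fasta",
        "squid_contigs": outdir / "squid_contigs.fasta",
        "homologue_map": outdir / "homologue_map.tsv",
        "go_annotations": outdir / "go_annotations.tsv",
        "coverage": outdir / "coverage.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(human_prots, paths["human_proteins"])
    write_fasta(fly_prots, paths["fly_proteins"])
    write_fasta(contigs["nautilus"], paths["nautilus_contigs"])
    write_fasta(contigs["squid"], paths["squid_contigs"])
    homologue_map = pd.DataFrame(homo_rows)
    go_annotations = pd.DataFrame(anno_rows)
    write_table(homologue_map, paths["homologue_map"])
    write_table(go_annotations, paths["go_annotations"])
    write_table(coverage, paths["coverage"])
    with open(paths["truth"], "w") as fh:
        json.dump({"seed": config.seed, "planted_term": str(planted_term),
                   "records": [t.to_dict() for t in truth]}, fh, indent=1)
        fh.write("\n")

    return DatasetBundle(
        config=config, outdir=outdir, paths=paths,
        human_proteins=human_prots, fly_proteins=fly_prots, contigs=contigs,
        homologue_map=homologue_map, go_annotations=go_annotations,
        coverage=coverage, truth=truth, planted_term=str(planted_term),
    )


def load_truth(path: str | Path) -> tuple[list[TruthRecord], str]:
    with open(path) as fh:
        data = json.load(fh)
    return [TruthRecord.from_dict(d) for d in data["records"]], data["planted_term"]


# ---------------------------------------------------------------------------
# detection scoring


@dataclass
class DetectionMetrics:
    sensitivity: float
    precision: float
    n_truth: int
    n_candidates: int
    n_recovered: int


_DUP_KINDS = {"duplication", "dual_origin_duplication"}


def score_detection(candidates: Mapping[str, Iterable[Iterable[str]]],
                    truth: Sequence[TruthRecord]) -> dict[str, DetectionMetrics]:
    """Sensitivity and precision of detected events against the ledger.

    ``candidates`` maps ``"duplication"``/``"selection"`` to iterables of
    contig-id collections; a candidate matches a planted event iff the
    contig-id sets are equal.  With zero candidates precision is reported as
    1 by convention (with a warning).
    """
    out: dict[str, DetectionMetrics] = {}
    for kind in ("duplication", "selection"):
        truth_sets = {
            frozenset(t.contig_ids) for t in truth
            if (t.event_kind in _DUP_KINDS if kind == "duplication"
                else t.event_kind == "selection")
        }
        cand_sets = [frozenset(c) for c in candidates.get(kind, [])]
        recovered = sum(1 for c in set(cand_sets) if c in truth_sets)
        sensitivity = recovered / len(truth_sets) if truth_sets else 1.0
        if cand_sets:
            precision = sum(1 for c in cand_sets if c in truth_sets) / len(cand_sets)
        else:
            if truth_sets:
                logger.warning("no %s candidates; precision reported as 1 "
                               "by convention", kind)
            precision = 1.0
        out[kind] = DetectionMetrics(sensitivity, precision,
                                     len(truth_sets), len(cand_sets), recovered)
    return out
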