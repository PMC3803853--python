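"""Stage orchestration: simulate -> search -> express -> enrich -> classify
-> detect -> tree -> score.

Each stage reads its inputs from, and writes its outputs to, a run directory
using the TSV/JSON contracts of the other modules, so stages are idempotent
and independently testable; :func:`run_pipeline` chains them and emits a
versioned run report with record counts, detection metrics (when truth is
available) and a checksummed file manifest.  Any stage failure aborts with a
stage-tagged error.

Run-directory layout::

    data/                      synthetic or user-supplied inputs
    hits_<species>.tsv         translated-search hit tables
    expression.tsv             normalized coverage + selected_sample column
    enrichment.tsv             GO term tests (nautilus-up vs squid-up)
    assignments_<species>.tsv  eye classification records
    duplications.tsv, selections.tsv
    trees/                     newick trees per candidate, trees.json
    metrics.json               detection metrics vs truth
    report.json, report.txt
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import enrichment as enr
from . import events, expression, eye, phylo
from .align import ScoringScheme
from .config import PipelineConfig
from .io import (COVERAGE_SCHEMA, GO_SCHEMA, HIT_SCHEMA, HOMOLOGUE_SCHEMA,
                 SequenceRecord, logger, read_fasta, read_table, write_table)
from .search import best_hits, search
from .simulate import (SPECIES, DatasetBundle, SimulationConfig,
                       generate_dataset, load_truth, score_detection)

REPORT_SCHEMA_VERSION = 1

_DATA_FILES = {
    "human_proteins": "human_proteins.fasta",
    "fly_proteins": "fly_proteins.fasta",
    "nautilus_contigs": "nautilus_contigs.fasta",
    "squid_contigs": "squid_contigs.fasta",
    "homologue_map": "homologue_map.tsv",
    "go_annotations": "go_annotations.tsv",
    "coverage": "coverage.tsv",
}


def _scheme(cfg: PipelineConfig) -> ScoringScheme:
    return ScoringScheme(gap_open=cfg.gap_open, gap_extend=cfg.gap_extend,
                         ka_lambda=cfg.ka_lambda, ka_k=cfg.ka_k)


class RunDirectory:
    """Typed access to the files of one pipeline run."""

    def __init__(self, outdir: str | Path):
        self.outdir = Path(outdir)
        self.data = self.outdir / "data"

    def path(self, name: str) -> Path:
        return self.outdir / name

    def read_proteomes(self) -> dict[str, list[SequenceRecord]]:
        return {
            "human": read_fasta(self.data / _DATA_FILES["human_proteins"]),
            "fly": read_fasta(self.data / _DATA_FILES["fly_proteins"]),
        }

    def read_contigs(self) -> dict[str, list[SequenceRecord]]:
        return {
            s: read_fasta(self.data / _DATA_FILES[f"{s}_contigs"], alphabet="dna")
            for s in SPECIES
        }

    def read_hits(self, species: str) -> pd.DataFrame:
        return read_table(self.path(f"hits_{species}.tsv"), HIT_SCHEMA)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(sim_config: SimulationConfig, outdir: str | Path) -> DatasetBundle:
    run = RunDirectory(outdir)
    run.outdir.mkdir(parents=True, exist_ok=True)
    return generate_dataset(sim_config, run.data)


def stage_search(outdir: str | Path, cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    run = RunDirectory(outdir)
    proteomes = run.read_proteomes()
    contigs = run.read_contigs()
    out = {}
    for species in SPECIES:
        hits = search(contigs[species], proteomes, _scheme(cfg),
                      e_cutoff=cfg.search_evalue,
                      min_contig_len=cfg.min_contig_len,
                      engine=cfg.search_engine)
        write_table(hits, run.path(f"hits_{species}.tsv"))
        out[species] = hits
    return out


def stage_express(outdir: str | Path, cfg: PipelineConfig) -> dict[str, set[str]]:
    run = RunDirectory(outdir)
    coverage = read_table(run.data / _DATA_FILES["coverage"], COVERAGE_SCHEMA)
    norm = expression.normalized_coverage(coverage)
    up = expression.select_candidates(norm, cfg.min_coverage, cfg.fold_change)
    selected = {c: s for s, cs in up.items() for c in cs}
    norm = norm.assign(
        selected_sample=norm.contig_id.map(selected).fillna(""))
    write_table(norm, run.path("expression.tsv"))
    return up


def _load_up_sets(run: RunDirectory) -> dict[str, set[str]]:
    df = read_table(run.path("expression.tsv"),
                    {**COVERAGE_SCHEMA, "normalized_coverage": float,
                     "selected_sample": str})
    up: dict[str, set[str]] = {s: set() for s in SPECIES}
    for row in df[df.selected_sample != ""].itertuples():
        up.setdefault(row.selected_sample, set()).add(row.contig_id)
    return up


def stage_enrich(outdir: str | Path, cfg: PipelineConfig) -> pd.DataFrame:
    run = RunDirectory(outdir)
    go_map = read_table(run.data / _DATA_FILES["go_annotations"], GO_SCHEMA)
    hits = pd.concat([run.read_hits(s) for s in SPECIES], ignore_index=True)
    contig_go = enr.transfer_annotations(hits, go_map, cfg.annotation_evalue)
    up = _load_up_sets(run)
    results = enr.enrich(up["nautilus"], up["squid"], contig_go,
                         alpha=cfg.fdr_alpha, two_tailed=cfg.fisher_two_tailed)
    table = enr.results_table(results)
    write_table(table, run.path("enrichment.tsv"))
    return table


def stage_classify(outdir: str | Path, cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    run = RunDirectory(outdir)
    go_map = read_table(run.data / _DATA_FILES["go_annotations"], GO_SCHEMA)
    homologue = read_table(run.data / _DATA_FILES["homologue_map"],
                           HOMOLOGUE_SCHEMA)
    organism_of = {}
    for r in homologue.itertuples():
        organism_of[r.human_protein_id] = "human"
        organism_of[r.fly_protein_id] = "fly"
    eye_sets = eye.select_eye_proteins(go_map, organism_of)
    out = {}
    for species in SPECIES:
        hits = run.read_hits(species)
        raw = eye.raw_eye_contigs(hits, eye_sets, cfg.annotation_evalue) \
            if not hits.empty else set()
        records = eye.qc_best_hits(raw, hits, eye_sets, species,
                                   strict=cfg.qc_strict)
        write_table(records, run.path(f"assignments_{species}.tsv"))
        out[species] = records
    return out


def stage_detect(outdir: str | Path, cfg: PipelineConfig
                 ) -> tuple[list[events.DuplicationCandidate],
                            list[events.SelectionCandidate]]:
    run = RunDirectory(outdir)
    homologue = read_table(run.data / _DATA_FILES["homologue_map"],
                           HOMOLOGUE_SCHEMA)
    proteomes = run.read_proteomes()
    proteins = {r.id: r.sequence for recs in proteomes.values() for r in recs}
    contigs = {r.id: r.sequence
               for recs in run.read_contigs().values() for r in recs}
    frames = events.FrameCache(homologue, proteins, _scheme(cfg))
    assignments = {
        s: read_table(run.path(f"assignments_{s}.tsv"),
                      {"contig_id": str, "species": str, "subject_id": str,
                       "origin": str, "bits": float, "evalue": float,
                       "sstart": int, "send": int, "eye_related": str,
                       "qc_pass": str})
        for s in SPECIES
    }
    for df in assignments.values():
        df["qc_pass"] = df.qc_pass.isin(["True", "true", "1"])
    duplications: list[events.DuplicationCandidate] = []
    for species in SPECIES:
        duplications.extend(events.detect_duplications(
            assignments[species], species, contigs, frames, cfg))
    selections = events.detect_selection_pairs(
        assignments["nautilus"], assignments["squid"], contigs, frames, cfg)
    write_table(events.duplication_table(duplications),
                run.path("duplications.tsv"))
    write_table(events.selection_table(selections), run.path("selections.tsv"))
    return duplications, selections


def _pair_hit(hits: pd.DataFrame, contig_id: str, subject_id: str):
    sub = hits[(hits.contig_id == contig_id) & (hits.subject_id == subject_id)]
    return None if sub.empty else sub.iloc[0]


def stage_tree(outdir: str | Path, cfg: PipelineConfig) -> dict:
    """NJ trees for dual-origin duplications and selection pairs.

    For each recovered dual-origin duplication the 4-leaf tree of the two
    trimmed contig fragments plus the two reference homologues is built and
    checked for the expected pattern (each contig clustering with its
    best-hit reference).  For each selection pair the contig-contig NJ
    distance is reported.  Pairs whose raw distance exceeds the Kimura
    domain fall back to uncorrected distances (logged).
    """
    run = RunDirectory(outdir)
    treedir = run.path("trees")
    treedir.mkdir(exist_ok=True)
    homologue = read_table(run.data / _DATA_FILES["homologue_map"],
                           HOMOLOGUE_SCHEMA)
    by_family = {r.family_id: r for r in homologue.itertuples()}
    proteomes = run.read_proteomes()
    proteins = {r.id: r.sequence for recs in proteomes.values() for r in recs}
    contigs = {r.id: r.sequence
               for recs in run.read_contigs().values() for r in recs}
    hits = {s: run.read_hits(s) for s in SPECIES}
    all_hits = pd.concat(list(hits.values()), ignore_index=True)
    scheme = _scheme(cfg)

    def _fragments(contig_ids, subject_ids) -> dict[str, str] | None:
        frags = {}
        for cid, sid in zip(contig_ids, subject_ids):
            hit = _pair_hit(all_hits, cid, sid)
            if hit is None:
                return None
            frags[cid] = phylo.trim_to_hit(contigs[cid], hit)
        return frags

    def _tree_for(seqs: Mapping[str, str], name: str):
        try:
            dm = phylo.distances_from_sequences(seqs, scheme, kimura=cfg.kimura)
        except ValueError as exc:
            logger.warning("tree %s: %s; using uncorrected distances",
                           name, exc)
            dm = phylo.distances_from_sequences(seqs, scheme, kimura=False)
        tree = phylo.neighbor_joining(dm)
        (treedir / f"{name}.nwk").write_text(phylo.to_newick(tree) + "\n")
        (treedir / f"{name}.phylip").write_text(dm.to_phylip())
        return tree

    report = {"dual_origin": [], "selection": []}
    dup = read_table(run.path("duplications.tsv"),
                     {"species": str, "family_id": str, "contig_ids": str,
                      "subject_ids": str, "origins": str, "min_identity": float,
                      "max_identity": float, "same_region": str,
                      "dual_origin": str})
    for row in dup[dup.dual_origin.isin(["True", "true", "1"])].itertuples():
        fam = by_family[row.family_id]
        cids = row.contig_ids.split(";")
        sids = row.subject_ids.split(";")
        origins = row.origins.split(";")
        frags = _fragments(cids, sids)
        if frags is None:
            continue
        seqs = dict(frags)
        seqs[fam.human_protein_id] = proteins[fam.human_protein_id]
        seqs[fam.fly_protein_id] = proteins[fam.fly_protein_id]
        name = f"dup_{row.species}_{row.family_id}"
        tree = _tree_for(seqs, name)
        concordant = all(
            phylo.has_cherry(tree, cid,
                             fam.human_protein_id if org == "human"
                             else fam.fly_protein_id)
            for cid, org in zip(cids, origins)
        )
        report["dual_origin"].append(
            {"name": name, "family_id": row.family_id,
             "contig_ids": cids, "concordant": bool(concordant)})

    sel = read_table(run.path("selections.tsv"),
                     {"family_id": str, "nautilus_contig": str,
                      "squid_contig": str, "nautilus_origin": str,
                      "squid_origin": str, "window_start": int,
                      "window_end": int, "overlap_fraction": float,
                      "window_identity": float, "nj_distance": str})
    nj_distances = []
    for row in sel.itertuples():
        fam = by_family[row.family_id]
        subjects = {
            row.nautilus_contig: (fam.human_protein_id
                                  if row.nautilus_origin == "human"
                                  else fam.fly_protein_id),
            row.squid_contig: (fam.human_protein_id
                               if row.squid_origin == "human"
                               else fam.fly_protein_id),
        }
        frags = _fragments(list(subjects), list(subjects.values()))
        if frags is None:
            nj_distances.append("")
            continue
        seqs = dict(frags)
        seqs[fam.human_protein_id] = proteins[fam.human_protein_id]
        seqs[fam.fly_protein_id] = proteins[fam.fly_protein_id]
        name = f"sel_{row.family_id}"
        tree = _tree_for(seqs, name)
        dist = phylo.leaf_distance(tree, row.nautilus_contig, row.squid_contig)
        nj_distances.append(f"{dist:.5f}")
        report["selection"].append(
            {"name": name, "family_id": row.family_id,
             "nj_distance": float(f"{dist:.5f}")})
    if len(sel):
        sel = sel.assign(nj_distance=nj_distances)
        write_table(sel, run.path("selections.tsv"))
    with open(run.path("trees/trees.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def stage_score(outdir: str | Path, cfg: PipelineConfig) -> dict:
    """Detection metrics against the truth ledger (synthetic runs only)."""
    run = RunDirectory(outdir)
    truth, planted_term = load_truth(run.data / "truth.json")

    dup = read_table(run.path("duplications.tsv"),
                     {"contig_ids": str, "dual_origin": str})
    sel = read_table(run.path("selections.tsv"),
                     {"nautilus_contig": str, "squid_contig": str})
    candidates = {
        "duplication": [row.contig_ids.split(";") for row in dup.itertuples()],
        "selection": [[row.nautilus_contig, row.squid_contig]
                      for row in sel.itertuples()],
    }
    det = score_detection(candidates, truth)

    up = _load_up_sets(run)
    expected_up = {
        cid: ("nautilus" if cid.startswith("naut_") else "squid")
        for rec in truth for cid, f in rec.expected_differential.items() if f
    }
    all_flags = {cid: f for rec in truth
                 for cid, f in rec.expected_differential.items()}
    selected = {c for s in up.values() for c in s}
    n_expected = len(expected_up)
    recovered = sum(1 for cid, s in expected_up.items() if cid in up.get(s, set()))
    non_diff = [cid for cid, f in all_flags.items() if not f]
    false_sel = sum(1 for cid in non_diff if cid in selected)

    enrich_df = read_table(run.path("enrichment.tsv"),
                           {"go_id": str, "direction": str, "q": float,
                            "significant": str})
    hit_rows = enrich_df[(enrich_df.go_id == planted_term)
                         & (enrich_df.direction == "over")
                         & enrich_df.significant.isin(["True", "true", "1"])]
    planted_recovered = bool(len(hit_rows))

    # origin accuracy over planted orthologs, from whole-proteome best hits
    origin_truth = {cid: org for rec in truth if rec.event_kind == "ortholog"
                    for cid, org in rec.expected_origin.items()}
    hits = pd.concat([run.read_hits(s) for s in SPECIES], ignore_index=True)
    winners = best_hits(hits)
    n_match = n_tot = 0
    for row in winners.itertuples():
        expected = origin_truth.get(row.contig_id)
        if expected is None:
            continue
        n_tot += 1
        n_match += int(row.organism == expected)

    trees = json.loads(run.path("trees/trees.json").read_text()) \
        if run.path("trees/trees.json").exists() else {"dual_origin": []}
    dual = trees.get("dual_origin", [])
    concordant = sum(1 for t in dual if t["concordant"])

    metrics = {
        "duplication": asdict(det["duplication"]),
        "selection": asdict(det["selection"]),
        "expression": {
            "recall": recovered / n_expected if n_expected else 1.0,
            "false_rate": false_sel / len(non_diff) if non_diff else 0.0,
            "n_expected": n_expected, "n_recovered": recovered,
        },
        "enrichment": {"planted_term": planted_term,
                       "recovered": planted_recovered},
        "origin_accuracy": n_match / n_tot if n_tot else None,
        "dual_origin_trees": {"n": len(dual), "concordant": concordant},
    }
    with open(run.path("metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return metrics


# ---------------------------------------------------------------------------
# full run


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, outdir: str | Path,
                 sim_config: SimulationConfig | None = None) -> dict:
    """Execute every stage in order and write ``report.json``/``report.txt``.

    With ``sim_config`` a synthetic dataset is generated first and scored
    against its truth ledger; otherwise ``<outdir>/data`` must already hold
    the input files (see ``_DATA_FILES``).
    """
    cfg.validate()
    run = RunDirectory(outdir)
    run.outdir.mkdir(parents=True, exist_ok=True)
    stages = []
    if sim_config is not None:
        stages.append(("simulate", lambda: stage_simulate(sim_config, outdir)))
    stages += [
        ("search", lambda: stage_search(outdir, cfg)),
        ("express", lambda: stage_express(outdir, cfg)),
        ("enrich", lambda: stage_enrich(outdir, cfg)),
        ("classify", lambda: stage_classify(outdir, cfg)),
        ("detect", lambda: stage_detect(outdir, cfg)),
        ("tree", lambda: stage_tree(outdir, cfg)),
    ]
    has_truth = sim_config is not None or (run.data / "truth.json").exists()
    if has_truth:
        stages.append(("score", lambda: stage_score(outdir, cfg)))
    for name, fn in stages:
        try:
            logger.info("stage %s", name)
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    report = _build_report(run, cfg, sim_config)
    with open(run.path("report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    run.path("report.txt").write_text(_format_report(report))
    return report


def _count_rows(path: Path) -> int:
    if not path.exists():
        return 0
    with open(path) as fh:
        return max(0, sum(1 for _ in fh) - 1)


def _build_report(run: RunDirectory, cfg: PipelineConfig,
                  sim_config: SimulationConfig | None) -> dict:
    contigs = run.read_contigs()
    counts = {
        "contigs_total": {s: len(contigs[s]) for s in SPECIES},
        "contigs_pass_length": {
            s: sum(1 for r in contigs[s] if len(r.sequence) > cfg.min_contig_len)
            for s in SPECIES},
        "hits": {s: _count_rows(run.path(f"hits_{s}.tsv")) for s in SPECIES},
        "up_regulated": {
            s: len(cs) for s, cs in sorted(_load_up_sets(run).items())},
        "enrichment_results": _count_rows(run.path("enrichment.tsv")),
        "eye_final": {
            s: _count_rows(run.path(f"assignments_{s}.tsv")) for s in SPECIES},
        "duplication_candidates": _count_rows(run.path("duplications.tsv")),
        "selection_candidates": _count_rows(run.path("selections.tsv")),
    }
    annotated = 0
    enrich_path = run.path("enrichment.tsv")
    if enrich_path.exists():
        df = pd.read_csv(enrich_path, sep="\t")
        counts["significant_terms"] = int(df["significant"].sum()) if len(df) else 0
    metrics = None
    if run.path("metrics.json").exists():
        metrics = json.loads(run.path("metrics.json").read_text())
    manifest = {}
    for path in sorted(run.outdir.rglob("*")):
        if path.is_file() and path.name not in ("report.json", "report.txt"):
            manifest[str(path.relative_to(run.outdir))] = _sha256(path)
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": asdict(cfg),
        "sim_config": asdict(sim_config) if sim_config else None,
        "counts": counts,
        "metrics": metrics,
        "files": manifest,
    }


def _format_report(report: dict) -> str:
    lines = ["eyevolve run report", "==================="]
    counts = report["counts"]
    for key in sorted(counts):
        lines.append(f"{key}: {counts[key]}")
    if report["metrics"]:
        lines.append("")
        lines.append("detection metrics vs truth:")
        for key in sorted(report["metrics"]):
            lines.append(f"  {key}: {report['metrics'][key]}")
    lines.append("")
    lines.append(f"files: {len(report['files'])}")
    return "\n".join(lines) + "\n"
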