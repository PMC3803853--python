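import math

import numpy as np
import pandas as pd
import pytest

from eyevolve.align import ScoringScheme
from eyevolve.io import SequenceRecord
from eyevolve.search import (best_hit, best_hits, bit_score_evalue, search,
                             search_blastx, search_native)
from eyevolve.simulate import SimulationConfig, generate_dataset, random_protein, reverse_translate


def test_bit_score_formula():
    bits, _ = bit_score_evalue(100, 100, 100)
    assert bits == pytest.approx(43.13, abs=0.01)


def test_evalue_formula_at_ten_bits():
    scheme = ScoringScheme()
    raw = (10 * math.log(2) + math.log(scheme.ka_k)) / scheme.ka_lambda
    _, evalue = bit_score_evalue(raw, 100, 100, scheme)
    assert evalue == pytest.approx(10000 / 1024, rel=1e-6)


def test_zero_bits_gives_search_space_evalue():
    scheme = ScoringScheme()
    raw = math.log(scheme.ka_k) / scheme.ka_lambda
    _, evalue = bit_score_evalue(raw, 37, 91, scheme)
    assert evalue == pytest.approx(37 * 91, rel=1e-9)


def test_exact_homologue_is_found_in_plus_one_frame(rng):
    prot = random_protein(120, rng)
    contig = SequenceRecord("c1", reverse_translate(prot, rng))
    hits = search_native([contig], {"human": [SequenceRecord("p1", prot)]})
    assert len(hits) == 1
    row = hits.iloc[0]
    assert row.frame == 1
    assert row.identity == 1.0
    assert (row.sstart, row.send) == (1, 120)
    assert (row.qstart, row.qend) == (1, 360)


def test_zero_cutoff_empties_the_table(rng):
    prot = random_protein(120, rng)
    contig = SequenceRecord("c1", reverse_translate(prot, rng))
    hits = search_native([contig], {"human": [SequenceRecord("p1", prot)]},
                         e_cutoff=0.0)
    assert hits.empty


def test_empty_proteome_warns_and_returns_empty(rng):
    contig = SequenceRecord("c1", reverse_translate(random_protein(80, rng), rng))
    assert search_native([contig], {"human": []}).empty


def _hit(contig, subject, bits, evalue):
    return dict(contig_id=contig, subject_id=subject, organism="human",
                frame=1, qstart=1, qend=3, sstart=1, send=1, raw=10.0,
                bits=bits, evalue=evalue, identity=1.0)


def test_best_hit_ordering_and_tie_breaks():
    table = pd.DataFrame([
        _hit("c1", "B", 35.0, 1e-5),
        _hit("c1", "A", 40.0, 1e-6),
        _hit("c2", "B", 40.0, 1e-6),
        _hit("c2", "A", 40.0, 1e-6),
    ])
    assert best_hit(table, "c1").subject_id == "A"      # higher bits win
    assert best_hit(table, "c2").subject_id == "A"      # full tie -> lexicographic
    assert best_hit(table, "missing") is None
    shuffled = table.iloc[::-1].reset_index(drop=True)
    assert best_hits(shuffled).set_index("contig_id").subject_id.to_dict() == \
        {"c1": "A", "c2": "A"}


@pytest.fixture(scope="module")
def mini_dataset(tmp_path_factory):
    cfg = SimulationConfig(n_families=12, n_duplications=2,
                           n_dual_origin_duplications=1,
                           n_selection_events=2, seed=5)
    return generate_dataset(cfg, tmp_path_factory.mktemp("mini"))


def test_native_and_blastx_engines_agree_on_best_hits(mini_dataset):
    """The exact engine and the BLAST+ backend assign the same best subject
    (and frame) to every contig of a small synthetic transcriptome."""
    bundle = mini_dataset
    proteomes = {"human": bundle.human_proteins, "fly": bundle.fly_proteins}
    contigs = bundle.contigs["nautilus"]
    native = search(contigs, proteomes, e_cutoff=1e-6, engine="native")
    blast = search(contigs, proteomes, e_cutoff=1e-6, engine="blastx")
    nb = best_hits(native).set_index("contig_id")
    bb = best_hits(blast).set_index("contig_id")
    shared = sorted(set(nb.index) & set(bb.index))
    assert len(shared) >= 0.9 * len(contigs)
    agree = sum(nb.subject_id[c] == bb.subject_id[c] for c in shared)
    assert agree == len(shared)
    assert all(int(nb.frame[c]) == int(bb.frame[c]) for c in shared)


def test_planted_orthologs_best_hit_their_own_family(mini_dataset):
    bundle = mini_dataset
    proteomes = {"human": bundle.human_proteins, "fly": bundle.fly_proteins}
    truth_origin = {
        cid: org for rec in bundle.truth if rec.event_kind == "ortholog"
        for cid, org in rec.expected_origin.items()
    }
    for species in ("nautilus", "squid"):
        hits = search(bundle.contigs[species], proteomes, e_cutoff=1e-6,
                      engine="native")
        winners = best_hits(hits)
        for row in winners.itertuples():
            expected = truth_origin.get(row.contig_id)
            if expected is None:
                continue
            fam = row.contig_id.split("_")[1]
            assert row.subject_id == f"{expected}_{fam}"
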