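import numpy as np
import pandas as pd
import pytest

from eyevolve.config import PipelineConfig
from eyevolve.events import (FrameCache, detect_duplications,
                             detect_selection_pairs, map_to_common_frame,
                             overlap_fraction, same_region,
                             window_conservation)
from eyevolve.simulate import random_protein, reverse_translate


class TestSameRegion:
    def test_starred_table_pair_overlaps(self):
        # the printed squid NF1/Nf1 intervals marked as "same region"
        assert same_region((1523, 1609), (1572, 1656))

    def test_disjoint_table_pair_does_not(self):
        assert not same_region((35, 318), (1597, 1919))

    def test_identical_intervals_always_overlap(self):
        assert same_region((7, 20), (7, 20))

    def test_symmetric_and_reflexive(self, rng):
        for _ in range(50):
            a0, b0 = rng.integers(1, 500, size=2)
            a = (int(a0), int(a0 + rng.integers(0, 200)))
            b = (int(b0), int(b0 + rng.integers(0, 200)))
            assert same_region(a, b) == same_region(b, a)
            assert same_region(a, a)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            same_region((10, 5), (1, 3))

    def test_overlap_fraction_matches_flag(self):
        assert overlap_fraction((1523, 1609), (1572, 1656)) == \
            pytest.approx(38 / 85)
        assert overlap_fraction((35, 318), (1597, 1919)) == 0.0


class TestCommonFrame:
    def test_identity_alignment_maps_unchanged(self):
        h = f = "MKVLNNRTE"
        assert map_to_common_frame((3, 6), h, f) == (3, 6)

    def test_insertion_before_interval_shifts_by_its_length(self):
        # ten human-only residues precede the aligned block
        h = "HHHHHHHHHH" + "MKVLNN"
        f = "----------" + "MKVLNN"
        assert map_to_common_frame((2, 5), h, f) == (12, 15)

    def test_gap_endpoints_slide_inward(self):
        h = "MK--LN"
        f = "MKVVLN"
        # fly 2..5 covers two fly-only residues; ends slide to aligned cols
        assert map_to_common_frame((2, 5), h, f) == (2, 3)

    def test_interval_entirely_opposite_gaps_is_unmappable(self):
        h = "MK---N"
        f = "MKVVLN"
        assert map_to_common_frame((3, 5), h, f) is None


class TestWindowConservation:
    def test_identical_homologues_are_fully_conserved(self):
        p = "MKVLNNRTEW"
        assert window_conservation(p, p, (2, 8)) == 1.0

    def test_mismatch_fraction_in_window(self):
        h = "MKVLNNRTEW"
        f = "MKVAANRTEW"
        ident = window_conservation(h, f, (1, 5), alignment=(h, f))
        assert ident == pytest.approx(3 / 5)

    def test_window_outside_protein_rejected(self):
        with pytest.raises(ValueError):
            window_conservation("MKV", "MKV", (2, 9))


def _records(rows):
    return pd.DataFrame(rows, columns=["contig_id", "species", "subject_id",
                                       "origin", "bits", "evalue", "sstart",
                                       "send", "eye_related", "qc_pass"])


def _mini_frames(rng, fam="famX", length=120):
    human = random_protein(length, rng)
    # ~55% identical homologue: mutate a random half of the sites
    fly = list(human)
    for i in rng.choice(length, size=length // 2, replace=False):
        fly[i] = "W" if fly[i] != "W" else "Y"
    fly = "".join(fly)
    hom = pd.DataFrame([{"human_protein_id": f"human_{fam}",
                         "fly_protein_id": f"fly_{fam}", "family_id": fam}])
    proteins = {f"human_{fam}": human, f"fly_{fam}": fly}
    return FrameCache(hom, proteins), human, fly


def test_near_identical_contigs_are_not_a_duplication(rng):
    """Two contigs at ~97% nucleotide identity sharing a best hit are treated
    as fragments/alleles, not duplication evidence."""
    frames, human, _ = _mini_frames(rng)
    dna = reverse_translate(human, rng)
    mutated = list(dna)
    n_mut = int(len(dna) * 0.03)
    for i in rng.choice(len(dna), size=n_mut, replace=False):
        mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
    contigs = {"c1": dna, "c2": "".join(mutated)}
    recs = _records([
        ("c1", "nautilus", "human_famX", "human", 100.0, 1e-30, 1, 120, True, True),
        ("c2", "nautilus", "human_famX", "human", 100.0, 1e-30, 1, 120, True, True),
    ])
    assert detect_duplications(recs, "nautilus", contigs, frames,
                               PipelineConfig()) == []


def test_diverged_contigs_sharing_a_best_hit_are_a_duplication(rng):
    frames, human, fly = _mini_frames(rng)
    # two clearly diverged copies of the same family, one per reference
    from eyevolve.simulate import evolve_protein
    a = evolve_protein(human, 0.12, rng)
    b = evolve_protein(fly, 0.12, rng)
    contigs = {"c1": reverse_translate(a, rng), "c2": reverse_translate(b, rng)}
    recs = _records([
        ("c1", "nautilus", "human_famX", "human", 100.0, 1e-30, 1, 120, True, True),
        ("c2", "nautilus", "fly_famX", "fly", 100.0, 1e-30, 1, 120, True, True),
    ])
    cands = detect_duplications(recs, "nautilus", contigs, frames,
                                PipelineConfig())
    assert len(cands) == 1
    c = cands[0]
    assert c.dual_origin and c.same_region
    assert c.max_pairwise_identity < 0.95
    assert sorted(c.contig_ids) == ["c1", "c2"]


def test_conserved_window_rejects_selection_pair(rng):
    """Cross-origin hits in a region where human and fly are near-identical
    carry no selection signal and are discarded."""
    fam = "famC"
    human = random_protein(120, rng)
    fly = human[:80] + random_protein(40, rng)   # conserved first 80 residues
    hom = pd.DataFrame([{"human_protein_id": f"human_{fam}",
                         "fly_protein_id": f"fly_{fam}", "family_id": fam}])
    frames = FrameCache(hom, {f"human_{fam}": human, f"fly_{fam}": fly})
    contigs = {"n1": "A" * 300, "s1": "A" * 300}
    naut = _records([("n1", "nautilus", f"fly_{fam}", "fly", 90.0, 1e-30,
                      1, 75, True, True)])
    squid = _records([("s1", "squid", f"human_{fam}", "human", 90.0, 1e-30,
                       1, 75, True, True)])
    assert detect_selection_pairs(naut, squid, contigs, frames,
                                  PipelineConfig()) == []
    # same setup, but hits in the non-conserved tail -> accepted
    naut2 = _records([("n1", "nautilus", f"fly_{fam}", "fly", 90.0, 1e-30,
                       81, 120, True, True)])
    squid2 = _records([("s1", "squid", f"human_{fam}", "human", 90.0, 1e-30,
                        81, 120, True, True)])
    cands = detect_selection_pairs(naut2, squid2, contigs, frames,
                                   PipelineConfig())
    assert len(cands) == 1
    assert cands[0].window_identity < 0.60
    assert {cands[0].nautilus_origin, cands[0].squid_origin} == {"human", "fly"}


def test_disjoint_hit_regions_reject_selection_pair(rng):
    fam = "famD"
    human = random_protein(200, rng)
    fly = random_protein(200, rng)
    hom = pd.DataFrame([{"human_protein_id": f"human_{fam}",
                         "fly_protein_id": f"fly_{fam}", "family_id": fam}])
    frames = FrameCache(hom, {f"human_{fam}": human, f"fly_{fam}": fly})
    contigs = {"n1": "A" * 300, "s1": "A" * 300}
    naut = _records([("n1", "nautilus", f"human_{fam}", "human", 90.0, 1e-30,
                      1, 60, True, True)])
    squid = _records([("s1", "squid", f"fly_{fam}", "fly", 90.0, 1e-30,
                       140, 200, True, True)])
    assert detect_selection_pairs(naut, squid, contigs, frames,
                                  PipelineConfig()) == []


def test_pipeline_candidates_respect_their_invariants(small_run):
    run, report = small_run
    dup = pd.read_csv(run.path("duplications.tsv"), sep="\t")
    assert (dup.max_identity < 0.95).all()
    sel = pd.read_csv(run.path("selections.tsv"), sep="\t")
    assert (sel.nautilus_origin != sel.squid_origin).all()
    assert (sel.window_identity < 0.60).all()
    assert (sel.overlap_fraction >= 0.4).all()


def test_planted_events_recovered_on_small_run(small_run):
    _, report = small_run
    m = report["metrics"]
    assert m["duplication"]["sensitivity"] == 1.0
    assert m["duplication"]["precision"] == 1.0
    assert m["selection"]["sensitivity"] == 1.0
    assert m["selection"]["precision"] == 1.0
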