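import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from eyevolve.simulate import (SimulationConfig, evolve_protein,
                               generate_dataset, plant_duplication,
                               plant_selection_event, random_protein,
                               score_detection, simulate_coverage,
                               sitewise_identity, TruthRecord)
from eyevolve.io import SequenceRecord


class TestEvolveProtein:
    def test_zero_probability_is_identity(self, rng):
        assert evolve_protein("MKV", 0.0, rng) == "MKV"

    def test_certain_substitution_always_changes(self, rng):
        for _ in range(20):
            out = evolve_protein("M", 1.0, rng)
            assert len(out) == 1 and out != "M"

    def test_rejects_non_amino_characters(self, rng):
        with pytest.raises(ValueError):
            evolve_protein("MKB!", 0.2, rng)

    def test_substitution_fraction_is_binomial(self):
        """Observed change fraction stays within 3 binomial SDs of p."""
        p, n = 0.2, 1000
        sd = math.sqrt(p * (1 - p) / n)
        seq = "A" * n
        for seed in range(20):
            r = np.random.default_rng(seed)
            changed = sum(1 for a, b in zip(seq, evolve_protein(seq, p, r))
                          if a != b) / n
            assert abs(changed - p) < 3 * sd


class TestPlantedEvents:
    def test_selection_window_identity_low_and_noise_free_limit(self):
        cfg = SimulationConfig(p_window_bias=0.0).validate()
        for seed in range(10):
            r = np.random.default_rng(seed)
            h0 = random_protein(120, r)
            f0 = evolve_protein(h0, cfg.p_global, r)
            h, f, naut, squid, info = plant_selection_event(h0, f0, cfg, r)
            lo, hi = info["window"]
            assert 1 <= lo <= hi <= 120
            win_ident = sitewise_identity(h[lo - 1:hi], f[lo - 1:hi])
            assert win_ident <= 0.30
            # with zero window noise each focal copy equals its reference
            # window exactly
            near = {"human": h, "fly": f}
            assert squid[lo - 1:hi] == near[info["origins"]["squid"]][lo - 1:hi]
            assert naut[lo - 1:hi] == near[info["origins"]["nautilus"]][lo - 1:hi]
            assert info["origins"]["squid"] != info["origins"]["nautilus"]

    def test_duplication_identity_band_holds_across_seeds(self):
        cfg = SimulationConfig()
        lo, hi = cfg.duplication_identity_range
        for seed in range(10):
            r = np.random.default_rng(seed)
            ref = random_protein(150, r)
            a, b = plant_duplication(ref, cfg, r)
            assert lo <= sitewise_identity(a, b) <= hi

    def test_dual_origin_copies_track_their_references(self):
        cfg = SimulationConfig()
        r = np.random.default_rng(3)
        h = random_protein(150, r)
        f = evolve_protein(h, cfg.p_global, r)
        a, b = plant_duplication(h, cfg, r, dual_origin=True, fly_prot=f)
        assert sitewise_identity(a, h) > sitewise_identity(a, f)
        assert sitewise_identity(b, f) > sitewise_identity(b, h)
        assert sitewise_identity(a, b) < 0.95


class TestCoverage:
    def test_degenerate_lognormal_gives_constant_coverage(self, rng):
        cfg = SimulationConfig(coverage_lognormal_params=(math.log(50), 0.0))
        recs = [SequenceRecord(f"c{i}", "ACGT" * 30) for i in range(5)]
        cov = simulate_coverage(recs, {r.id: "nautilus" for r in recs},
                                {}, cfg, rng)
        assert np.allclose(cov.aligned_bases / cov.contig_length, 50.0)

    def test_planted_differential_ratio_is_at_least_2_5(self, rng):
        cfg = SimulationConfig(coverage_lognormal_params=(math.log(50), 0.0))
        recs = [SequenceRecord("c0", "ACGT" * 30)]
        cov = simulate_coverage(recs, {"c0": "nautilus"}, {"c0": True}, cfg, rng)
        wide = cov.set_index("sample").aligned_bases
        assert wide["nautilus"] / wide["squid"] >= 2.5


class TestGenerateDataset:
    def test_same_seed_gives_byte_identical_output(self, tmp_path):
        cfg = SimulationConfig(n_families=15, n_duplications=2,
                               n_dual_origin_duplications=1,
                               n_selection_events=2, seed=42)
        a = generate_dataset(cfg, tmp_path / "a")
        b = generate_dataset(cfg, tmp_path / "b")
        for name in a.paths:
            assert a.paths[name].read_bytes() == b.paths[name].read_bytes(), name

    def test_bundle_counts_and_invariants(self, small_bundle):
        bundle = small_bundle
        cfg = bundle.config
        assert len(bundle.homologue_map) == cfg.n_families
        assert len(bundle.human_proteins) == cfg.n_families
        all_contigs = [c for s in bundle.contigs.values() for c in s]
        assert all(len(c.sequence) > 100 for c in all_contigs)
        emitted = {c.id for c in all_contigs}
        for rec in bundle.truth:
            assert set(rec.contig_ids) <= emitted
            if rec.window is not None:
                fam_len = len(next(
                    p.sequence for p in bundle.human_proteins
                    if p.id == f"human_{rec.family_id}"))
                assert 1 <= rec.window[0] <= rec.window[1] <= fam_len
        kinds = [t.event_kind for t in bundle.truth]
        assert kinds.count("selection") == cfg.n_selection_events
        assert kinds.count("dual_origin_duplication") == \
            cfg.n_dual_origin_duplications

    def test_event_families_carry_eye_annotations(self, small_bundle):
        eye_proteins = set(
            small_bundle.go_annotations
            .loc[small_bundle.go_annotations.eye_flag == 1, "protein_id"])
        for rec in small_bundle.truth:
            if rec.event_kind != "ortholog":
                assert f"human_{rec.family_id}" in eye_proteins

    def test_truth_json_round_trip(self, small_bundle):
        data = json.loads(small_bundle.paths["truth"].read_text())
        back = [TruthRecord.from_dict(d) for d in data["records"]]
        assert back == small_bundle.truth


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"p_global": 1.2},
        {"n_families": 5, "n_duplications": 4, "n_selection_events": 4},
        {"n_duplications": 2, "n_dual_origin_duplications": 3},
        {"family_length_range": (20, 100)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs).validate()


class TestScoreDetection:
    TRUTH = [
        TruthRecord(f"fam{i}", "duplication", [f"a{i}", f"b{i}"], {}, None, {})
        for i in range(10)
    ]

    def test_empty_candidates_give_zero_sensitivity_unit_precision(self):
        m = score_detection({"duplication": []}, self.TRUTH)["duplication"]
        assert (m.sensitivity, m.precision) == (0.0, 1.0)

    def test_perfect_candidates(self):
        cands = {"duplication": [t.contig_ids for t in self.TRUTH]}
        m = score_detection(cands, self.TRUTH)["duplication"]
        assert (m.sensitivity, m.precision) == (1.0, 1.0)

    def test_one_spurious_extra_among_ten(self):
        cands = {"duplication": [t.contig_ids for t in self.TRUTH]
                 + [["x", "y"]]}
        m = score_detection(cands, self.TRUTH)["duplication"]
        assert m.sensitivity == 1.0
        assert m.precision == pytest.approx(10 / 11)
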