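"""Generator correctness: determinism, recoverability, closed forms."""

import dataclasses
import math

import numpy as np
import pytest

import lickmicro as lm
from lickmicro.simulate import SimConfigError, expected_preference


class TestSimulateTrain:
    def test_degenerate_unit_clusters(self):
        params = lm.SimParams(cluster_size_mean=1.0, duration=600.0)
        tr = lm.simulate_train(params, np.random.default_rng(0))
        assert all(c.n_licks == 1 for c in lm.segment_clusters(tr, 0.5))

    def test_fixed_seed_reproducible(self):
        params = lm.SimParams(duration=600.0)
        a = lm.simulate_train(params, np.random.default_rng(42))
        b = lm.simulate_train(params, np.random.default_rng(42))
        np.testing.assert_array_equal(a.timestamps, b.timestamps)

    def test_unrecoverable_ili_config_rejected(self):
        with pytest.raises(SimConfigError, match="unrecoverable"):
            lm.SimParams(ili_mean=0.6)

    def test_generated_clusters_are_exactly_recoverable(self, rng):
        """Pauses > threshold and ILIs <= threshold: segmentation returns
        exactly the generated cluster structure."""
        params = lm.SimParams(duration=1200.0)
        tr = lm.simulate_train(params, rng)
        for c in lm.segment_clusters(tr, 0.5):
            assert np.all(c.within_ilis <= 0.5)
        ilis = lm.interlick_intervals(tr)
        # every gap is either a within-cluster ILI or a pause > threshold
        assert np.all((ilis <= 0.5) | (ilis > 0.5))
        assert np.all(ilis[ilis > 0.5] >= params.pause_min - 1e-9)

    def test_mean_cluster_size_recovered(self):
        params = lm.SimParams(cluster_size_mean=6.0, duration=3600.0,
                              pause_median=3.0)
        rng = np.random.default_rng(5)
        sizes = []
        while len(sizes) < 500:
            sizes += [c.n_licks for c in
                      lm.segment_clusters(lm.simulate_train(params, rng), 0.5)]
        sizes = np.asarray(sizes, float)
        sem = sizes.std(ddof=1) / math.sqrt(sizes.size)
        assert abs(sizes.mean() - 6.0) < 3 * sem

    def test_nbinom_law_mean_recovered(self):
        params = lm.SimParams(cluster_size_mean=6.0, cluster_size_law="nbinom",
                              duration=3600.0, pause_median=3.0)
        rng = np.random.default_rng(6)
        sizes = np.array([c.n_licks for c in
                          lm.segment_clusters(lm.simulate_train(params, rng), 0.5)], float)
        sem = sizes.std(ddof=1) / math.sqrt(sizes.size)
        assert abs(sizes.mean() - 6.0) < 4 * sem

    def test_satiety_inflates_late_pauses(self):
        params = lm.SimParams(duration=3600.0, satiety_decay=0.02)
        tr = lm.simulate_train(params, np.random.default_rng(7))
        clusters = lm.segment_clusters(tr, 0.5)
        starts = np.array([c.start_time for c in clusters])
        gaps = np.diff(starts)
        half = gaps.size // 2
        assert gaps[half:].mean() > gaps[:half].mean()


class TestPreferenceSession:
    def test_symmetric_config_gives_half(self):
        params = lm.SimParams(duration=900.0)
        scores = []
        for i in range(50):
            s = lm.simulate_preference_session(
                f"r{i}", "NR", params, params, 0.5, np.random.default_rng(100 + i))
            scores.append(lm.preference_score(
                s.train_for_solution("casein").n_licks,
                s.train_for_solution("maltodextrin").n_licks))
        scores = np.asarray(scores)
        sem = scores.std(ddof=1) / math.sqrt(scores.size)
        assert abs(scores.mean() - 0.5) < 3 * sem

    def test_p_one_gives_score_one(self):
        params = lm.SimParams(duration=600.0)
        s = lm.simulate_preference_session("r", "PR", params, params, 1.0,
                                           np.random.default_rng(1))
        assert s.train_for_solution("maltodextrin").n_licks == 0
        assert lm.preference_score(
            s.train_for_solution("casein").n_licks, 0) == 1.0

    def test_closed_form_expectation_recovered(self):
        """p = 0.6, mu_c = 7.5, mu_m = 5 -> expected score 0.6923."""
        pc = lm.SimParams(cluster_size_mean=7.5, duration=1800.0)
        pm = lm.SimParams(cluster_size_mean=5.0, duration=1800.0)
        expected = expected_preference(0.6, 7.5, 5.0)
        assert expected == pytest.approx(0.6923, abs=5e-5)
        scores = []
        for i in range(40):
            s = lm.simulate_preference_session(
                f"r{i}", "PR", pc, pm, 0.6, np.random.default_rng(500 + i))
            scores.append(lm.preference_score(
                s.train_for_solution("casein").n_licks,
                s.train_for_solution("maltodextrin").n_licks))
        scores = np.asarray(scores)
        sem = scores.std(ddof=1) / math.sqrt(scores.size)
        assert abs(scores.mean() - expected) < 3 * sem


class TestSimulateExperiment:
    def test_structure_matches_design(self):
        cfg = lm.CohortConfig(n_rats=3, n_conditioning_days=4,
                              base_params=lm.SimParams(duration=300.0), seed=1)
        data = lm.simulate_experiment(cfg)
        # 2 groups x 3 rats x (4 conditioning + 1 preference)
        assert len(data.sessions) == 2 * 3 * 5
        prefs = [s for s in data.sessions if s.session_type == "preference"]
        assert len(prefs) == 6 and all(len(s.bottles) == 2 for s in prefs)
        conds = [s for s in data.sessions if s.session_type == "conditioning"]
        assert all(len(s.bottles) == 1 for s in conds)
        # each rat sees each solution on 2 of the 4 conditioning days
        for rat in {s.rat_id for s in conds}:
            sols = [s.solutions[0] for s in conds if s.rat_id == rat]
            assert sorted(sols) == ["casein", "casein", "maltodextrin", "maltodextrin"]
        # cage table mirrors the described housing: 3-rat main + 2-rat pilot cages
        assert len(data.cage_intake) == 16
        assert {c.n_rats for c in data.cage_intake} == {2, 3}

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = lm.CohortConfig(n_rats=2, n_conditioning_days=1,
                              base_params=lm.SimParams(duration=300.0), seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        lm.simulate_experiment(cfg).write(d1)
        lm.simulate_experiment(cfg).write(d2)
        for name in ("licks.csv", "intake.csv", "manifest.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_adding_a_rat_never_perturbs_others(self):
        base = lm.CohortConfig(n_rats=2, n_conditioning_days=1,
                               base_params=lm.SimParams(duration=300.0), seed=4)
        bigger = dataclasses.replace(base, n_rats=3)
        small = lm.simulate_experiment(base).sessions
        big = lm.simulate_experiment(bigger).sessions
        big_by_key = {(s.rat_id, s.session_type, s.day_index): s for s in big}
        for s in small:
            match = big_by_key[(s.rat_id, s.session_type, s.day_index)]
            for ta, tb in zip(s.bottles, match.bottles):
                np.testing.assert_array_equal(ta.timestamps, tb.timestamps)

    def test_manifest_carries_ground_truth(self):
        cfg = lm.CohortConfig(n_rats=2, base_params=lm.SimParams(duration=300.0))
        m = lm.simulate_experiment(cfg).manifest
        assert m["expected"]["preference_PR"] == pytest.approx(
            expected_preference(0.75, 6.0 * 1.4, 6.0))
        assert m["config"]["seed"] == cfg.seed

    def test_single_rat_cohort_degrades_gracefully(self):
        """n = 1 per group: the ANOVA refuses with a clear error rather
        than emitting undefined statistics."""
        from lickmicro.calibration import simulate_preference_cohort
        from lickmicro.stats import MixedAnova
        cfg = lm.CohortConfig(n_rats=1, base_params=lm.SimParams(duration=300.0))
        frame = simulate_preference_cohort(cfg, seed=2)
        with pytest.raises(ValueError, match=">= 2 subjects"):
            MixedAnova(frame, dv="licks_per_cluster", subject="rat",
                       between="group", within="solution").fit()
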