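import numpy as np
import pytest

import sagarep as sr
from sagarep.overlap import state_presence_windows
from sagarep.simulate import SimulationError, redraw_verification, truth_pi


class TestDefaultStateCount:
    @pytest.mark.parametrize("n,expected", [(11, 16), (1, 12), (9, 16), (13, 17)])
    def test_heuristic(self, n, expected):
        assert sr.default_state_count(n) == expected

    def test_rejects_zero_assays(self):
        with pytest.raises(SimulationError):
            sr.default_state_count(0)


class TestGeneratePair:
    def test_noise_free_pair_is_identical_and_fully_confident(self):
        cfg = sr.GeneratorConfig(G=3000, K=5, flip_prob=0.0, jitter_sd=0.0, seed=1)
        truth = sr.generate_pair(cfg)
        assert np.array_equal(truth.base.labels, truth.verif.labels)
        assert np.array_equal(truth.verif.labels, truth.true_labels)
        res = sr.ReproducibilityModel(truth.base, truth.verif, w=0, b=10).fit()
        np.testing.assert_allclose(res.rvalues.r, 1.0)

    def test_same_seed_reproduces_pair_exactly(self):
        cfg = sr.GeneratorConfig(G=2000, K=6, flip_prob=0.3, jitter_sd=1.0, seed=9)
        t1, t2 = sr.generate_pair(cfg), sr.generate_pair(cfg)
        assert np.array_equal(t1.base.labels, t2.base.labels)
        assert np.array_equal(t1.base.posterior, t2.base.posterior)
        assert np.array_equal(t1.verif.labels, t2.verif.labels)
        assert np.array_equal(t1.pi, t2.pi)

    def test_posterior_rows_normalized_and_map_consistent(self):
        cfg = sr.GeneratorConfig(G=2000, K=6, flip_prob=0.2, seed=3)
        truth = sr.generate_pair(cfg)
        np.testing.assert_allclose(truth.base.posterior.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(
            np.argmax(truth.base.posterior, axis=1), truth.base.labels
        )

    def test_adjacent_segments_differ(self):
        cfg = sr.GeneratorConfig(G=5000, K=4, seed=5)
        truth = sr.generate_pair(cfg)
        for segs in truth.segments.values():
            states = [s.state for s in segs]
            assert all(a != b for a, b in zip(states, states[1:]))

    def test_split_states_extend_verification_alphabet(self):
        cfg = sr.GeneratorConfig(G=5000, K=4, flip_prob=0.0,
                                 split_states={0: 2, 2: 3}, seed=2)
        truth = sr.generate_pair(cfg)
        assert truth.verif.K == 4 + 3
        # substates of a split state occupy exactly the true state's bins
        sub = np.isin(truth.verif.labels, [0, 4])
        assert np.array_equal(sub, truth.true_labels == 0)


class TestTruthPi:
    def test_no_jitter_interior_pi_is_one_minus_flip(self):
        cfg = sr.GeneratorConfig(G=4000, K=8, flip_prob=0.3, jitter_sd=0.0, seed=7)
        truth = sr.generate_pair(cfg, w=0)
        np.testing.assert_allclose(truth.pi, 0.7, atol=1e-12)

    def test_wide_window_erases_boundary_effects(self):
        cfg = sr.GeneratorConfig(G=2000, K=8, flip_prob=0.2, jitter_sd=2.0,
                                 mean_segment_len=15, seed=4)
        pi = sr.generate_pair(cfg, w=100 * 200).pi
        # window >> jitter: visibility terms saturate, only flips remain
        np.testing.assert_allclose(pi, np.maximum(0.8, pi), atol=1e-9)
        assert pi.min() >= 0.8 - 1e-9

    def test_boundary_bin_matches_monte_carlo(self):
        # single boundary-bin check at jitter sd = 2 bins, w = 0
        cfg = sr.GeneratorConfig(G=2000, K=16, flip_prob=0.2, jitter_sd=2.0,
                                 mean_segment_len=30, seed=12)
        truth = sr.generate_pair(cfg, w=0)
        segs = truth.segments["chrS1"]
        # first bin of a long interior segment with long neighbours
        idx = next(
            i for i in range(1, len(segs) - 1)
            if min(segs[j].end - segs[j].start for j in (i - 1, i, i + 1)) >= 12
        )
        g = segs[idx].start
        n = 4000
        hits = sum(
            redraw_verification(truth, seed=50_000 + i)[g] == truth.true_labels[g]
            for i in range(n)
        )
        emp = hits / n
        se = np.sqrt(emp * (1 - emp) / n)
        assert abs(emp - truth.pi[g]) <= 3 * se

    def test_class_frequencies_match_within_three_se(self):
        # Monte-Carlo validation of the closed form per distance-to-edge
        # class, restricted to its validity regime (segments >> jitter sd)
        cfg = sr.GeneratorConfig(G=3000, K=16, flip_prob=0.2, jitter_sd=1.5,
                                 mean_segment_len=25, seed=5)
        truth = sr.generate_pair(cfg, w=0)
        segs = truth.segments["chrS1"]
        dist = np.full(cfg.G, -1.0)
        for i, s in enumerate(segs):
            neighbours = [s] + [segs[j] for j in (i - 1, i + 1)
                                if 0 <= j < len(segs)]
            if min(x.end - x.start for x in neighbours) >= 9:
                g = np.arange(s.start, s.end)
                dist[s.start:s.end] = np.minimum(g - s.start, s.end - 1 - g)
        classes = [np.flatnonzero(dist == d) for d in range(4)]
        classes.append(np.flatnonzero(dist >= 4))
        n = 500
        per_draw = np.empty((n, len(classes)))
        for i in range(n):
            rep = redraw_verification(truth, seed=10_000 + i) == truth.true_labels
            per_draw[i] = [rep[c].mean() for c in classes]
        for j, idx in enumerate(classes):
            bias = per_draw[:, j].mean() - truth.pi[idx].mean()
            se = per_draw[:, j].std(ddof=1) / np.sqrt(n)
            assert abs(bias) <= 3 * se, f"class {j}: bias {bias:+.4f}, se {se:.4f}"

    def test_windowed_empirical_frequency_matches(self):
        cfg = sr.GeneratorConfig(G=2000, K=16, flip_prob=0.2, jitter_sd=1.5,
                                 mean_segment_len=25, seed=6)
        w = 400  # 2 bins
        truth = sr.generate_pair(cfg, w=w)
        segs = truth.segments["chrS1"]
        ok = np.zeros(cfg.G, dtype=bool)
        for i, s in enumerate(segs):
            neighbours = [s] + [segs[j] for j in (i - 1, i + 1)
                                if 0 <= j < len(segs)]
            if min(x.end - x.start for x in neighbours) >= 9:
                ok[s.start:s.end] = True
        n = 400
        per_draw = np.empty(n)
        wb = truth.genome.bins_per_window(w)
        for i in range(n):
            labs = redraw_verification(truth, seed=30_000 + i)
            V = sr.Annotation(truth.genome, labs, K=cfg.K)
            rep = state_presence_windows(V, wb)[np.arange(cfg.G), truth.true_labels]
            per_draw[i] = rep[ok].mean()
        bias = per_draw.mean() - truth.pi[ok].mean()
        se = per_draw.std(ddof=1) / np.sqrt(n)
        assert abs(bias) <= 3 * se


class TestSettings:
    def test_shared_model_more_reproducible_than_independent(self):
        cfg = sr.GeneratorConfig(G=30_000, K=8, flip_prob=0.25,
                                 obs_flip_prob=0.05, jitter_sd=1.0, seed=21)
        overlaps = {}
        for setting in ("S1", "S2"):
            a, b = sr.generate_setting_pair(cfg, setting)
            corr = sr.match_states(sr.iou_matrix(sr.joint_overlap(a, b)))
            _, overlaps[setting] = sr.naive_overlap(a, b, corr)
        assert overlaps["S2"] > overlaps["S1"]

    def test_s3_pair_valid_and_distinct(self):
        cfg = sr.GeneratorConfig(G=10_000, K=6, flip_prob=0.2, seed=8)
        a, b = sr.generate_setting_pair(cfg, "S3")
        assert not np.array_equal(a.labels, b.labels)
        _, overall = sr.naive_overlap(
            a, b, sr.match_states(sr.iou_matrix(sr.joint_overlap(a, b)))
        )
        assert 0.3 < overall < 1.0


class TestCalibrationRecovery:
    def test_identity_calibration_recovered(self):
        # posteriors equal to the true reproduction probability: the fitted
        # calibration curve should approximate the identity on [0.5, 1].
        # Short segments maximize the number of independent flip units.
        cfg = sr.GeneratorConfig(G=200_000, K=2, mean_segment_len=5,
                                 flip_prob_range=(0.0, 0.5),
                                 calibrated_posteriors=True, seed=2)
        truth = sr.generate_pair(cfg, w=0)
        res = sr.ReproducibilityModel(truth.base, truth.verif, w=0, b=25,
                                      matching="plain").fit()
        for curve in res.calibration_curves.values():
            sel = curve.x >= 0.5
            mae = float(np.mean(np.abs(curve.fitted[sel] - curve.x[sel])))
            assert mae <= 0.02
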