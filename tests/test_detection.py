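"""Classifier training, sliding-window evaluation, metrics and tests."""

import numpy as np
import pytest

import moveintent as mi
from moveintent.detection import (
    DetectionSummary,
    PredictionTimeline,
    _split,
    extract_session_features,
)


@pytest.fixture(scope="module")
def small_feats(clean_small):
    cfg = mi.DetectorConfig(n_repeats=5, seed=0)
    return extract_session_features(clean_small, cfg), cfg


class TestTimelineGrid:
    def test_grid_arithmetic(self):
        grid = mi.timeline_grid(-10.0, 1.0, 0.1)
        assert grid.size == 101
        assert grid[0] == pytest.approx(-9.0)
        assert grid[-1] == pytest.approx(1.0)
        assert np.allclose(np.diff(grid), 0.1)

    def test_grid_never_reaches_into_missing_data(self):
        grid = mi.timeline_grid(-6.0, 1.0, 0.1)
        assert grid[0] >= -5.0 - 1e-9


class TestTrainDetector:
    def test_separable_clouds_learned(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 10)), rng.normal(4, 1, (50, 10))])
        y = np.repeat([0, 1], 50)
        clf = mi.train_detector(X, y, mi.DetectorConfig())
        assert clf.score(X, y) >= 0.95

    def test_permuted_labels_give_chance(self, rng):
        X = np.vstack([rng.normal(0, 1, (60, 10)), rng.normal(4, 1, (60, 10))])
        y = rng.permutation(np.repeat([0, 1], 60))
        clf = mi.train_detector(X[:80], y[:80], mi.DetectorConfig())
        acc = clf.score(X[80:], y[80:])
        assert 0.30 <= acc <= 0.70  # binomial CI around 0.5 at n=40

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            mi.train_detector(X, np.zeros(10), mi.DetectorConfig())


class TestEvaluateOnce:
    def test_deterministic_given_rng_state(self, small_feats):
        feats, cfg = small_feats
        r1 = mi.evaluate_once(feats, cfg, np.random.default_rng(3))
        r2 = mi.evaluate_once(feats, cfg, np.random.default_rng(3))
        assert r1.ca == r2.ca and r1.tpe == r2.tpe and r1.tne == r2.tne
        np.testing.assert_array_equal(r1.da, r2.da)

    def test_ca_is_pooled_rate(self, small_feats):
        feats, cfg = small_feats
        res = mi.evaluate_once(feats, cfg, np.random.default_rng(5))
        # balanced phase windows make CA the plain mean of TPE and TNE
        assert res.ca == pytest.approx((res.tpe + res.tne) / 2)
        for v in (res.ca, res.tpe, res.tne):
            assert 0.0 <= v <= 1.0
        assert np.all((res.da >= 0) & (res.da <= 1))

    def test_trial_level_split(self):
        train, test = _split(96, 0.8, np.random.default_rng(0))
        assert train.size == 77 and test.size == 19
        assert np.intersect1d(train, test).size == 0


class TestRepeatedEvaluation:
    def test_distributions_shape(self, small_feats):
        feats, cfg = small_feats
        summary = mi.repeated_evaluation(feats, cfg, seed=1)
        assert summary.ca.shape == (cfg.n_repeats,)
        assert summary.da.shape == (cfg.n_repeats, feats.grid.size)
        assert len(summary.timelines) > 0

    def test_single_repeat_warns(self, small_feats):
        feats, _ = small_feats
        cfg = mi.DetectorConfig(n_repeats=1, seed=0)
        with pytest.warns(UserWarning):
            mi.repeated_evaluation(feats, cfg, seed=1)


class TestPermutationChance:
    def test_chance_level_near_half_and_deterministic(self, clean_small):
        # 20 runs: few enough to stay fast, enough that residual label
        # alignment in single permutations averages out of the chance curve
        cfg = mi.DetectorConfig(n_repeats=20, seed=0)
        feats = extract_session_features(clean_small, cfg)
        da1, ca1 = mi.permutation_chance(feats, cfg, seed=2)
        da2, ca2 = mi.permutation_chance(feats, cfg, seed=2)
        np.testing.assert_array_equal(da1, da2)
        assert ca1 == ca2
        assert 0.40 <= ca1 <= 0.65  # small-sample spread around 0.5
        # chance DA has no time locking: pre- and post-onset levels agree
        prof = da1.mean(axis=0)
        grid = feats.grid
        assert abs(prof[grid < -1.0].mean() - prof[grid > 0.0].mean()) < 0.2


def _constructed_summary(da_high_from, n_repeats=30):
    grid = mi.timeline_grid(-3.0, 1.0, 0.1)
    da = np.where(grid >= da_high_from - 1e-9, 1.0, 0.5)
    da = np.tile(da, (n_repeats, 1))
    da_sig = np.full((n_repeats, grid.size), 0.5)
    timelines = [PredictionTimeline(times=grid,
                                    labels=(grid >= da_high_from).astype(int))
                 for _ in range(10)]
    return DetectionSummary(grid=grid, ca=np.full(n_repeats, 0.8),
                            tpe=np.full(n_repeats, 0.8),
                            tne=np.full(n_repeats, 0.8),
                            da=da, da_sig=da_sig, ca_sig=0.52,
                            timelines=timelines)


class TestDetectionMetrics:
    def test_constructed_strong_separation_recovers_tmi(self):
        summary = _constructed_summary(da_high_from=-1.0)
        cfg = mi.DetectorConfig(n_repeats=30)
        tmi, ntd = mi.detection_metrics(summary, cfg)
        assert tmi == pytest.approx(-1.0)
        assert ntd == 1.0  # every timeline holds a sustained pre-onset run

    def test_null_gives_undefined_metrics(self):
        summary = _constructed_summary(da_high_from=2.0)  # never above chance
        summary.da = summary.da_sig.copy()
        tmi, ntd = mi.detection_metrics(summary, mi.DetectorConfig())
        assert tmi is None and ntd is None

    def test_post_onset_only_separation_gives_undefined_tmi(self):
        summary = _constructed_summary(da_high_from=0.3)
        tmi, ntd = mi.detection_metrics(summary, mi.DetectorConfig())
        assert tmi is None and ntd is None


class TestSignificanceTests:
    def test_identical_samples_no_rejection(self):
        summary = _constructed_summary(-1.0)
        summary.ca = np.full(30, 0.52)
        summary.ca_sig = 0.52
        out = mi.significance_tests(summary, mi.DetectorConfig())
        assert out["ca_above_chance"] is False

    def test_consistent_margin_rejects_at_n30(self):
        summary = _constructed_summary(-1.0)
        summary.ca = 0.60 + np.linspace(0, 0.01, 30)
        summary.ca_sig = 0.52
        out = mi.significance_tests(summary, mi.DetectorConfig())
        assert out["p_ca"] < 0.01 and out["ca_above_chance"] is True

    def test_five_repeats_cannot_reach_one_percent(self):
        summary = _constructed_summary(-1.0, n_repeats=5)
        summary.ca = 0.60 + np.linspace(0, 0.01, 5)
        summary.ca_sig = 0.52
        out = mi.significance_tests(summary, mi.DetectorConfig())
        # minimal attainable two-sided signed-rank p at n=5 is 1/16
        assert out["p_ca"] >= 1 / 16 - 1e-12
        assert out["ca_above_chance"] is False


class TestNoLeakage:
    def test_scaling_and_training_use_training_trials_only(self, small_feats,
                                                           clean_small):
        feats, cfg = small_feats
        # corrupting a known test trial must not change the fitted model's
        # predictions on other trials
        rng = np.random.default_rng(9)
        train_idx, test_idx = _split(len(feats.trials), cfg.train_fraction, rng)
        victim = test_idx[0]
        feats2 = extract_session_features(clean_small, cfg)
        feats2.trials[victim].train_X = feats2.trials[victim].train_X * 100.0
        feats2.trials[victim].grid_X = feats2.trials[victim].grid_X * 100.0
        r1 = mi.evaluate_once(feats, cfg, np.random.default_rng(9))
        r2 = mi.evaluate_once(feats2, cfg, np.random.default_rng(9))
        other = [i for i, t in enumerate(test_idx) if t != victim]
        for i in other:
            np.testing.assert_array_equal(r1.timelines[i].labels,
                                          r2.timelines[i].labels)
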