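"""Time-frequency maps, the ERDS formula, bootstrap mask, band tables."""

import numpy as np
import pytest

import moveintent as mi
from moveintent.erds import ERDSMap, TFRStack

FS = 256.0


def one_channel_session(trials_data, t0=-6.0):
    trials = [mi.Trial(eeg=np.atleast_2d(x), emg=None, fs=FS, t0=t0,
                       time_ref="onset", onset=5.0) for x in trials_data]
    return mi.Session(subject="t", trials=trials, fs=FS, eeg_labels=["Cz"],
                      emg_labels=[])


def synthetic_stack(power, n_trials=30, noise=0.0, seed=0):
    """TFRStack with prescribed mean power (F, T) plus optional jitter."""
    rng = np.random.default_rng(seed)
    F, T = power.shape
    p = np.tile(power, (n_trials, 1, 1, 1))  # (trials, 1 channel, F, T)
    if noise:
        p = p * rng.lognormal(0.0, noise, size=p.shape)
    times = np.linspace(-6, 1, T)
    return TFRStack(power=p.astype(np.float32),
                    freqs=np.arange(2.0, 2.0 + F), times=times,
                    valid=np.ones((F, T), dtype=bool), channels=["Cz"])


class TestTrimCommon:
    def test_spans_and_no_drops_after_screening(self, clean_small,
                                                trimmed_small):
        assert trimmed_small.n_trials == clean_small.n_trials
        for trial in trimmed_small.trials:
            assert trial.t0 == pytest.approx(-6.0)
            assert trial.n_samples == int(7 * FS)

    def test_short_trial_dropped(self):
        t = np.zeros(int(6 * FS))
        sess = one_channel_session([t], t0=-5.0)  # spans [-5, 1): too short
        out = mi.trim_common(sess)
        assert out.n_trials == 0

    def test_requires_onset_reference(self, small_session):
        sess, _, _ = small_session
        with pytest.raises(ValueError):
            mi.trim_common(sess)


class TestMorletTfr:
    def test_pure_tone_peaks_at_its_frequency(self):
        t = -6.0 + np.arange(int(7 * FS)) / FS
        sess = one_channel_session([10 * np.sin(2 * np.pi * 10 * t)])
        tfrs = mi.compute_tfr(sess)
        avg = np.where(tfrs.valid, tfrs.power[0, 0], np.nan)
        profile = np.nanmean(avg, axis=1)
        assert tfrs.freqs[np.nanargmax(profile)] == 10.0

    def test_amplitude_step_quarters_power(self):
        t = -6.0 + np.arange(int(7 * FS)) / FS
        amp = np.where(t < 0, 10.0, 5.0)
        sess = one_channel_session([amp * np.sin(2 * np.pi * 10 * t)])
        tfrs = mi.compute_tfr(sess)
        row = list(tfrs.freqs).index(10.0)
        p = tfrs.power[0, 0, row]
        pre = p[(tfrs.times > -5) & (tfrs.times < -1)].mean()
        post = p[(tfrs.times > 0.3) & (tfrs.times < 0.9)].mean()
        assert post / pre == pytest.approx(0.25, rel=0.10)

    def test_white_noise_power_flat_in_time(self, rng):
        xs = rng.standard_normal((150, int(7 * FS)))
        tfrs = mi.compute_tfr(one_channel_session(list(xs)))
        avg = tfrs.power[:, 0].mean(axis=0)  # (F, T)
        for row in [6, 18, 28]:  # 8, 20, 30 Hz
            vals = avg[row][tfrs.valid[row]]
            assert vals.std() / vals.mean() < 0.10

    def test_frequency_above_nyquist_rejected(self, trimmed_small):
        with pytest.raises(ValueError):
            mi.compute_tfr(trimmed_small, freqs=np.array([200.0]))


class TestErdsMap:
    def test_formula_gives_minus_50_for_halved_power(self):
        F, T = 5, 140
        power = np.ones((F, T))
        power[:, 100:] = 0.5  # power halves late in the trial
        m = mi.erds_map(synthetic_stack(power), "Cz")
        assert np.allclose(m.erds[:, 100:], -50.0)
        assert np.allclose(m.erds[:, :100][:, 10:90], 0.0)

    def test_stationary_input_is_flat(self, rng):
        xs = rng.standard_normal((100, int(7 * FS)))
        tfrs = mi.compute_tfr(one_channel_session(list(xs)))
        m = mi.erds_map(tfrs, "Cz")
        # cell-level noise is ~10-15 % at 100 trials; the map is flat on
        # average and band/window summaries are near zero
        assert abs(np.nanmean(m.erds)) < 3.0
        assert np.nanmean(np.abs(m.erds) > 50.0) < 0.01
        assert abs(mi.band_average(m, (8, 13), (0, 1))) < 5.0

    def test_lower_bound_minus_100(self, trimmed_small):
        tfrs = mi.compute_tfr(trimmed_small)
        for ch in range(3):
            m = mi.erds_map(tfrs, ch)
            assert np.nanmin(m.erds) >= -100.0

    def test_zero_baseline_rejected(self):
        power = np.ones((3, 140))
        stack = synthetic_stack(power)
        stack.power[:, :, 1, :60] = 0.0  # kill the whole baseline of one frequency
        with pytest.raises(ValueError, match="baseline"):
            mi.erds_map(stack, "Cz")


class TestBootstrapMask:
    def test_deterministic_given_seed(self):
        power = np.ones((4, 140))
        power[1, 100:] = 0.6
        stack = synthetic_stack(power, noise=0.3, seed=4)
        m1 = mi.bootstrap_mask(stack, "Cz", B=200, seed=11)
        m2 = mi.bootstrap_mask(stack, "Cz", B=200, seed=11)
        np.testing.assert_array_equal(m1, m2)

    def test_identical_trials_flag_every_nonzero_cell(self):
        power = np.ones((4, 140))
        power[1, 100:] = 0.5
        stack = synthetic_stack(power, n_trials=25, noise=0.0)
        mask = mi.bootstrap_mask(stack, "Cz", B=200, seed=0)
        assert mask[1, 100:].all()          # true ERD: zero bootstrap variance
        assert not mask[0].any()            # exactly zero ERDS elsewhere
        assert not mask[1, 10:90].any()

    def test_detects_planted_erd_not_baseline(self):
        power = np.ones((6, 140))
        power[2:4, 110:] = 0.5
        stack = synthetic_stack(power, n_trials=40, noise=0.25, seed=6)
        mask = mi.bootstrap_mask(stack, "Cz", B=400, seed=1)
        assert mask[2:4, 115:].mean() > 0.9
        assert mask[:, 5:35].mean() < 0.1   # baseline interval stays quiet

    def test_guards(self):
        stack = synthetic_stack(np.ones((3, 140)), n_trials=10)
        with pytest.raises(ValueError):
            mi.bootstrap_mask(stack, "Cz", B=50, seed=0)
        with pytest.raises(ValueError):
            mi.bootstrap_mask(stack, "Cz", B=500, seed=0)  # < 20 trials


class TestBandWindowTable:
    def _masked_map(self, erds_value, sig):
        F, T = 39, 140
        erds = np.full((F, T), float(erds_value))
        mask = np.full((F, T), bool(sig))
        return ERDSMap(erds=erds, freqs=np.arange(2.0, 41.0),
                       times=np.linspace(-6, 1, T), baseline=(-6, -3),
                       channel="Cz", mask=mask, alpha=0.05)

    def test_no_significant_cells_give_exact_zero(self):
        table = mi.band_window_table([self._masked_map(-30.0, False)])
        vals = table.drop(columns=["channel", "band"]).to_numpy(dtype=float)
        assert np.all(vals == 0.0)

    def test_uniform_significant_erds_passes_through(self):
        table = mi.band_window_table([self._masked_map(-30.0, True)])
        vals = table.drop(columns=["channel", "band"]).to_numpy(dtype=float)
        assert np.allclose(vals, -30.0)

    def test_requires_mask(self):
        m = self._masked_map(-30.0, True)
        m.mask = None
        with pytest.raises(ValueError):
            mi.band_window_table([m])

    def test_average_row_added(self):
        table = mi.band_window_table([self._masked_map(-30.0, True),
                                      self._masked_map(-10.0, True)])
        avg = table[table.channel == "Avg"]
        assert len(avg) == 2  # one row per band
        assert np.allclose(avg["[0,1)"], -20.0)
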