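"""Synthetic EEG+EMG sessions for self-paced reaching experiments.

The generator emulates the statistical structure the analysis pipeline
assumes, with known ground truth so that every downstream stage can be
tested as a parameter-recovery problem:

* cue-locked 18 s trials (relax cue 3 s -> move cue 12 s -> rest cue 3 s),
  an even left/right split presented in a seeded shuffle;
* self-paced movement onsets drawn from a truncated normal
  N(7.04, 1.42^2) s after the move cue, truncated to [3, 11] s;
* background EEG as Gaussian 1/f noise, per-channel independent plus a
  shared component that induces spatial correlation (so the common average
  reference does nontrivial work);
* alpha- and beta-band oscillations (band-limited Gaussian noise) on the
  nine motor channels whose amplitude ramps down linearly from ``erd_lead``
  seconds before the true onset, producing an event-related power drop of
  ``erd_depth_alpha`` / ``erd_depth_beta`` during execution;
* EMG that is quiescent until the onset and then bursts on the moved arm's
  channels.  The burst morphology (rectangular RMS step with a 30 ms rise)
  is a stand-in: real reaching EMG shape is not modelled, only its
  detectability by a high-pass + Hilbert-envelope onset detector.

Generation runs at the full acquisition rate (2048 Hz) so that the
pipeline's resampling stage is genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .session import (
    CUE_TIMES,
    EEG_CHANNELS_FULL,
    EMG_CHANNELS,
    MOTOR_CHANNELS,
    TRIAL_DURATION,
    Session,
    Trial,
)


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic session.

    Defaults reproduce the recording protocol: 96 trials of 18 s at
    2048 Hz, onsets ~ N(7.04, 1.42^2) s post move cue truncated to [3, 11] s,
    alpha power dropping by 40% and beta by 20% from 1 s before the onset.
    """

    n_trials: int = 96
    fs: float = 2048.0
    n_eeg_channels: int = 21
    onset_mean: float = 7.04
    onset_sd: float = 1.42
    onset_bounds: tuple = (3.0, 11.0)
    erd_lead: float = 1.0
    erd_depth_alpha: float = 0.40
    erd_depth_beta: float = 0.20
    alpha_band: tuple = (8.0, 13.0)   # Hz, flat-ish narrowband noise
    beta_band: tuple = (14.0, 30.0)
    alpha_rms: float = 4.0            # uV, per motor channel at rest
    beta_rms: float = 2.5
    background_rms: float = 3.0       # uV, broadband 1/f per channel
    background_spectrum_exponent: float = 1.0
    spatial_corr: float = 0.3         # shared-component weight
    emg_rest_rms: float = 2.0         # uV
    emg_burst_gain: float = 10.0      # burst/rest RMS ratio
    emg_burst_duration: float = 2.0   # s of elevated EMG after onset
    #: seconds of recording context before cue 1 (the protocol records
    #: continuous blocks; this stands in for the preceding trial's rest
    #: phase so filters never see a data boundary inside the relax phase)
    pre_roll: float = 2.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_trials < 0:
            raise ConfigurationError("n_trials must be >= 0")
        if self.n_trials % 2 != 0:
            raise ConfigurationError(
                "n_trials must be even (equal left and right movements)")
        lo, hi = self.onset_bounds
        if not (0.0 < lo < hi < 12.0):
            raise ConfigurationError("onset_bounds must lie within (0, 12)")
        for name in ("erd_depth_alpha", "erd_depth_beta"):
            d = getattr(self, name)
            if not (0.0 <= d < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1)")
        top = max(self.alpha_band[1], self.beta_band[1])
        if self.fs <= 2 * top:
            raise ConfigurationError(
                "fs must exceed twice the highest generated frequency (fs)")
        if self.erd_lead <= 0:
            raise ConfigurationError("erd_lead must be positive")
        if self.emg_burst_gain < 1:
            raise ConfigurationError("emg_burst_gain must be >= 1")
        if self.pre_roll < 0:
            raise ConfigurationError("pre_roll must be >= 0")

    @property
    def alpha_center(self) -> float:
        return 0.5 * (self.alpha_band[0] + self.alpha_band[1])

    @property
    def beta_center(self) -> float:
        return 0.5 * (self.beta_band[0] + self.beta_band[1])


@dataclass
class GroundTruth:
    """Per-trial generative truth for parameter-recovery tests."""

    onsets: np.ndarray        # s post move cue
    arms: list = field(default_factory=list)
    erd_start: float = -1.0   # s relative to onset (= -erd_lead)


def erd_gain(t, cfg: GeneratorConfig, band: str):
    """Amplitude multiplier encoding the event-related power drop.

    1 for ``t <= -erd_lead``; linear amplitude ramp down to
    ``sqrt(1 - depth)`` at ``t = 0`` (a power gain of ``1 - depth``), then
    constant.  ``t`` is seconds relative to the movement onset; scalar or
    array.
    """
    try:
        depth = {"alpha": cfg.erd_depth_alpha, "beta": cfg.erd_depth_beta}[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}") from None
    g_end = np.sqrt(1.0 - depth)
    frac = np.clip((np.asarray(t, dtype=float) + cfg.erd_lead) / cfg.erd_lead,
                   0.0, 1.0)
    out = 1.0 + frac * (g_end - 1.0)
    return out if out.ndim else float(out)


def _oneoverf_noise(rng, n_channels, n_samples, fs, exponent, rms):
    """Gaussian noise with a 1/f^exponent power spectrum, unit-free RMS."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    x *= rms / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x


def _narrowband_noise(rng, n_channels, n_samples, fs, band, rms):
    """Band-limited Gaussian noise with flat passband and configured RMS."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal((n_channels, n_samples + int(fs))),
                       axis=1)[:, int(fs):]  # discard filter warm-up
    x *= rms / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x


def generate_emg(onset: float, trial_len: float, fs: float,
                 cfg: GeneratorConfig, rng, arm: str,
                 t0: float = 0.0) -> np.ndarray:
    """Four bipolar EMG channels (biceps/triceps x left/right), microvolts.

    All channels carry band-limited (>10 Hz) noise at the rest RMS; the
    moved arm's channels multiply their RMS by ``emg_burst_gain`` from the
    onset, reaching full amplitude within 30 ms, for ``emg_burst_duration``
    seconds.  ``onset`` is seconds after the move cue; ``t0`` the time of
    the first sample on the cue-referenced axis (negative for pre-roll).
    """
    if not (0.0 <= onset <= t0 + trial_len - CUE_TIMES[1]):
        raise ValueError(f"onset {onset} s outside trial")
    n = int(round(trial_len * fs))
    high = min(500.0, 0.45 * fs)
    sos = signal.butter(4, [20.0, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal((4, n + int(fs))),
                       axis=1)[:, int(fs):]
    x *= cfg.emg_rest_rms / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))

    t = t0 + np.arange(n) / fs
    onset_abs = CUE_TIMES[1] + onset
    rise = 0.03  # s to full burst amplitude
    envelope = np.ones(n)
    burst = (t >= onset_abs) & (t < onset_abs + cfg.emg_burst_duration)
    ramp_frac = np.clip((t - onset_abs) / rise, 0.0, 1.0)
    envelope += burst * ramp_frac * (cfg.emg_burst_gain - 1.0)
    moved = [0, 1] if arm == "left" else [2, 3]
    x[moved] *= envelope
    return x


def _sample_onsets(rng, cfg: GeneratorConfig, n: int) -> np.ndarray:
    """Truncated-normal onsets by rejection sampling."""
    lo, hi = cfg.onset_bounds
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(cfg.onset_mean, cfg.onset_sd, size=max(2 * (n - filled), 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def truncated_onset_mean(cfg: GeneratorConfig) -> float:
    """Analytic mean of the truncated onset distribution (scipy oracle)."""
    lo, hi = cfg.onset_bounds
    a = (lo - cfg.onset_mean) / cfg.onset_sd
    b = (hi - cfg.onset_mean) / cfg.onset_sd
    return float(stats.truncnorm.mean(a, b, loc=cfg.onset_mean, scale=cfg.onset_sd))


def generate_session(cfg: GeneratorConfig | None = None,
                     seed: int | None = None):
    """Generate one synthetic session plus its ground truth.

    Returns ``(session, truth)``.  Identical configuration and seed give
    bit-identical output.  ``seed`` overrides ``cfg.seed`` when given.
    """
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)

    t0 = -cfg.pre_roll
    trial_len = TRIAL_DURATION + cfg.pre_roll
    n = int(round(trial_len * cfg.fs))
    onsets = _sample_onsets(rng, cfg, cfg.n_trials)
    arms = ["left"] * (cfg.n_trials // 2) + ["right"] * (cfg.n_trials // 2)
    rng.shuffle(arms)

    eeg_labels = list(EEG_CHANNELS_FULL[:cfg.n_eeg_channels])
    motor_rows = [eeg_labels.index(ch) for ch in MOTOR_CHANNELS if ch in eeg_labels]
    t = t0 + np.arange(n) / cfg.fs

    trials = []
    for i in range(cfg.n_trials):
        onset_abs = CUE_TIMES[1] + onsets[i]
        shared = _oneoverf_noise(rng, 1, n, cfg.fs,
                                 cfg.background_spectrum_exponent, cfg.background_rms)
        own = _oneoverf_noise(rng, cfg.n_eeg_channels, n, cfg.fs,
                              cfg.background_spectrum_exponent, cfg.background_rms)
        c = cfg.spatial_corr
        eeg = np.sqrt(1 - c) * own + np.sqrt(c) * shared

        alpha = _narrowband_noise(rng, len(motor_rows), n, cfg.fs,
                                  cfg.alpha_band, cfg.alpha_rms)
        beta = _narrowband_noise(rng, len(motor_rows), n, cfg.fs,
                                 cfg.beta_band, cfg.beta_rms)
        g_a = erd_gain(t - onset_abs, cfg, "alpha")
        g_b = erd_gain(t - onset_abs, cfg, "beta")
        eeg[motor_rows] += alpha * g_a + beta * g_b

        emg = generate_emg(onsets[i], trial_len, cfg.fs, cfg, rng, arms[i],
                           t0=t0)
        trials.append(Trial(
            eeg=eeg.astype(np.float32), emg=emg.astype(np.float32),
            fs=cfg.fs, arm=arms[i], t0=t0,
        ))

    session = Session(
        subject="synthetic", trials=trials, fs=cfg.fs,
        eeg_labels=eeg_labels, emg_labels=list(EMG_CHANNELS),
    )
    session.log_stage("generate_session", n_trials=cfg.n_trials, seed=seed,
                      erd_depth_alpha=cfg.erd_depth_alpha,
                      erd_depth_beta=cfg.erd_depth_beta,
                      erd_lead=cfg.erd_lead)
    truth = GroundTruth(onsets=onsets, arms=list(arms), erd_start=-cfg.erd_lead)
    return session, truth
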