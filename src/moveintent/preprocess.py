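"""EEG preprocessing: channel selection, resampling, band-pass, CAR.

The stage order is fixed — select the nine motor-cortex channels, resample
to 256 Hz, band-pass 0.1–100 Hz with a zero-phase 4th-order Butterworth,
then common average reference over the retained channels — and each stage
appends a provenance record.  EMG is neither resampled nor re-referenced:
it has already been consumed by onset detection, and `preprocess_session`
drops it.

The final stage trims each realigned trial to the analysis span
[t_ini, 1] s around the movement onset.  Trimming comes last deliberately:
the 0.1 Hz high-pass edge has a ~1.6 s time constant, and filtering an
already-trimmed trial puts its boundary transient inside the relax phase
(at t_ini) and just past the execution window (at +1 s) — measurably
biasing windows near the span edges.  With the trim last, the filters see
real recording context on both sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .session import MOTOR_CHANNELS, Session, Trial


@dataclass
class PreprocessConfig:
    keep_channels: list = field(default_factory=lambda: list(MOTOR_CHANNELS))
    target_fs: float = 256.0
    band: tuple = (0.1, 100.0)
    filter_order: int = 4

    def validate(self) -> None:
        lo, hi = self.band
        if not (0.0 < lo < hi < self.target_fs / 2):
            raise ValueError("band must lie inside (0, target_fs/2)")


def select_channels(trial: Trial, labels: list, keep: list) -> Trial:
    """Reduce the EEG to ``keep`` (in that order); errors name missing labels."""
    missing = [ch for ch in keep if ch not in labels]
    if missing:
        raise ValueError(f"channel(s) not in session: {', '.join(missing)}")
    rows = [labels.index(ch) for ch in keep]
    return Trial(eeg=trial.eeg[rows], emg=trial.emg, fs=trial.fs, t0=trial.t0,
                 arm=trial.arm, time_ref=trial.time_ref, onset=trial.onset,
                 cue_times=trial.cue_times)


def resample_trial(trial: Trial, target_fs: float) -> Trial:
    """Anti-aliased polyphase resampling of the EEG; times are unchanged
    because they are stored in seconds."""
    if target_fs > trial.fs:
        raise ValueError("upsampling not supported (target_fs > fs)")
    if target_fs == trial.fs:
        warnings.warn("target_fs equals the current rate; pass-through",
                      stacklevel=2)
        return trial
    frac = Fraction(target_fs / trial.fs).limit_denominator(10000)
    eeg = signal.resample_poly(np.asarray(trial.eeg, dtype=float),
                               frac.numerator, frac.denominator, axis=1)
    return Trial(eeg=eeg, emg=None, fs=target_fs, t0=trial.t0, arm=trial.arm,
                 time_ref=trial.time_ref, onset=trial.onset,
                 cue_times=trial.cue_times)


def bandpass_trial(trial: Trial, band=(0.1, 100.0), order: int = 4) -> Trial:
    """Zero-phase (forward–backward) Butterworth band-pass of the EEG."""
    if band[1] >= trial.fs / 2:
        raise ValueError("band edge at or above Nyquist")
    sos = signal.butter(order, band, btype="bandpass", fs=trial.fs, output="sos")
    eeg = signal.sosfiltfilt(sos, np.asarray(trial.eeg, dtype=float), axis=1)
    return Trial(eeg=eeg, emg=trial.emg, fs=trial.fs, t0=trial.t0,
                 arm=trial.arm, time_ref=trial.time_ref, onset=trial.onset,
                 cue_times=trial.cue_times)


def apply_car(trial: Trial) -> Trial:
    """Common average reference: subtract the across-channel mean per sample."""
    if trial.eeg.shape[0] < 2:
        raise ValueError("CAR requires at least two channels")
    eeg = trial.eeg - trial.eeg.mean(axis=0, keepdims=True)
    return Trial(eeg=eeg, emg=trial.emg, fs=trial.fs, t0=trial.t0,
                 arm=trial.arm, time_ref=trial.time_ref, onset=trial.onset,
                 cue_times=trial.cue_times)


def trim_to_analysis_span(trial: Trial, post_onset: float = 1.0) -> Trial:
    """Cut a realigned trial to [t_ini, post_onset] around the onset."""
    if trial.time_ref != "onset":
        raise ValueError("trimming requires an onset-referenced trial")
    a = int(round((trial.t_ini - trial.t0) * trial.fs))
    b = int(round((post_onset - trial.t0) * trial.fs))
    if a < 0 or b > trial.n_samples:
        raise ValueError("analysis span outside trial data")
    return Trial(eeg=trial.eeg[:, a:b], emg=None, fs=trial.fs,
                 t0=trial.t_ini, arm=trial.arm, time_ref="onset",
                 onset=trial.onset, cue_times=trial.cue_times)


def preprocess_session(session: Session,
                       cfg: PreprocessConfig | None = None) -> Session:
    """select -> resample -> band-pass -> CAR -> trim to [t_ini, 1]."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    realigned = session.trials and session.trials[0].time_ref == "onset"
    trials = []
    for trial in session.trials:
        tr = select_channels(trial, session.eeg_labels, cfg.keep_channels)
        tr = resample_trial(tr, cfg.target_fs)
        tr = bandpass_trial(tr, cfg.band, cfg.filter_order)
        tr = apply_car(tr)
        if realigned:
            tr = trim_to_analysis_span(tr)
        trials.append(tr)
    out = Session(
        subject=session.subject, trials=trials, fs=cfg.target_fs,
        eeg_labels=list(cfg.keep_channels), emg_labels=[],
        provenance=[dict(r) for r in session.provenance],
    )
    out.log_stage("preprocess",
                  order=("select,resample,bandpass,car,trim" if realigned
                         else "select,resample,bandpass,car"),
                  keep_channels=cfg.keep_channels, target_fs=cfg.target_fs,
                  band=list(cfg.band), filter_order=cfg.filter_order,
                  n_trials=len(trials))
    return out
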