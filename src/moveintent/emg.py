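"""EMG-based movement onset labelling, trial screening, and realignment.

Self-paced movements have no stimulus-locked onset, so the time of movement
initiation is estimated per trial from the surface EMG of the moved arm:
high-pass filter (6th-order Butterworth, 10 Hz, zero-phase), Hilbert
envelope, 200 ms moving-average smoothing, z-score over the trial, and the
first value greater than zero sustained for at least 100 ms after the move
cue.  Trials whose onset falls before 3 s or after 11 s post move cue are
screened out; the survivors are re-referenced so that t = 0 is the movement
onset.  The trim to the analysis span [t_ini, 1] s (t_ini = -(onset + 3),
the relax-cue time) is deferred to the end of preprocessing so that the
filters run with real recording context on both sides of the span.

The sustain guard is an addition to the bare first-positive-value rule: a
whole-trial z-scored envelope inevitably has spurious zero crossings during
rest, and requiring 100 ms of positivity preserves the rule on clean data
while stabilizing it on noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session import CUE_TIMES, Session, Trial

#: cue-referenced span used for onset estimation (cue1 .. cue3)
_ANALYSIS_SPAN = (CUE_TIMES[0], CUE_TIMES[2])


@dataclass
class OnsetConfig:
    early_bound: float = 3.0     # s post move cue
    late_bound: float = 11.0
    sustain: float = 0.1         # s the envelope must stay positive
    smooth: float = 0.2          # moving-average window, s
    highpass: float = 10.0       # Hz
    filter_order: int = 6
    #: realigned trials keep [t_ini, post_onset] s around the onset
    post_onset: float = 1.0
    #: onsets are snapped to this grid so later resampling lands on samples
    snap_hz: float = 256.0


@dataclass
class OnsetResult:
    """Estimated onset (s post move cue) and the screening outcome."""

    onset: float | None
    accepted: bool
    reason: str  # 'early' | 'late' | 'none'


def emg_envelope(x: np.ndarray, fs: float, cfg: OnsetConfig | None = None,
                 zscore: bool = True) -> np.ndarray:
    """Smoothed Hilbert envelope of one EMG channel.

    High-pass -> analytic-signal magnitude -> centered moving average ->
    z-score over the whole input (skipped when ``zscore`` is False, which
    exposes the envelope in microvolts).  Output length equals input length.
    """
    cfg = cfg or OnsetConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("emg_envelope expects a 1-D signal")
    if x.size < fs:
        raise ValueError("signal shorter than filter warm-up (1 s)")
    win = int(round(cfg.smooth * fs))
    if x.size < win:
        raise ValueError("signal shorter than the smoothing window")
    sos = signal.butter(cfg.filter_order, cfg.highpass, btype="highpass",
                        fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    env = np.abs(signal.hilbert(y))
    kernel = np.ones(win) / win
    # reflect-pad so the centered average is defined at the edges
    padded = np.pad(env, (win // 2, win - win // 2 - 1), mode="reflect")
    env = np.convolve(padded, kernel, mode="valid")
    if zscore:
        sd = env.std()
        if sd == 0:
            raise ValueError("flat envelope: cannot z-score")
        env = (env - env.mean()) / sd
    return env


def _first_sustained_positive(env, fs, start_idx, sustain):
    """Index of the first sample >= start_idx beginning a positive run of
    at least ``sustain`` seconds, or None."""
    need = max(int(round(sustain * fs)), 1)
    pos = env > 0
    pos[:start_idx] = False
    if pos.size < need:
        return None
    c = np.concatenate(([0], np.cumsum(pos)))
    full = np.flatnonzero(c[need:] - c[:-need] == need)  # all-positive windows
    return int(full[0]) if full.size else None


def detect_onset(trial: Trial, cfg: OnsetConfig | None = None) -> OnsetResult:
    """Estimate the movement onset of one cue-referenced trial.

    The detection channel is the moved arm's biceps; when the triceps is
    also present the earlier sustained crossing of the two wins.
    """
    cfg = cfg or OnsetConfig()
    if trial.time_ref != "cue":
        raise ValueError("detect_onset expects a cue-referenced trial")
    if trial.emg is None:
        raise ValueError("trial has no EMG")
    rows = [0, 1] if trial.arm == "left" else [2, 3]
    # onset estimation runs on the [cue1, cue3] span only
    a = int(round((_ANALYSIS_SPAN[0] - trial.t0) * trial.fs))
    b = min(int(round((_ANALYSIS_SPAN[1] - trial.t0) * trial.fs)),
            trial.n_samples)
    start_idx = int(round((CUE_TIMES[1] - _ANALYSIS_SPAN[0]) * trial.fs))

    candidates = []
    for row in rows:
        try:
            env = emg_envelope(trial.emg[row, a:b], trial.fs, cfg)
        except ValueError:
            continue  # flat channel: no envelope, no crossing
        idx = _first_sustained_positive(env, trial.fs, start_idx, cfg.sustain)
        if idx is not None:
            candidates.append(idx)
    if not candidates:
        return OnsetResult(onset=None, accepted=False, reason="late")
    onset = min(candidates) / trial.fs + _ANALYSIS_SPAN[0] - CUE_TIMES[1]
    onset = round(onset * cfg.snap_hz) / cfg.snap_hz
    if onset < cfg.early_bound:
        return OnsetResult(onset=onset, accepted=False, reason="early")
    if onset > cfg.late_bound:
        return OnsetResult(onset=onset, accepted=False, reason="late")
    return OnsetResult(onset=onset, accepted=True, reason="none")


def realign_trial(trial: Trial, onset: float, cfg: OnsetConfig) -> Trial:
    """Re-reference a trial's time axis so t = 0 is the movement onset.

    All samples are kept: the final trim to the analysis span
    [t_ini, post_onset] happens at the end of preprocessing, after the
    filters have run with real context on both sides of the span (trimming
    first would put a filter boundary right at the span edges).
    """
    onset_abs = CUE_TIMES[1] + onset  # relative to cue 1
    return Trial(
        eeg=trial.eeg,
        emg=trial.emg,
        fs=trial.fs, t0=trial.t0 - onset_abs, arm=trial.arm,
        time_ref="onset", onset=onset, cue_times=trial.cue_times,
    )


def screen_and_realign(session: Session,
                       cfg: OnsetConfig | None = None) -> Session:
    """Label onsets, drop screened-out trials, re-reference survivors.

    Onset-referenced sessions pass through unchanged (idempotent).  An empty
    output session is a warning, not an error.
    """
    cfg = cfg or OnsetConfig()
    if session.trials and all(tr.time_ref == "onset" for tr in session.trials):
        return session
    kept, n_early, n_late = [], 0, 0
    for trial in session.trials:
        res = detect_onset(trial, cfg)
        if res.accepted:
            kept.append(realign_trial(trial, res.onset, cfg))
        elif res.reason == "early":
            n_early += 1
        else:
            n_late += 1
    out = Session(
        subject=session.subject, trials=kept, fs=session.fs,
        eeg_labels=list(session.eeg_labels), emg_labels=list(session.emg_labels),
        provenance=[dict(r) for r in session.provenance],
    )
    out.log_stage("screen_and_realign", n_in=session.n_trials, n_kept=len(kept),
                  n_rejected_early=n_early, n_rejected_late=n_late,
                  early_bound=cfg.early_bound, late_bound=cfg.late_bound)
    if session.n_trials and not kept:
        import warnings
        warnings.warn("all trials rejected during screening", stacklevel=2)
    return out


def onset_table(session: Session, cfg: OnsetConfig | None = None):
    """Per-trial onset estimates plus mean/std/min/max summary (DataFrame)."""
    import pandas as pd

    cfg = cfg or OnsetConfig()
    rows = []
    for i, trial in enumerate(session.trials):
        if trial.time_ref == "onset":
            rows.append({"trial": i, "onset": trial.onset, "accepted": True,
                         "reason": "none"})
        else:
            res = detect_onset(trial, cfg)
            rows.append({"trial": i, "onset": res.onset,
                         "accepted": res.accepted, "reason": res.reason})
    df = pd.DataFrame(rows)
    acc = df[df.accepted]["onset"]
    df.attrs["summary"] = {"mean": acc.mean(), "std": acc.std(),
                           "min": acc.min(), "max": acc.max()}
    return df
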