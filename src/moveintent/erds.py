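"""Event-related desynchronization/synchronization maps with bootstrap
significance.

For each trial and channel a Morlet-wavelet time-frequency representation
TFR(t, f) is computed on the 1 Hz grid [2, 40] Hz (7 fixed cycles).  The
percent power change relative to the per-frequency baseline mean over
[-6, -3) s is

    ERDS(t, f) = 100 * (TFR(t, f) - TFR_baseline(f)) / TFR_baseline(f),

negative values being desynchronization (power loss).  Significance of each
(t, f) cell is assessed by a percentile bootstrap over trials at alpha =
0.05: the cell is significant when the empirical (alpha/2, 1 - alpha/2)
interval of the trial-resampled ERDS excludes zero.

Edge handling: cells whose wavelet support (taken as +-5 sigma_t, i.e. the
full length mne uses) extends past the trial edges are excluded from
baseline statistics and masked non-significant.  At 2-3 Hz this can leave
no valid baseline sample, in which case the whole frequency row is NaN and
non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import Session

DEFAULT_FREQS = np.arange(2.0, 41.0)   # Hz, 1 Hz resolution
N_CYCLES = 7
BASELINE = (-6.0, -3.0)
ANALYSIS_SPAN = (-6.0, 1.0)
BANDS = {"alpha": (8.0, 13.0), "beta": (14.0, 30.0)}


def trim_common(session: Session, span=ANALYSIS_SPAN) -> Session:
    """Trim all onset-referenced trials to a common span (default [-6, 1] s,
    half-open at the right in samples).  Trials too short are dropped."""
    lo, hi = span
    n_span = int(round((hi - lo) * session.fs))
    kept, dropped = [], 0
    for trial in session.trials:
        if trial.time_ref != "onset":
            raise ValueError("trim_common requires onset-referenced trials")
        if trial.t0 > lo + 1e-9 or trial.t0 + trial.duration < hi - 1e-9:
            dropped += 1
            continue
        a = int(round((lo - trial.t0) * trial.fs))
        kept.append(trial.copy(eeg=trial.eeg[:, a:a + n_span],
                               emg=(trial.emg[:, a:a + n_span]
                                    if trial.emg is not None else None),
                               t0=lo))
    out = Session(subject=session.subject, trials=kept, fs=session.fs,
                  eeg_labels=list(session.eeg_labels),
                  emg_labels=list(session.emg_labels),
                  provenance=[dict(r) for r in session.provenance])
    out.log_stage("trim_common", span=list(span), n_in=session.n_trials,
                  n_dropped=dropped)
    return out


@dataclass
class TFRStack:
    """Per-trial wavelet power for all channels of one session.

    ``power`` has shape (n_trials, n_channels, n_freqs, n_times) in uV^2;
    ``valid`` flags (f, t) cells with complete wavelet support.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    channels: list


def compute_tfr(session: Session, freqs=None, n_cycles: int = N_CYCLES,
                decim: int = 4) -> TFRStack:
    """Morlet time-frequency power for every trial and channel.

    Trials must share a common span (see :func:`trim_common`).  ``decim``
    subsamples the time axis of the power (power varies slowly compared to
    the raw signal; 4 gives a 64 Hz grid at fs = 256).
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.max() > session.fs / 2:
        raise ValueError("requested frequency above Nyquist")
    if not session.trials:
        raise ValueError("empty session")
    t0 = session.trials[0].t0
    n = session.trials[0].n_samples
    data = np.stack([np.asarray(tr.eeg, dtype=float) for tr in session.trials])
    power = tfr_array_morlet(data, session.fs, freqs, n_cycles=n_cycles,
                             output="power", decim=decim, verbose="error")
    times = t0 + np.arange(n)[::decim] / session.fs
    # +-5 sigma_t support, the full wavelet length used by mne
    half_support = 5.0 * n_cycles / (2.0 * np.pi * freqs)
    t_lo, t_hi = t0, t0 + (n - 1) / session.fs
    valid = ((times[None, :] >= t_lo + half_support[:, None])
             & (times[None, :] <= t_hi - half_support[:, None]))
    return TFRStack(power=power.astype(np.float32), freqs=freqs, times=times,
                    valid=valid, channels=list(session.eeg_labels))


@dataclass
class ERDSMap:
    """Percent power change per (frequency, time) with significance mask."""

    erds: np.ndarray            # (n_freqs, n_times), % change; NaN where undefined
    freqs: np.ndarray
    times: np.ndarray
    baseline: tuple
    channel: str
    mask: np.ndarray | None = None
    alpha: float | None = None


def _baseline_cols(times, baseline):
    return (times >= baseline[0]) & (times < baseline[1])


def erds_map(tfrs: TFRStack, channel: int | str,
             baseline=BASELINE) -> ERDSMap:
    """Trial-averaged ERDS map of one channel (no significance mask)."""
    ch = tfrs.channels.index(channel) if isinstance(channel, str) else channel
    P = tfrs.power[:, ch].mean(axis=0)                    # (F, T)
    bcols = _baseline_cols(tfrs.times, baseline)
    erds = np.full_like(P, np.nan)
    for i in range(P.shape[0]):
        cols = bcols & tfrs.valid[i]
        if not cols.any():
            continue
        pb = P[i, cols].mean()
        if pb == 0:
            raise ValueError(f"zero baseline power at {tfrs.freqs[i]:g} Hz")
        erds[i] = 100.0 * (P[i] - pb) / pb
    erds[~tfrs.valid] = np.nan
    name = tfrs.channels[ch] if tfrs.channels else str(ch)
    return ERDSMap(erds=erds, freqs=tfrs.freqs, times=tfrs.times,
                   baseline=tuple(baseline), channel=name)


def bootstrap_mask(tfrs: TFRStack, channel: int | str, baseline=BASELINE,
                   alpha: float = 0.05, B: int = 1000,
                   seed: int | None = None) -> np.ndarray:
    """Percentile-bootstrap significance mask for one channel's ERDS map.

    Trials are the resampling unit: each of the B resamples redraws trials
    with replacement, recomputes the trial-averaged ERDS, and a cell is
    significant when the empirical (alpha/2, 1 - alpha/2) interval excludes
    zero.  Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for stable percentiles")
    ch = tfrs.channels.index(channel) if isinstance(channel, str) else channel
    X = tfrs.power[:, ch]                                  # (n_trials, F, T)
    n = X.shape[0]
    if n < 20:
        raise ValueError("bootstrap requires at least 20 trials")
    rng = np.random.default_rng(seed)
    bcols = _baseline_cols(tfrs.times, baseline)
    F, T = X.shape[1], X.shape[2]

    # resample means via a (B, n) weight matrix of draw counts / n
    idx = rng.integers(0, n, size=(B, n))
    W = np.zeros((B, n), dtype=np.float32)
    for bi in range(B):
        np.add.at(W[bi], idx[bi], 1.0)
    W /= n

    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    mask = np.zeros((F, T), dtype=bool)
    Xf = X.reshape(n, F * T)
    # chunk over frequencies to bound the (B, F*T) intermediate
    chunk = max(1, int(2e7 // (B * T)))
    for f0 in range(0, F, chunk):
        f1 = min(f0 + chunk, F)
        cols = slice(f0 * T, f1 * T)
        M = W @ Xf[:, cols]                                # (B, (f1-f0)*T)
        M = M.reshape(B, f1 - f0, T)
        for i, fi in enumerate(range(f0, f1)):
            vcols = bcols & tfrs.valid[fi]
            if not vcols.any():
                continue
            pb = M[:, i, vcols].mean(axis=1)               # (B,)
            boot = 100.0 * (M[:, i, :] - pb[:, None]) / pb[:, None]
            lo = np.percentile(boot, lo_q, axis=0)
            hi = np.percentile(boot, hi_q, axis=0)
            mask[fi] = (lo > 0) | (hi < 0)
    mask &= tfrs.valid
    return mask


def significant_erds_map(tfrs: TFRStack, channel, baseline=BASELINE,
                         alpha: float = 0.05, B: int = 1000,
                         seed: int | None = None) -> ERDSMap:
    """ERDS map plus bootstrap significance mask."""
    m = erds_map(tfrs, channel, baseline)
    m.mask = bootstrap_mask(tfrs, channel, baseline, alpha, B, seed)
    m.alpha = alpha
    return m


def band_average(map_: ERDSMap, band, window) -> float:
    """Unmasked mean ERDS over a (band x time-window) region (valid cells)."""
    frows = (map_.freqs >= band[0]) & (map_.freqs <= band[1])
    tcols = (map_.times >= window[0]) & (map_.times < window[1])
    region = map_.erds[np.ix_(frows, tcols)]
    return float(np.nanmean(region))


def band_window_table(maps, bands=None, windows=None):
    """Significant-ERDS summary per channel x band x 1-s window (DataFrame).

    Entries are the mean of ERDS over each region with non-significant cells
    contributing zero, so fully quiet windows show exact 0.00.  A final
    'Avg' row averages across channels.
    """
    import pandas as pd

    bands = bands or BANDS
    if windows is None:
        windows = [(s, s + 1.0) for s in np.arange(ANALYSIS_SPAN[0],
                                                   ANALYSIS_SPAN[1])]
    rows = []
    for m in maps:
        if m.mask is None:
            raise ValueError("band_window_table requires masked maps")
        for bname, band in bands.items():
            frows = (m.freqs >= band[0]) & (m.freqs <= band[1])
            entry = {"channel": m.channel, "band": bname}
            for win in windows:
                tcols = (m.times >= win[0]) & (m.times < win[1])
                region = np.ix_(frows, tcols)
                vals = np.where(m.mask[region], m.erds[region], 0.0)
                vals = np.where(np.isnan(vals), 0.0, vals)
                entry[f"[{win[0]:g},{win[1]:g})"] = float(vals.mean())
            rows.append(entry)
    df = pd.DataFrame(rows)
    avg = df.groupby("band", sort=False).mean(numeric_only=True).reset_index()
    avg.insert(0, "channel", "Avg")
    return pd.concat([df, avg], ignore_index=True)
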