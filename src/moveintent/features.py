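"""Causal autoregressive spectral-power features.

For a window of EEG ending at time ``t`` (length ``T``, so only samples in
``[t - T, t)`` enter — the features are causal), each electrode's segment is
demeaned, an AR(16) model is fitted with Burg's method, and the parametric
power spectral density is evaluated on the 1 Hz grid covering the
motor-related alpha [8, 14] Hz and beta [14, 25] Hz bands.  The shared
14 Hz point is counted once, so there are 18 power values per electrode and
the feature vector over the nine motor electrodes has D = 162 entries.

The Burg recursion is implemented as a batch over many segments at once
(one session's sliding-window grid needs ~1e5 fits); a single-segment call
is the batch of one.  The PSD convention is one-sided,
``P(f) = 2 sigma^2 / fs / |A(e^{2 pi i f / fs})|^2`` — only relative
consistency matters downstream because features are z-scored per dimension
before classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import MOTOR_CHANNELS, Trial

#: 1 Hz grid over alpha [8, 14] and beta [14, 25] Hz; 14 Hz counted once.
FEATURE_FREQS = np.arange(8, 26, dtype=float)
AR_ORDER = 16
ELECTRODE_ORDER = list(MOTOR_CHANNELS)
N_FEATURES = len(ELECTRODE_ORDER) * len(FEATURE_FREQS)  # 162


def burg_batch(segments: np.ndarray, order: int = AR_ORDER):
    """Fit AR models to many segments at once with Burg's method.

    Parameters
    ----------
    segments : ndarray, shape (m, n)
        m real-valued series of length n > order.  Each should be demeaned
        by the caller.
    order : int
        AR model order p.

    Returns
    -------
    a : ndarray, shape (m, p)
        Coefficients of the prediction-error polynomial
        ``A(z) = 1 + a_1 z^-1 + ... + a_p z^-p`` (note the sign: the AR
        recursion is ``x_t = -sum_k a_k x_{t-k} + e_t``).
    sigma2 : ndarray, shape (m,)
        Driving-noise variance (final prediction-error power).
    """
    X = np.atleast_2d(np.asarray(segments, dtype=float))
    m, n = X.shape
    if n <= order:
        raise ValueError(f"segment length {n} must exceed AR order {order}")
    f = X.copy()          # forward prediction errors
    b = X.copy()          # backward prediction errors
    a = np.zeros((m, order))
    sigma2 = np.mean(X ** 2, axis=1)
    if np.any(sigma2 == 0):
        raise ValueError("constant segment: zero variance, AR fit undefined")
    for k in range(1, order + 1):
        ef = f[:, 1:]        # forward errors, stage k
        eb = b[:, :-1]       # backward errors, stage k
        den = np.sum(ef ** 2, axis=1) + np.sum(eb ** 2, axis=1)
        if np.any(den == 0):
            raise ValueError("degenerate segment: prediction error vanished")
        refl = -2.0 * np.sum(ef * eb, axis=1) / den
        # Levinson update of the coefficient rows
        prev = a[:, :k - 1]
        a[:, :k - 1] = prev + refl[:, None] * prev[:, ::-1]
        a[:, k - 1] = refl
        f, b = ef + refl[:, None] * eb, eb + refl[:, None] * ef
        sigma2 = sigma2 * (1.0 - refl ** 2)
    return a, sigma2


def ar_psd(a: np.ndarray, sigma2: np.ndarray, freqs, fs: float) -> np.ndarray:
    """One-sided AR power spectral density at the requested frequencies.

    ``a`` has shape (m, p) in the :func:`burg_batch` convention; the result
    has shape (m, len(freqs)) and is strictly positive.
    """
    a = np.atleast_2d(a)
    freqs = np.asarray(freqs, dtype=float)
    p = a.shape[1]
    # A(f) = 1 + sum_k a_k exp(-2 pi i f k / fs), evaluated as a matrix product
    E = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)
    A = 1.0 + a @ E.T
    return 2.0 * np.atleast_1d(sigma2)[:, None] / fs / np.abs(A) ** 2


def burg_spectrum(segment: np.ndarray, order: int = AR_ORDER,
                  freqs=FEATURE_FREQS, fs: float = 256.0) -> np.ndarray:
    """AR(order) Burg power spectrum of one demeaned segment at ``freqs``."""
    seg = np.asarray(segment, dtype=float)
    seg = seg - seg.mean()
    a, s2 = burg_batch(seg[None, :], order)
    return ar_psd(a, s2, freqs, fs)[0]


def _window_slice(trial: Trial, t: float, T: float):
    """Half-open sample window [t - T, t): endpoint t maps to floor(t*fs)."""
    fs = trial.fs
    end = int(np.floor(t * fs + 1e-9)) - int(np.floor(trial.t0 * fs + 1e-9))
    n = int(round(T * fs))
    start = end - n
    if start < 0 or end > trial.n_samples:
        raise ValueError(
            f"window [{t - T:.3f}, {t:.3f}) s outside trial span "
            f"[{trial.t0:.3f}, {trial.t0 + trial.duration:.3f}] s")
    return start, end


def feature_vector(trial: Trial, t: float, T: float,
                   order: int = AR_ORDER, freqs=FEATURE_FREQS) -> np.ndarray:
    """Spectral-power feature vector for the causal window ending at ``t``.

    The trial must be preprocessed (nine motor channels).  Electrode blocks
    are concatenated in the configured order; with the default grid the
    result has 162 entries.
    """
    return feature_matrix(trial, [t], T, order, freqs)[0]


def feature_matrix(trial: Trial, ts, T: float,
                   order: int = AR_ORDER, freqs=FEATURE_FREQS) -> np.ndarray:
    """Feature vectors for many window endpoints of one trial, batched.

    Returns shape (len(ts), n_channels * len(freqs)).
    """
    slices = [_window_slice(trial, t, T) for t in ts]
    n_ch = trial.eeg.shape[0]
    segs = np.empty((len(slices) * n_ch, slices[0][1] - slices[0][0]))
    eeg = np.asarray(trial.eeg, dtype=float)
    for i, (a, b) in enumerate(slices):
        segs[i * n_ch:(i + 1) * n_ch] = eeg[:, a:b]
    segs -= segs.mean(axis=1, keepdims=True)
    coef, s2 = burg_batch(segs, order)
    psd = ar_psd(coef, s2, freqs, trial.fs)
    return psd.reshape(len(slices), n_ch * len(freqs))


def training_windows(trial: Trial, T: float):
    """Nonoverlapping labelled window endpoints in the two training phases.

    Relax phase [t_ini, t_ini + 3]: endpoints ``t_ini + 3 - k T`` while the
    window stays inside the phase.  Movement-intention phase [-3, 0]:
    endpoints ``-k T`` likewise.  Returns a list of ``(t, label)`` with
    label in {'relax', 'intention'}; both phases are 3 s long, so the counts
    are equal by construction.
    """
    if trial.time_ref != "onset":
        raise ValueError("training windows require an onset-referenced trial")
    t_ini = trial.t_ini
    eps = 1e-9
    out = []
    k = 0
    while True:
        t = t_ini + 3.0 - k * T
        if t - T < t_ini - eps:
            break
        out.append((t, "relax"))
        k += 1
    k = 0
    while True:
        t = -k * T
        if t - T < -3.0 - eps:
            break
        out.append((t, "intention"))
        k += 1
    return out


@dataclass
class FeatureScaling:
    """Per-feature z-scoring statistics, fitted on training data only."""

    mu: np.ndarray
    sigma: np.ndarray


def fit_scaling(X: np.ndarray) -> FeatureScaling:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=0)
    bad = np.flatnonzero(sigma == 0)
    if bad.size:
        raise ValueError(f"zero-variance feature(s) at index {bad.tolist()}")
    return FeatureScaling(mu=mu, sigma=sigma)


def apply_scaling(X: np.ndarray, scaling: FeatureScaling) -> np.ndarray:
    return (np.asarray(X, dtype=float) - scaling.mu) / scaling.sigma
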