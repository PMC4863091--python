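"""Relax-vs-intention classification and continuous detection metrics.

A soft-margin SVM with RBF kernel (C = 1, width sigma = 0.5) is trained on
z-scored spectral-power features from the relax phase ``[t_ini, t_ini + 3]`` and the
movement-intention phase ``[-3, 0]`` of the training trials, then applied to
test trials with sliding windows of length T in 0.1 s steps.  The procedure —
an 80/20 trial-level split, training, and continuous evaluation — is repeated
(30 times by default) and the distributions of the metrics are kept:

* CA / TPE / TNE: accuracy over the two phases' fixed windows (pooled /
  intention phase / relax phase);
* DA(t): fraction of test trials labelled "intention" at grid time t;
* DA_sig(t), CA_sig: empirical chance levels from the same procedure with
  training labels randomly permuted;
* tMI: earliest t < 0 from which DA(t) is sustainedly, significantly above
  DA_sig(t) (Wilcoxon rank-sum at alpha = 0.01 at every grid point up to 0);
* NT_D: fraction of test timelines with an unequivocal pre-movement
  detection (>= 3 consecutive "intention" outputs ending before t = 0).

tMI and NT_D are explicitly undefined (None) when no sustained significant
interval exists — the no-detectable-intention outcome.

Kernel width convention: by default the squared distance in the RBF kernel is
normalized per feature dimension, ``k(u, v) = exp(-||u - v||^2 / (2 sigma^2 D))``
(scikit-learn ``gamma = 1 / (2 sigma^2 D)``).  On D = 162 z-scored features
the unnormalized form ``gamma = 1 / (2 sigma^2)`` makes every kernel value
``exp(-~2D/2sigma^2) ~ 0`` — the Gram matrix degenerates to the identity and
the classifier outputs a constant — so the per-dimension form is the default;
set ``scale_gamma_by_dim=False`` for the unnormalized convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .features import (
    FeatureScaling,
    apply_scaling,
    feature_matrix,
    fit_scaling,
    training_windows,
)
from .session import Session


@dataclass
class DetectorConfig:
    C: float = 1.0
    sigma: float = 0.5          # RBF width; see gamma() for the convention
    T: float = 1.0              # feature window length, s
    step: float = 0.1           # sliding-window step, s
    train_fraction: float = 0.8
    n_repeats: int = 30
    alpha_test: float = 0.01
    ntd_run_length: int = 3     # consecutive windows for an unequivocal detection
    #: normalize the kernel's squared distance by the feature dimension
    scale_gamma_by_dim: bool = True
    seed: int | None = None

    def validate(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.C <= 0 or self.sigma <= 0:
            raise ValueError("C and sigma must be positive")

    def gamma(self, n_features: int) -> float:
        g = 1.0 / (2.0 * self.sigma ** 2)
        return g / n_features if self.scale_gamma_by_dim else g


def timeline_grid(t_ini: float, T: float, step: float = 0.1) -> np.ndarray:
    """Window-endpoint grid over [t_ini + T, 1] anchored at 1.0.

    Endpoints are ``1 - k step`` for k = 0, 1, ... while the causal window
    stays inside the trial; returned ascending.
    """
    k_max = int(np.floor((1.0 - (t_ini + T)) / step + 1e-9))
    return 1.0 - step * np.arange(k_max, -1, -1)


@dataclass
class TrialFeatures:
    """Precomputed features of one trial (training phases + sliding grid)."""

    train_t: np.ndarray
    train_X: np.ndarray
    train_y: np.ndarray         # 1 = intention, 0 = relax
    grid_times: np.ndarray
    grid_X: np.ndarray


@dataclass
class SessionFeatures:
    trials: list
    grid: np.ndarray            # common grid shared by all trials
    T: float


def extract_session_features(session: Session,
                             cfg: DetectorConfig) -> SessionFeatures:
    """Compute all feature vectors a detection run needs, once per session.

    Features are deterministic given the data, so repeated splits and
    permutation runs reuse them; only classifier training varies.
    """
    cfg.validate()
    out = []
    for trial in session.trials:
        wins = training_windows(trial, cfg.T)
        ts = [t for t, _ in wins]
        y = np.array([1 if lab == "intention" else 0 for _, lab in wins])
        Xtr = feature_matrix(trial, ts, cfg.T)
        grid = timeline_grid(trial.t_ini, cfg.T, cfg.step)
        Xg = feature_matrix(trial, grid, cfg.T)
        out.append(TrialFeatures(train_t=np.array(ts), train_X=Xtr,
                                 train_y=y, grid_times=grid, grid_X=Xg))
    common_t_ini = max(tr.t_ini for tr in session.trials)
    grid = timeline_grid(common_t_ini, cfg.T, cfg.step)
    return SessionFeatures(trials=out, grid=grid, T=cfg.T)


def train_detector(X: np.ndarray, y: np.ndarray,
                   cfg: DetectorConfig | None = None) -> SVC:
    """Fit the RBF-SVM on already-scaled features."""
    cfg = cfg or DetectorConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if min(np.sum(y == c) for c in np.unique(y)) < 2:
        raise ValueError("need at least two examples per class")
    clf = SVC(C=cfg.C, kernel="rbf", gamma=cfg.gamma(np.shape(X)[1]))
    clf.fit(X, y)
    return clf


@dataclass
class PredictionTimeline:
    """Per-trial sequence of relax/intention decisions on the sliding grid."""

    times: np.ndarray
    labels: np.ndarray          # 1 = intention


def predict_timeline(detector: SVC, scaling: FeatureScaling, trial,
                     cfg: DetectorConfig) -> PredictionTimeline:
    """Continuous classification of one (preprocessed, realigned) trial."""
    grid = timeline_grid(trial.t_ini, cfg.T, cfg.step)
    X = feature_matrix(trial, grid, cfg.T)
    labels = detector.predict(apply_scaling(X, scaling))
    return PredictionTimeline(times=grid, labels=np.asarray(labels))


@dataclass
class EvalResult:
    ca: float
    tpe: float
    tne: float
    da: np.ndarray              # fraction "intention" per common-grid time
    timelines: list             # PredictionTimeline per test trial


def _split(n: int, train_fraction: float, rng) -> tuple:
    n_test = max(1, int(round((1.0 - train_fraction) * n)))
    perm = rng.permutation(n)
    return perm[n_test:], perm[:n_test]


def evaluate_once(feats: SessionFeatures, cfg: DetectorConfig, rng,
                  permute_labels: bool = False) -> EvalResult:
    """One 80/20 split: train (optionally with permuted training labels),
    then classify the test trials' phase windows and sliding grids."""
    n = len(feats.trials)
    train_idx, test_idx = _split(n, cfg.train_fraction, rng)
    if test_idx.size == 0 or train_idx.size == 0:
        raise ValueError("empty train or test set")
    Xtr = np.vstack([feats.trials[i].train_X for i in train_idx])
    ytr = np.concatenate([feats.trials[i].train_y for i in train_idx])
    if permute_labels:
        ytr = rng.permutation(ytr)
    scaling = fit_scaling(Xtr)
    clf = train_detector(apply_scaling(Xtr, scaling), ytr, cfg)

    m = feats.grid.size
    n_int = n_int_hit = n_rel = n_rel_hit = 0
    da_counts = np.zeros(m)
    timelines = []
    for i in test_idx:
        tf = feats.trials[i]
        yhat = clf.predict(apply_scaling(tf.train_X, scaling))
        n_int += int(np.sum(tf.train_y == 1))
        n_rel += int(np.sum(tf.train_y == 0))
        n_int_hit += int(np.sum((tf.train_y == 1) & (yhat == 1)))
        n_rel_hit += int(np.sum((tf.train_y == 0) & (yhat == 0)))
        ghat = clf.predict(apply_scaling(tf.grid_X, scaling))
        timelines.append(PredictionTimeline(times=tf.grid_times, labels=ghat))
        da_counts += ghat[-m:]  # grids share the trailing [common, 1] span
    tpe = n_int_hit / n_int
    tne = n_rel_hit / n_rel
    ca = (n_int_hit + n_rel_hit) / (n_int + n_rel)
    return EvalResult(ca=ca, tpe=tpe, tne=tne, da=da_counts / test_idx.size,
                      timelines=timelines)


@dataclass
class DetectionSummary:
    """Distributions over repeats plus chance levels, metrics and tests."""

    grid: np.ndarray
    ca: np.ndarray
    tpe: np.ndarray
    tne: np.ndarray
    da: np.ndarray              # (n_repeats, n_grid)
    da_sig: np.ndarray | None = None
    ca_sig: float | None = None
    tmi: float | None = None
    ntd: float | None = None
    timelines: list = field(default_factory=list)
    p_ca: float | None = None
    ca_above_chance: bool | None = None
    p_da: np.ndarray | None = None
    config: DetectorConfig | None = None

    def to_dict(self) -> dict:
        return {
            "ca_mean": float(self.ca.mean()),
            "ca_sd": float(self.ca.std(ddof=1)) if self.ca.size > 1 else 0.0,
            "tpe_mean": float(self.tpe.mean()),
            "tne_mean": float(self.tne.mean()),
            "ca_sig": self.ca_sig,
            "p_ca": self.p_ca,
            "ca_above_chance": self.ca_above_chance,
            "tmi": self.tmi,
            "ntd": self.ntd,
        }


def repeated_evaluation(feats: SessionFeatures, cfg: DetectorConfig,
                        seed: int | None = None) -> DetectionSummary:
    """Repeat the split/train/evaluate procedure and keep the distributions."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if cfg.n_repeats == 1:
        warnings.warn("n_repeats=1: degenerate distributions, no tests run",
                      stacklevel=2)
    ca, tpe, tne, da, tls = [], [], [], [], []
    for _ in range(cfg.n_repeats):
        res = evaluate_once(feats, cfg, rng)
        ca.append(res.ca)
        tpe.append(res.tpe)
        tne.append(res.tne)
        da.append(res.da)
        tls.extend(res.timelines)
    return DetectionSummary(grid=feats.grid, ca=np.array(ca), tpe=np.array(tpe),
                            tne=np.array(tne), da=np.array(da), timelines=tls,
                            config=cfg)


def permutation_chance(feats: SessionFeatures, cfg: DetectorConfig,
                       seed: int | None = None):
    """Empirical chance levels: the same repeated procedure with training
    labels permuted.  Returns ``(da_sig, ca_sig)`` where ``da_sig`` is the
    (n_repeats, n_grid) chance detection-accuracy matrix and ``ca_sig`` the
    maximum of the mean chance accuracy over the two phases."""
    base = cfg.seed if seed is None else seed
    rng = np.random.default_rng(None if base is None else base + 1)
    da, tpe, tne = [], [], []
    for _ in range(cfg.n_repeats):
        res = evaluate_once(feats, cfg, rng, permute_labels=True)
        da.append(res.da)
        tpe.append(res.tpe)
        tne.append(res.tne)
    ca_sig = float(max(np.mean(tpe), np.mean(tne)))
    return np.array(da), ca_sig


def _run_ending_before_zero(timeline: PredictionTimeline, run_length: int) -> bool:
    lab = np.asarray(timeline.labels) == 1
    if lab.size < run_length:
        return False
    c = np.concatenate(([0], np.cumsum(lab)))
    full = c[run_length:] - c[:-run_length] == run_length
    ends = timeline.times[run_length - 1:]
    return bool(np.any(full & (ends < 0)))


def detection_metrics(summary: DetectionSummary,
                      cfg: DetectorConfig | None = None):
    """tMI and NT_D from completed true-label and chance-level runs.

    tMI is the earliest t* < 0 such that at every grid point in [t*, 0) the
    rank-sum test between DA(t) and DA_sig(t) rejects (two-sided, alpha_test)
    with mean DA above mean DA_sig.  NT_D is the fraction of test timelines
    containing >= ``ntd_run_length`` consecutive "intention" outputs ending
    before t = 0.  Both are None when no sustained significant interval
    exists (the no-detection outcome).
    """
    cfg = cfg or summary.config or DetectorConfig()
    if summary.da_sig is None:
        raise ValueError("run permutation_chance first")
    grid = summary.grid
    neg = np.flatnonzero(grid < -1e-9)
    reject = np.zeros(grid.size, dtype=bool)
    pvals = np.full(grid.size, np.nan)
    for j in range(grid.size):
        x, y = summary.da[:, j], summary.da_sig[:, j]
        stat = stats.ranksums(x, y)
        pvals[j] = stat.pvalue
        reject[j] = (stat.pvalue < cfg.alpha_test) and (x.mean() > y.mean())
    summary.p_da = pvals
    if neg.size == 0 or not reject[neg[-1]]:
        return None, None
    # walk back from the last pre-movement grid point through the rejections
    start = neg[-1]
    for j in neg[::-1]:
        if reject[j]:
            start = j
        else:
            break
    tmi = float(grid[start])
    run = max(int(cfg.ntd_run_length), 1)
    detected = [_run_ending_before_zero(tl, run) for tl in summary.timelines]
    ntd = float(np.mean(detected)) if detected else None
    return tmi, ntd


def significance_tests(summary: DetectionSummary,
                       cfg: DetectorConfig | None = None) -> dict:
    """Wilcoxon signed-rank of CA repeats against CA_sig, and the per-grid
    rank-sum decisions between DA(t) and DA_sig(t)."""
    cfg = cfg or summary.config or DetectorConfig()
    out = {}
    if summary.ca_sig is not None and summary.ca.size > 1:
        diffs = summary.ca - summary.ca_sig
        if np.allclose(diffs, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diffs).pvalue)
        out["p_ca"] = p
        out["ca_above_chance"] = bool(p < cfg.alpha_test
                                      and diffs.mean() > 0)
        summary.p_ca = out["p_ca"]
        summary.ca_above_chance = out["ca_above_chance"]
    if summary.p_da is not None:
        out["p_da"] = summary.p_da
        out["da_above_chance"] = (summary.p_da < cfg.alpha_test)
    return out


def detect_movement_intention(session: Session, cfg: DetectorConfig | None = None,
                              seed: int | None = None) -> DetectionSummary:
    """Full detection analysis of a preprocessed, realigned session."""
    cfg = cfg or DetectorConfig()
    feats = extract_session_features(session, cfg)
    summary = repeated_evaluation(feats, cfg, seed)
    summary.da_sig, summary.ca_sig = permutation_chance(feats, cfg, seed)
    summary.tmi, summary.ntd = detection_metrics(summary, cfg)
    significance_tests(summary, cfg)
    return summary
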