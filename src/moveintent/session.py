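"""Session and trial containers, on-disk formats, configuration and logging.

A recording session is a list of cue-locked trials: a 21-channel scalp EEG
matrix plus a 4-channel bipolar EMG matrix (biceps/triceps of both arms),
sampled at a common rate.  Two on-disk representations are supported:

* ``bundle`` — a directory with one JSON sidecar and per-trial raw binaries
  (32-bit little-endian float, C order).  Lossless round trip; the canonical
  interchange format of this package.
* ``edf`` — EDF+C, the lingua franca for clinical EEG.  16-bit, so the round
  trip is exact only up to the quantization step of the chosen physical
  range.  Only cue-referenced sessions with equal-length trials can be
  written (trials are concatenated into one continuous record with cue and
  arm annotations); onset-referenced sessions must use the bundle format.

All time quantities are seconds, float64.  Within a trial, sample index 0
corresponds to the trial's first retained sample, and windows are half-open
``[a, b)`` in samples.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger("moveintent")

# 10/10 montage used for recording: 21 scalp positions.
EEG_CHANNELS_FULL = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz", "C4",
    "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2", "A1", "A2",
]
# Nine electrodes on or surrounding the motor cortex, kept for analysis.
MOTOR_CHANNELS = ["F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4"]
EMG_CHANNELS = ["EMG_biceps_L", "EMG_triceps_L", "EMG_biceps_R", "EMG_triceps_R"]

# Cue-referenced protocol timing (s): relax cue at 0, move cue at 3,
# rest cue at 15; each trial lasts 18 s in total.
CUE_TIMES = (0.0, 3.0, 15.0)
TRIAL_DURATION = 18.0
TRIALS_PER_BLOCK = 24
BLOCKS_PER_SESSION = 4


class ParseError(ValueError):
    """Raised when a session file is malformed; names the file and field."""


@dataclass
class Trial:
    """One cue-locked (or onset-referenced) recording segment.

    Parameters
    ----------
    eeg : ndarray, shape (n_eeg_channels, n_samples)
        EEG in microvolts.
    emg : ndarray or None, shape (4, n_samples)
        Bipolar EMG in microvolts; ``None`` once the EMG has been consumed
        by onset detection and dropped during preprocessing.
    fs : float
        Sampling rate in Hz, shared by EEG and EMG.
    t0 : float
        Time of the first sample on the trial's reference axis.  0.0 for
        cue-referenced trials; ``t_ini`` (negative) after realignment to the
        movement onset.
    arm : {'left', 'right'}
        Which arm the move cue instructed.
    time_ref : {'cue', 'onset'}
        Whether t = 0 is the relax-cue presentation or the EMG-based
        movement onset.
    onset : float or None
        EMG-based movement onset in seconds after the move cue; ``None``
        until detected.
    """

    eeg: np.ndarray
    emg: np.ndarray | None
    fs: float
    t0: float = 0.0
    arm: str = "left"
    time_ref: str = "cue"
    onset: float | None = None
    cue_times: tuple = CUE_TIMES

    def __post_init__(self):
        self.eeg = np.asarray(self.eeg)
        if self.eeg.ndim != 2:
            raise ValueError("eeg must be a (channels, samples) matrix")
        if self.emg is not None:
            self.emg = np.asarray(self.emg)
            if self.emg.ndim != 2 or self.emg.shape[1] != self.eeg.shape[1]:
                raise ValueError("emg must match eeg sample count")
        if self.arm not in ("left", "right"):
            raise ValueError(f"arm must be 'left' or 'right', got {self.arm!r}")
        if self.time_ref not in ("cue", "onset"):
            raise ValueError(f"time_ref must be 'cue' or 'onset', got {self.time_ref!r}")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time axis (s) on the trial's reference frame."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    @property
    def t_ini(self) -> float:
        """Relax-cue time in onset-referenced seconds: -(onset + 3).

        Defined after realignment; equals ``t0`` once the trial has been
        trimmed to the analysis span [t_ini, 1].
        """
        if self.time_ref != "onset":
            raise ValueError("t_ini is defined only for onset-referenced trials")
        if self.onset is None:
            raise ValueError("t_ini requires a detected onset")
        return -(self.onset + self.cue_times[1])

    def index_of(self, t: float) -> int:
        """Sample index of time ``t``: floor((t - t0) * fs), clipped to valid."""
        idx = int(np.floor((t - self.t0) * self.fs + 1e-9))
        if idx < 0 or idx > self.n_samples:
            raise ValueError(f"time {t} s outside trial span")
        return idx

    def copy(self, **changes) -> "Trial":
        out = replace(self, **changes)
        if "eeg" not in changes:
            out.eeg = self.eeg.copy()
        if "emg" not in changes and self.emg is not None:
            out.emg = self.emg.copy()
        return out


@dataclass
class Session:
    """An ordered collection of trials for one subject plus provenance."""

    subject: str
    trials: list
    fs: float
    eeg_labels: list = field(default_factory=lambda: list(EEG_CHANNELS_FULL))
    emg_labels: list = field(default_factory=lambda: list(EMG_CHANNELS))
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        for tr in self.trials:
            if tr.fs != self.fs:
                raise ValueError("all trials must share the session sampling rate")
            if tr.eeg.shape[0] != len(self.eeg_labels):
                raise ValueError("trial EEG channel count mismatch with labels")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def log_stage(self, stage: str, **params) -> None:
        """Append a structured processing record to the session provenance."""
        rec = {"stage": stage, **params}
        self.provenance.append(rec)
        logger.info("%s: %s", stage, params)

    def copy(self) -> "Session":
        return Session(
            subject=self.subject,
            trials=[tr.copy() for tr in self.trials],
            fs=self.fs,
            eeg_labels=list(self.eeg_labels),
            emg_labels=list(self.emg_labels),
            provenance=[dict(r) for r in self.provenance],
        )


# ---------------------------------------------------------------------------
# Bundle format: JSON sidecar + per-trial float32 little-endian binaries.
# ---------------------------------------------------------------------------

_SIDECAR = "session.json"


def _write_f32(path: Path, arr: np.ndarray) -> None:
    np.asarray(arr, dtype="<f4").tofile(path)


def _read_f32(path: Path, shape) -> np.ndarray:
    arr = np.fromfile(path, dtype="<f4")
    if arr.size != shape[0] * shape[1]:
        raise ParseError(f"{path}: expected {shape[0] * shape[1]} floats, got {arr.size}")
    return arr.reshape(shape)


def write_bundle(session: Session, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject": session.subject,
        "fs": session.fs,
        "eeg_labels": session.eeg_labels,
        "emg_labels": session.emg_labels,
        "provenance": session.provenance,
        "trials": [],
    }
    for i, tr in enumerate(session.trials):
        eeg_file = f"trial_{i:03d}_eeg.f32"
        _write_f32(path / eeg_file, tr.eeg)
        emg_file = None
        if tr.emg is not None:
            emg_file = f"trial_{i:03d}_emg.f32"
            _write_f32(path / emg_file, tr.emg)
        meta["trials"].append({
            "arm": tr.arm,
            "t0": tr.t0,
            "time_ref": tr.time_ref,
            "onset": tr.onset,
            "cue_times": list(tr.cue_times),
            "n_samples": tr.n_samples,
            "eeg_file": eeg_file,
            "emg_file": emg_file,
        })
    (path / _SIDECAR).write_text(json.dumps(meta, indent=1))


def read_bundle(path) -> Session:
    path = Path(path)
    sidecar = path / _SIDECAR
    if not sidecar.exists():
        raise ParseError(f"{sidecar}: sidecar not found")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{sidecar}: invalid JSON ({e})") from None
    for key in ("fs", "subject", "eeg_labels", "emg_labels", "trials"):
        if key not in meta:
            raise ParseError(f"{sidecar}: missing field \"{key}\"")
    trials = []
    for i, tmeta in enumerate(meta["trials"]):
        for key in ("n_samples", "eeg_file", "arm"):
            if key not in tmeta:
                raise ParseError(f"{sidecar}: trial {i} missing field \"{key}\"")
        shape_eeg = (len(meta["eeg_labels"]), tmeta["n_samples"])
        eeg = _read_f32(path / tmeta["eeg_file"], shape_eeg)
        emg = None
        if tmeta.get("emg_file"):
            emg = _read_f32(path / tmeta["emg_file"],
                            (len(meta["emg_labels"]), tmeta["n_samples"]))
        trials.append(Trial(
            eeg=eeg, emg=emg, fs=meta["fs"],
            t0=tmeta.get("t0", 0.0), arm=tmeta["arm"],
            time_ref=tmeta.get("time_ref", "cue"),
            onset=tmeta.get("onset"),
            cue_times=tuple(tmeta.get("cue_times", CUE_TIMES)),
        ))
    return Session(
        subject=meta["subject"], trials=trials, fs=meta["fs"],
        eeg_labels=list(meta["eeg_labels"]), emg_labels=list(meta["emg_labels"]),
        provenance=list(meta.get("provenance", [])),
    )


# ---------------------------------------------------------------------------
# EDF+C writer (16-bit).  Reading goes through mne.io.read_raw_edf, so the
# round trip crosses two independent implementations of the format.
# ---------------------------------------------------------------------------

def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")
    if len(b) > n:
        raise ValueError(f"EDF header field too long: {s!r}")
    return b.ljust(n)


def write_edf(session: Session, path) -> None:
    """Write a cue-referenced session as one continuous EDF+C file.

    Trials are concatenated back to back (they are contiguous 18 s epochs in
    the recording); per-trial cue times and the arm label are stored as
    EDF+ annotations.  Physical range per channel is the symmetric signal
    maximum, so the quantization step is ``2*max|x| / 65535``.
    """
    path = Path(path)
    if any(tr.time_ref != "cue" for tr in session.trials):
        raise ValueError("EDF export supports cue-referenced sessions only; "
                         "use the bundle format for realigned sessions")
    durs = {tr.n_samples for tr in session.trials}
    if len(durs) > 1:
        raise ValueError("EDF export requires equal-length trials")
    if any(tr.emg is None for tr in session.trials):
        raise ValueError("EDF export requires EMG channels present")

    n_samp = durs.pop() if durs else 0
    fs = session.fs
    if fs != int(fs):
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(fs)
    record_dur = 1.0  # s
    spr = fs  # samples per record per signal
    n_trials = session.n_trials
    trial_dur = n_samp / fs if n_trials else 0.0
    n_records = int(round(n_trials * trial_dur / record_dur))

    labels = list(session.eeg_labels) + list(session.emg_labels)
    if n_trials:
        data = np.concatenate(
            [np.vstack([tr.eeg, tr.emg]) for tr in session.trials], axis=1)
    else:
        data = np.zeros((len(labels), 0))

    # physical/digital scaling per channel; the range is re-parsed from its
    # 8-char header encoding so writer and reader use the identical value
    pmaxs = np.maximum(np.abs(data).max(axis=1, initial=0.0), 1.0)
    pmaxs = np.array([float(f"{v:.6g}"[:8]) for v in pmaxs])
    dmin, dmax = -32768, 32767

    # annotations: one timestamp TAL per record + trial events
    events = []
    for i, tr in enumerate(session.trials):
        off = i * trial_dur  # file time of the trial's first sample
        events.append((off + tr.cue_times[0] - tr.t0,
                       f"cue1_relax trial={i} arm={tr.arm} t0={tr.t0:g}"))
        events.append((off + tr.cue_times[1] - tr.t0, f"cue2_move trial={i}"))
        events.append((off + tr.cue_times[2] - tr.t0, f"cue3_rest trial={i}"))
    rec_events = [[] for _ in range(max(n_records, 1))]
    for t, text in events:
        rec = min(int(t // record_dur), n_records - 1)
        rec_events[rec].append((t, text))
    ann_bytes_per_rec = 16 + max(
        (sum(len(f"+{t:.7g}\x14{txt}\x14\x00") for t, txt in evs)
         for evs in rec_events), default=0)
    ann_spr = (ann_bytes_per_rec + 1) // 2  # 2 bytes per "sample"

    ns = len(labels) + 1
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad("Startdate 01-JAN-2000 X X X", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(256 * (ns + 1)), 8))
        f.write(_pad("EDF+C", 44))
        f.write(_pad(str(n_records), 8))
        f.write(_pad(f"{record_dur:g}", 8))
        f.write(_pad(str(ns), 4))
        sig_labels = labels + ["EDF Annotations"]
        for lab in sig_labels:
            f.write(_pad(lab, 16))
        for _ in sig_labels:
            f.write(_pad("", 80))  # transducer
        for lab in sig_labels:
            f.write(_pad("" if lab == "EDF Annotations" else "uV", 8))
        for i, lab in enumerate(sig_labels):
            f.write(_pad("-1" if lab == "EDF Annotations" else f"-{pmaxs[i]:.6g}"[:8], 8))
        for i, lab in enumerate(sig_labels):
            f.write(_pad("1" if lab == "EDF Annotations" else f"{pmaxs[i]:.6g}"[:8], 8))
        for _ in sig_labels:
            f.write(_pad(str(dmin), 8))
        for _ in sig_labels:
            f.write(_pad(str(dmax), 8))
        for _ in sig_labels:
            f.write(_pad("", 80))  # prefiltering
        for lab in sig_labels:
            f.write(_pad(str(ann_spr if lab == "EDF Annotations" else spr), 8))
        for _ in sig_labels:
            f.write(_pad("", 32))

        scale = (dmax - dmin) / (2 * pmaxs)  # digital units per physical unit
        for rec in range(n_records):
            sl = slice(rec * spr, (rec + 1) * spr)
            for ch in range(len(labels)):
                dig = np.round((data[ch, sl] + pmaxs[ch]) * scale[ch]) + dmin
                f.write(np.clip(dig, dmin, dmax).astype("<i2").tobytes())
            tal = f"+{rec * record_dur:g}\x14\x14\x00"
            for t, txt in rec_events[rec]:
                tal += f"+{t:.7g}\x14{txt}\x14\x00"
            b = tal.encode("ascii")
            if len(b) > 2 * ann_spr:
                raise ValueError("annotation record overflow")
            f.write(b.ljust(2 * ann_spr, b"\x00"))


def read_edf(path) -> Session:
    """Read a session written by :func:`write_edf` via mne's EDF reader."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = raw.info["sfreq"]
    labels = raw.ch_names
    eeg_labels = [l for l in labels if not l.startswith("EMG")]
    emg_labels = [l for l in labels if l.startswith("EMG")]
    data = raw.get_data() * 1e6  # mne loads EEG/EMG in volts

    trials_meta = {}
    for ann in raw.annotations:
        desc = ann["description"]
        parts = desc.split()
        if not parts or not parts[0].startswith("cue"):
            continue
        fields = dict(p.split("=") for p in parts[1:])
        i = int(fields["trial"])
        d = trials_meta.setdefault(i, {})
        cue_idx = int(parts[0][3]) - 1
        d.setdefault("cues", {})[cue_idx] = float(ann["onset"])
        if "arm" in fields:
            d["arm"] = fields["arm"]
        if "t0" in fields:
            d["t0"] = float(fields["t0"])
    if not trials_meta:
        return Session(subject=Path(path).stem, trials=[], fs=fs,
                       eeg_labels=eeg_labels, emg_labels=emg_labels)

    idx = sorted(trials_meta)
    # trial data starts t0 seconds before its first cue in file time
    starts = [trials_meta[i]["cues"][0] + trials_meta[i].get("t0", 0.0)
              for i in idx]
    starts.append(data.shape[1] / fs)
    trials = []
    eeg_rows = [labels.index(l) for l in eeg_labels]
    emg_rows = [labels.index(l) for l in emg_labels]
    for k, i in enumerate(idx):
        a = int(round(starts[k] * fs))
        b = int(round(starts[k + 1] * fs))
        cues = trials_meta[i]["cues"]
        rel = tuple(cues[j] - cues[0] for j in sorted(cues))
        trials.append(Trial(
            eeg=data[eeg_rows, a:b], emg=data[emg_rows, a:b], fs=fs,
            arm=trials_meta[i]["arm"], cue_times=rel,
            t0=trials_meta[i].get("t0", 0.0),
        ))
    return Session(subject=Path(path).stem, trials=trials, fs=fs,
                   eeg_labels=eeg_labels, emg_labels=emg_labels)


def write_session(session: Session, path, format: str = "bundle") -> None:
    """Write a session as a lossless bundle or a 16-bit EDF+C file."""
    if format == "bundle":
        write_bundle(session, path)
    elif format == "edf":
        write_edf(session, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_session(path, format: str = "bundle") -> Session:
    if format == "bundle":
        return read_bundle(path)
    elif format == "edf":
        return read_edf(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Flat key=value configuration files (overridable by CLI flags).
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Parse a flat ``key = value`` text file; values are type-guessed."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        for cast in (int, float):
            try:
                out[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            out[key] = {"true": True, "false": False}.get(val.lower(), val)
    return out
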