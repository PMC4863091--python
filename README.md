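# moveintent

Continuous detection of upper-limb **movement intention** from EEG in
self-paced reaching experiments — for BMI/BCI researchers who want the full
analysis chain (EMG-based onset labelling, ERD/ERS mapping with bootstrap
significance, causal spectral features, sliding-window classification with
permutation chance levels) as a tested, reusable Python library.

## The problem and the method

In a self-paced protocol a participant sees a "relax" cue (3 s), then a
"move" cue (12 s) during which they reach with the cued arm whenever they
wish, then a "rest" cue (3 s).  Because the movement is self-initiated, its
onset is latent: it is estimated per trial from the biceps/triceps EMG
(10 Hz high-pass → Hilbert envelope → smoothing → z-score → first sustained
positive value), trials with onsets outside [3, 11] s post-cue are dropped,
and the time axis is re-referenced so t = 0 is the movement onset.

Before and during movement, the sensorimotor α (8–13 Hz) and β (14–30 Hz)
rhythms desynchronize.  The package quantifies this as the percent power
change relative to a pre-movement baseline,

    ERDS(t, f) = 100 · (TFR(t, f) − TFR_b(f)) / TFR_b(f),

where TFR is a 7-cycle Morlet time–frequency map (2–40 Hz) and TFR_b the
per-frequency baseline mean over [−6, −3) s; cell-wise significance comes
from a trial-level percentile bootstrap (α = 0.05).

Detection treats the problem as continuous binary classification.  Causal
windows [t − T, t) of the nine motor-cortex channels are summarized by
Burg AR(16) spectral power at 18 frequencies (8–25 Hz), giving
D = 162 features, z-scored with training statistics.  An RBF-SVM (C = 1,
σ = 0.5) is trained on relax-phase vs intention-phase windows of 80% of the
trials and slid in 0.1 s steps over the held-out 20%; the split is
repeated 30 times.  Reported metrics: classification accuracy CA (with
TPE/TNE per phase), the time-resolved detection accuracy DA(t), the
permutation chance levels CA_sig and DA_sig(t), the movement-intention
onset tMI (earliest pre-movement time from which DA(t) stays significantly
above chance, Wilcoxon rank-sum α = 0.01), and NT_D (fraction of trials
with a sustained pre-movement detection).

No public recordings accompany this protocol, so the package ships a
synthetic EEG+EMG generator that reproduces its statistical structure
(truncated-normal onsets N(7.04, 1.42²) s in [3, 11], 1/f background,
band-limited α/β rhythms whose power ramps down by 40%/20% from 1 s before
each onset, EMG bursts) with ground truth for parameter-recovery testing.
See `docs/methods.md` for modelling details and limitations.

## Worked example

```sh
moveintent simulate --n-trials 96 --seed 7 --out raw/
moveintent onset --in raw/ --out aligned/
moveintent preprocess --in aligned/ --out clean/
moveintent detect --in clean/ --repeats 30 --seed 1 --out detect/
```

prints (numbers from this exact run):

```
wrote 96 trials to raw/
kept 96/96 trials; onset mean=6.79 std=1.21 min=3.41 max=9.82 s
preprocessed 96 trials at 256 Hz
CA=0.589±0.038 CA_sig=0.504 tMI=-0.3 s NT_D=1.00
```

Reading: the EMG onsets of all 96 trials fall inside the screening bounds
(sample mean 6.79 s after the move cue, close to the generator's truncated
N(7.04, 1.42²) law); relax vs intention classification reaches CA = 0.589
against an empirical chance level of 0.504 (significantly above it — the
signed-rank p-value is in `detect/summary.json`); DA(t) rises above chance
just before the onset (tMI = −0.3 s) and nearly every test trial contains a
sustained pre-movement detection.  `detect/` also holds the per-repeat
CA/TPE/TNE table and the DA(t) curve with chance bands as CSV.  The same
steps are available as library calls (`generate_session`,
`screen_and_realign`, `preprocess_session`, `detect_movement_intention`);
`moveintent erds` adds the ERDS maps and the per-channel band/window
summary table.

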