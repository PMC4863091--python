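# Methods

`moveintent` implements continuous detection of upper-limb movement
intention from multichannel EEG in self-paced reaching experiments, together
with the synthetic data needed to exercise and validate every stage.  This
note records the models, the tunable parameters that matter, the numerical
choices, and what the synthetic validation does and does not establish.

## Experimental structure assumed

A session is a sequence of cue-locked 18 s trials: a "relax" cue (3 s), a
"move" cue (12 s) during which the participant self-initiates a reaching
movement with the cued arm, and a "rest" cue (3 s).  EEG is recorded from 21
scalp electrodes (10/10 system) and bipolar EMG from biceps and triceps of
both arms, all at 2048 Hz.  Because movements are self-paced, the movement
onset is latent and must be estimated from the EMG.

## EMG onset labelling

Per trial, the moved arm's EMG is high-pass filtered (6th-order Butterworth,
10 Hz cutoff, applied forward-backward so the onset estimate is not delayed
by group delay), the Hilbert-envelope magnitude is smoothed with a 200 ms
centered moving average and z-scored over the trial, and the onset is the
first time after the move cue at which the envelope is positive and stays
positive for at least 100 ms.  The raw first-positive-value rule alone is
ill-posed on a whole-trial z-scored envelope — rest-period noise crosses
zero constantly — and the 100 ms sustain guard preserves the rule on clean
data while stabilizing it on noisy data.  The z-score reference is the whole
trial (an alternative would be the relax baseline only); with a clear burst
the two differ only in the constant being crossed.  Trials with onsets
earlier than 3 s or later than 11 s after the move cue are discarded;
survivors are re-referenced so t = 0 is the onset.  All samples are kept at
this stage — the trim to the analysis span [t_ini, 1] s (t_ini =
-(onset + 3), the relax-cue time) happens at the end of preprocessing, for
the reason given there.  Onsets are snapped to the 1/256 s grid so the
later resampling stage lands on integer samples.  On synthetic sessions the estimator's bias is about -60 ms
(the centered smoothing window reaches into the burst) with a few ms of
spread, within the 100 ms tolerance the analysis assumes.

## Preprocessing

Fixed stage order: keep the nine motor-cortex electrodes (F3, Fz, F4, C3,
Cz, C4, P3, Pz, P4), resample the EEG 2048 -> 256 Hz (polyphase FIR
anti-aliasing), band-pass 0.1-100 Hz with a zero-phase 4th-order
Butterworth, common average reference over the nine retained channels, and
finally trim each trial to the analysis span [t_ini, 1] s.  Each stage
appends a provenance record.  EMG is dropped at this point — it exists
only to label onsets.  Note the two-pass Butterworth's roll-off already
costs ~6% energy at 90 Hz; everything the analysis uses lies below 40 Hz.

The trim is deliberately the *last* stage.  The 0.1 Hz high-pass edge has
a ~1.6 s time constant, and any boundary-handling scheme distorts roughly
that much signal next to a data edge.  Filtering an already-trimmed trial
therefore plants a transient exactly at t_ini — inside the relax phase
whose windows train the classifier — and just past the +1 s edge; on null
sessions this artifact alone made relax windows systematically
distinguishable (classification accuracy significantly above the
permutation chance level with no ERD present).  With the trim last, the
filters always see real recording context on both sides of the span and
the null calibration is restored.

## ERD/ERS maps

Trials are trimmed to the common span [-6, 1] s around the onset.  Morlet
wavelets with a fixed 7 cycles give TFR(t, f) on the 1 Hz grid 2-40 Hz
(time axis decimated to 64 Hz; wavelet power varies on the scale of the
wavelet envelope, so nothing is lost).  The map is

    ERDS(t, f) = 100 (TFR(t, f) - TFR_b(f)) / TFR_b(f),

with TFR_b(f) the per-frequency mean over the baseline [-6, -3) s of the
trial-averaged TFR; ERDS >= -100 always.  Cells whose wavelet support
(+-5 sigma_t, the full length mne uses) crosses a trial edge are excluded
from baseline statistics and masked non-significant; below ~4 Hz this can
consume the entire baseline, leaving those rows undefined (NaN).

Significance per cell is a percentile bootstrap over trials: B = 1000
resamples with replacement, recompute the trial-averaged ERDS, flag the
cell when the empirical (alpha/2, 1 - alpha/2) interval excludes zero
(alpha = 0.05).  The resampling unit is the trial — cells within a trial
are strongly dependent, samples are not exchangeable.  On null sessions
(no ERD) the flagged fraction stays near the nominal 5%.

The band/window summary averages ERDS over alpha [8, 13] and beta
[14, 30] Hz in 1 s windows from -6 to 1 s, counting non-significant cells
as zero, so fully quiet windows report exactly 0.00; a final row averages
across channels.  (The detection features below use alpha up to 14 Hz;
the two bounds are kept as given, per analysis stage.)

## Spectral features

For a window [t - T, t) (half-open in samples; endpoint t maps to sample
floor(t fs); features are strictly causal), each electrode's segment is
demeaned and an AR(16) model is fitted by Burg's method; the parametric
PSD is evaluated at the 18 integer frequencies 8-25 Hz (alpha 8-14 and
beta 14-25, the shared 14 Hz point counted once).  Nine electrodes, in the
order F3, Fz, F4, C3, Cz, C4, P3, Pz, P4, give D = 162 features.  The Burg
recursion is implemented as a batch over segments because a single
session's sliding-window grid needs ~1e5 fits; it matches
`statsmodels.regression.linear_model.burg` to machine precision and the
closed-form AR spectrum on known-coefficient processes.  The PSD convention
(one-sided, 2 sigma^2 / fs / |A|^2) is internal: features are z-scored
per dimension with training-set statistics before classification, so only
relative consistency matters.

Training windows are non-overlapping: relax-phase endpoints
t_ini + 3 - kT within [t_ini, t_ini + 3], intention-phase endpoints -kT
within [-3, 0].  Both phases last 3 s, so classes are balanced for any T
dividing 3.

## Detection

An RBF-kernel SVM (C = 1, width sigma = 0.5) is trained on the z-scored
phase windows of a random 80% of trials and applied to the remaining 20%
with sliding windows stepped every 0.1 s; the split/train/test procedure is
repeated 30 times.  Reported metrics: CA/TPE/TNE over the fixed phase
windows (balanced by construction, so CA = (TPE + TNE)/2), the
time-resolved detection accuracy DA(t) (fraction of test trials labelled
"intention" at grid time t; the grid is anchored at t = 1.0 so all trials
share it), and the chance levels DA_sig(t) and CA_sig from the identical
procedure with training labels permuted (CA_sig is the larger of the mean
chance accuracies of the two phases).  The intention onset tMI is the
earliest t* < 0 such that at every grid point in [t*, 0) the two-sided
Wilcoxon rank-sum between the 30 DA(t) and 30 DA_sig(t) values rejects at
alpha = 0.01 with mean DA above chance — sustained significance, so an
isolated spurious crossing cannot define tMI.  NT_D is the fraction of test
timelines containing at least 3 consecutive "intention" outputs (0.3 s)
ending before t = 0.  Both are reported as undefined, not zero, when no
sustained significant interval exists.  CA is compared with CA_sig by a
Wilcoxon signed-rank over the 30 repeats at alpha = 0.01.

**Kernel width convention.**  The kernel is
k(u, v) = exp(-||u - v||^2 / (2 sigma^2 D)) by default — the squared
distance is normalized per feature dimension (scikit-learn
`gamma = 1/(2 sigma^2 D)`, numerically close to `gamma='scale'` on
z-scored data and to LIBSVM's `1/num_features` default).  The reason is
geometric: z-scored D = 162 features put independent samples at squared
distance ~2D ~ 324, so the unnormalized convention gamma = 1/(2 sigma^2)
makes every off-diagonal kernel entry exp(-648) = 0; the Gram matrix is
then the identity and the SVM degenerates to a constant predictor (we
verified CA pins at 0.5).  Set `scale_gamma_by_dim=False` to get the
unnormalized convention.

## Synthetic sessions

The generator emulates the statistical structure the pipeline assumes,
with ground truth for parameter-recovery testing:

* onsets ~ N(7.04, 1.42^2) s after the move cue, truncated to [3, 11] s by
  rejection sampling (matching the recovered-onset statistics the protocol
  produces);
* background EEG: Gaussian 1/f noise, 3 uV RMS per channel, per-channel
  independent plus a shared component (weight 0.3) so the common average
  reference does nontrivial work;
* alpha and beta rhythms: band-limited Gaussian noise (4th-order
  Butterworth passbands 8-13 and 14-30 Hz; 4 and 2.5 uV RMS) added to the
  nine motor channels, independently per channel.  The RMS values are
  chosen so the rhythms dominate the 1/f background at their frequencies
  (in-band SNR ~10-50x), as over motor cortex at rest;
* ERD: the rhythm amplitude ramps linearly from 1 at t = -erd_lead
  (default 1 s before the true onset) to sqrt(1 - depth) at t = 0 and stays
  there — a power drop of `depth` (defaults 0.40 alpha, 0.20 beta) during
  execution.  The ramp is the simplest shape consistent with 1 s window
  averages; it is applied uniformly to all nine motor channels;
* EMG: band-limited (>10 Hz) noise, 2 uV RMS at rest, whose RMS multiplies
  by 10 within 30 ms of the onset on the moved arm's two channels for 2 s.
  The burst morphology is a stand-in — only its detectability by the
  high-pass + Hilbert procedure is modelled, not reaching-EMG shape;
* pre-roll: each trial carries 2 s of plain recording before cue 1
  (`pre_roll`).  The protocol records continuous blocks of 24 trials, so
  cue 1 is never a recording boundary in real data; the pre-roll stands in
  for the preceding trial's rest phase so that the preprocessing filters
  have context before the relax phase (see the trim note above).

Generation runs at 2048 Hz so resampling is genuinely exercised; identical
seeds give bit-identical sessions.

### What the synthetic validation shows — and does not

Passing parameter-recovery tests shows the pipeline correctly estimates
onsets, reconstructs the programmed ERD depths (band-averaged ERDS in
[0, 1) s within a few points of -40 alpha / -20 beta), keeps the bootstrap
and permutation nulls calibrated, and detects intention windows whose
spectra differ from relax.  It does not show performance on real EEG: the
generator has no ocular/muscular artifacts, no volume conduction beyond a
shared background component, no lateralization, and — importantly — its
ERD is locked to the EMG onset with a fixed 1 s lead.  In real data the
cortical power decrease precedes measurable EMG activity by a variable
margin, so deep "execution" ERD leaks into the causal windows that end
shortly before the labelled onset.  With the EMG-locked ramp this cannot
happen: a causal window ending at t = -0.5 s sees a mean power change of
only ~5%, far below single-window detectability, so the sustained
significance that defines tMI can begin only in the last few tenths of a
second before onset regardless of sample size.  Synthetic tMI values are
therefore expected around -0.1 to -0.4 s (or undefined), shallower than on real
recordings; the positive control for the tMI machinery is the constructed-
timeline unit test, and the synthetic end-to-end check validates the
pipeline's calibration, not a specific pre-movement margin.

## Window-size comparison

Detection quality grows with the window length T when the intention-phase
signal is present throughout the phase: a longer window then integrates
more of an always-on power difference.  The package's monotonicity check
therefore uses *sustained-ERD* sessions (`erd_lead = 3`, the ERD declining
across the entire intention phase) and compares mean CA over
T in {0.5, 0.75, 1} s with paired splits.  On ramping sessions
(`erd_lead = 1`) the ordering of T = 0.75 vs T = 1 is genuinely marginal:
the shorter window covers a deeper average drop, the longer one integrates
more samples, and the two nearly cancel.

## Problem sizes used by the test suite

The shipped tests and the acceptance script use: 24-trial sessions for
unit-level checks; 96-trial sessions (the protocol size) for parameter
recovery and detection; thirty independent 100-trial no-ERD sessions with
B = 1000 bootstrap resamples each for null calibration (the flagged
fraction of a single session has substantial realization variance, so the
calibration claim is about its mean over sessions); 30 evaluation repeats
for the headline CA comparison and 15 for multi-seed sweeps.  These sizes
give Monte-Carlo error well inside every asserted tolerance.
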