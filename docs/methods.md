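# Methods

`tmrdecode` implements a per-subject pipeline for detecting cued memory
reactivation in sleep EEG, together with a synthetic session generator
that provides ground truth for every stage. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Pipeline

### Epoching

Continuous 16-channel EEG (fixed montage F3, F4, C5, C3, Cz, C4, C6,
CP5, CP3, CP4, CP6, P7, Pz, P8, O1, O2; 200 Hz) is cut into 1500 ms
epochs, 500 ms of which precede the stimulus (300 samples, stimulus at
index 100). The post-stimulus 1000 ms is baseline-corrected by
subtracting the per-channel mean of the 500 ms baseline. Classification
uses the first 400 ms after the stimulus (80 samples), where the evoked
responses concentrate. A fifth "no cue" class is built from randomly
drawn 400 ms segments of cue-free intervals, baseline-corrected the same
way; by default as many null epochs are drawn as there are trials per
cued class, keeping the five classes balanced. Sample indexing is
0-based with half-open windows, and event times must be integer sample
indices — the experimental timing is an exact multiple of the 5 ms
sample period, so non-integer times indicate a bug upstream and are
rejected rather than rounded.

### Features

Each trial is summarised by 1328 features in three families:

* **DWT (976)** — per channel, a 5-level Daubechies-4 decomposition with
  symmetric (half-point) extension; detail levels 2–5 are kept, spanning
  roughly 3.1–50 Hz. On an 80-sample window the detail lengths are
  25/16/11/9, i.e. 61 coefficients per channel. (A cascade that kept 62
  per channel would need a different boundary convention; the symmetric
  cascade's count is the one this package realises and pins.)
* **Spectral (48)** — Welch band power in theta 4–8 Hz, alpha 8–12 Hz
  and beta 16–24 Hz per channel. Segments are 64 samples, Hann-windowed,
  advanced by 6 samples — the closest integer step to a 90 % overlap
  ratio (58/64 ≈ 90.6 %) — giving three segments per window; a PSD bin
  (width 3.125 Hz) belongs to a band when its centre frequency lies in
  [low, high), and band power is the rectangle-rule sum. No detrending
  is applied; DC leakage cannot reach the 4 Hz-and-up bands.
* **Time-domain (304)** — a length-4 moving average (valid positions
  only) decimated by 4, keeping valid indices 3, 7, …, 75: 19 coarse
  amplitude samples per channel at 20 ms resolution. This decimation
  offset is the only one that yields exactly 19 values.

Columns are ordered DWT → spectral → time, channels ascending within
each family. Features are standardised per column with statistics
fitted on the **training split only**; evaluation and sleep data reuse
those statistics (no leakage; per-set normalisation is available as an
explicit alternative but not the default). Columns whose spread is at
floating-point noise level are treated as constant and normalised to 0
with a warning.

### Feature selection

1. **Discretization** — each training column is cut at its empirical
   1/3 and 2/3 quantiles (linear-interpolation quantiles) into three
   levels; cutpoints are reused wherever levels are needed later.
2. **JMI filter** — features are greedily ranked by joint mutual
   information with the class label: the first feature maximises
   I(X;Y); each next feature maximises the sum over already-ranked X_j
   of I((X_k, X_j); Y). Estimates are plug-in empirical frequencies in
   bits, 0·log0 := 0, no bias correction; ties break to the lower column
   index. The full ranking is a permutation of all columns.
3. **Wrapper** — starting from the two top-ranked features, the ranked
   list is scanned once in order; a candidate is accepted only if it
   *strictly* lowers the stratified 10-fold cross-validated error of the
   discriminant classifier. Strictness prevents bloat from ties; the
   error curve is therefore strictly decreasing by construction. On
   pure-noise features acceptances still occur as chance record-lows of
   the CV error — a property of the acceptance rule itself, not a bug —
   which is why realistic selected-subset sizes run into the tens. The
   scan has no early stop; a `scan_limit` cap trades fidelity for speed
   and is used by the test suite.

### Classifier

A normal-density linear discriminant: Gaussian class-conditional model
with a shared pooled covariance, priors from empirical class
frequencies, posteriors by Bayes' rule (computed via the Cholesky factor
of the pooled covariance). The pooled covariance receives a ridge of
1e−6 × mean diagonal — small enough to be statistically irrelevant,
enough to keep the factorisation stable when selected features are
nearly collinear. Posterior ties break to the lowest class label, so
predictions are deterministic.

Evaluation draws class-balanced 60/40 train/evaluation splits and runs
the complete pipeline (normalisation → discretization → ranking →
wrapper → training) on the training side, five times with fresh splits;
the correct classification rate CCR = n_correct/n_total on the held-out
side is reported per repeat with mean and SD. CCR is carried as a
fraction in [0, 1]; chance for five balanced classes is 0.20. Every
stochastic step consumes a named seed stream spawned from one root seed,
so a repeat is exactly reproducible.

### Sleep decoding

Reactivation latency after a cue is unknown, so each post-cue second is
scanned at 120 lags: 400 ms windows with onsets 0, 5, …, 595 ms (the
naive 0–600 ms grid has 121 onsets; the final endpoint is dropped to
keep 120). Features are extracted per lag, normalised with the training
statistics, restricted to the selected subset and classified — a
120-long label series per trial. A modified majority vote picks the
class with the longest uninterrupted run inside a voting window; ties
go to the run occurring earliest. Twelve windows with 0-based start
lags 0, 10, …, 110, all ending at lag 120, are evaluated, and the
window with the highest all-trial CCR is kept (ties → earliest).
Because the trained cue sequence never repeats a class adjacently,
predictions are chained in presentation order: a prediction equal to
the previous trial's is replaced by the class with the next-longest
run. The chain resets at stimulation-block boundaries (blocks are
separated by 2 min of silence). When a lag series contains a single
class and the constraint forbids it, the fallback is the class with
the highest mean posterior among the remaining four; the *predicted*
(not true) previous label is used, since the true label would leak.

The "true" CCR is the mean over 1000 draws of 50 % of trials (drawn
without replacement) of the chosen window's constrained predictions;
the window is fixed from the full data before resampling. The null
distribution comes from 1000 label shuffles, each re-optimising the
voting window on the shuffled labels (the conservative choice: the
re-optimised null stochastically dominates a fixed-window null), and
p = #(shuffled CCR ≥ true mean)/1000. The (count+1)/(N+1) variant is a
config switch. Note that with re-optimisation the null mean sits
slightly above 0.20 — it is a maximum of twelve correlated window CCRs
— while the fixed-window null is binomial at chance.

### Post-hoc analyses

* Behavioural composite score per block of 10 sequences (120 trials):
  trials with RT > 1000 ms are dropped from both numerator and
  denominator, then CS = mean RT / accuracy (ms; lower is better). A
  block with zero retained accuracy has undefined CS and is flagged.
* Decay across cue repetitions: a 240-trial sliding mean (step 1) of
  per-trial correctness of the constraint-corrected predictions, with a
  Pearson correlation of window mean against window position (undefined
  for a constant series).
* Selection consistency: counts of how often each feature (or
  electrode, family, band) was selected across the 5 training repeats,
  per participant; columns are clustered with Euclidean distance and
  average linkage (UPGMA). The dendrogram cut height is left to the
  user. Group-level inferential tests over participants are out of
  scope; the matrices are what such tests would consume.

## Synthetic sessions

The generator emulates the experiment's structure: a fixed 12-item cue
sequence (1-2-1-4-2-3-4-1-3-2-4-3; each class three times, no adjacent
repeats even across the wrap-around) at 1500 ms spacing; wake blocks of
10 sequences and sleep blocks of 5, separated by 2-minute quiet gaps; a
control condition with 140 sequence presentations. Defaults follow that
design (70 wake sequences → 840 cued trials, 210 per class).

Signals are embedded in 1/f Gaussian noise (exponent 1 by default, the
standard EEG background) at amplitude `snr × noise_sd`:

* **Wake templates** are *topographic*: a smooth 400 ms bump on the
  right-central channels for the left-hand classes 1–2, on the
  left-central channels for classes 3–4, with a negative posterior
  (P7/P8) deflection at 170 ms for the face-cued classes 1 and 3, plus
  a class-shared fronto-central tone response (amplitude `tone_snr ×
  noise_sd`, default ratio 2). The spatial code was chosen deliberately
  over per-class oscillatory bursts: the sliding-lag decoder can only
  work if a misaligned window still carries class information, and a
  channel topography is invariant to lag shifts where an oscillation's
  phase is not.
* **Sleep reactivation** is modelled as a *sustained* response: the
  class's spatial pattern under a plateau (Tukey) envelope lasting
  `sleep_response_ms` (default 800 ms), starting at a latency drawn
  uniformly from [0, 200] ms on the 5 ms lag grid, with amplitude
  multiplied by `decay_per_cue^cue_index` across repetitions. The
  duration default matters: all twelve voting windows end at lag 120,
  so only the start of the voting region can be cut. If the simulated
  response were a brief early transient, the post-response background —
  confidently classified as the "no cue" class — would always form the
  longest run and no voting window could recover the cue (measured:
  0.25 recovery even at extreme SNR). A response persisting late into
  the post-cue second is thus the regime the voting scheme is designed
  for, and with it recovery reaches 1.0 at snr 5. The default jitter
  (200 ms) plus duration (800 ms) keeps the response inside the
  analysed second.
* **Control sessions** embed only the shared tone response, identical
  for all four classes: the tones are then mutually indistinguishable
  while tone-versus-background (class 5) remains decodable.

What the generator does *not* emulate: sleep graphoelements (spindles,
K-complexes, slow oscillations), artefacts, non-stationary noise,
inter-subject variability, or any biophysical head model. Passing the
synthetic benchmarks shows the pipeline recovers planted structure
under its own assumptions; it does not certify performance on real
polysomnography.

## Problem sizes in the test suite

The suite and the acceptance script run scaled-down sessions — 8 wake
sequences (120 cued + 30 null trials), 5 sleep sequences (60 cues), 22
sleep sequences (264 cues) for the decay analysis, wrapper scans capped
at 8–20 candidates, and null-calibration with 100–200 experiments of
200 permutations each — sizes chosen so the statistical assertions
retain power while the whole suite completes in minutes. The full-scale
defaults (70/140 sequences, full wrapper scan, 1000 resamples and
permutations) are exercised for the schedule arithmetic and are the
package defaults throughout.

## Known limitations

* The DWT feature count is extension-mode-dependent; only the symmetric
  cascade's 61-per-channel layout is supported.
* The wrapper's single fixed-order scan does not re-rank after
  acceptances; with strongly redundant features a re-ranking scan could
  select smaller subsets.
* Wake-evaluation CCR does not guarantee sleep transfer: two
  classifiers with equal wake CCR can differ substantially on jittered
  sleep data depending on whether lag-sensitive (DWT) or lag-tolerant
  (time/spectral) features were selected. The acceptance script
  therefore reports sleep recovery averaged over all five repeat
  classifiers.
* EDF reading requires the optional `mne` dependency; EDF writing is
  not supported (sessions are written in the array-archive format).
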