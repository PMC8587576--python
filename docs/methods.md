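# Methods

## Model

The estimator treats beat-to-beat blood-pressure prediction as a regression
between two low-dimensional spectral codes. A single-period waveform of
period T is modeled as a truncated Fourier series

    x(t) = B0 + Σ_{n=1}^{N} A_n cos(n ω0 t + φ_n),  ω0 = 2π/T.

Because the series is linear in the equivalent cos/sin coefficients
(a_n, b_n), the least-squares fit is solved exactly by `numpy.linalg.lstsq`
on the design matrix {cos(n ω0 t_k), sin(n ω0 t_k)} and converted to
amplitude/phase afterwards: A_n = √(a_n² + b_n²), φ_n = atan2(−b_n, a_n).
Fitting amplitude/phase directly would make the problem nonlinear for no
benefit; the linear route reaches the same global optimum of the residual
sum of squares. Phases are wrapped to (−π, π] and set to 0 wherever the
amplitude vanishes (at zero amplitude the phase is unidentifiable).

PPG beats use N = 9 harmonics and no DC term — after a 0.5–8 Hz band-pass
the signal has no DC, and 9 harmonics of a ≤1.5 Hz fundamental cover the
passband. BP beats use N = 17 harmonics *plus* the DC term B0: B0 is the
beat's mean arterial level in mmHg, and without it the decoded waveform's
absolute pressure — hence SBP and DBP — would be undefined. The BP feature
vector is therefore `[B0, A_1..A_17, φ_1..φ_17]` (length 35) and the
regressor predicts the DC along with the harmonics. At prediction time the
decoder needs a period for the output beat; it uses the input PPG beat's
period, since the two channels are synchronized and segmented at matched
feet.

The code-to-code map is a generalized regression neural network: a lazy
Nadaraya–Watson estimator whose "fit" stores the training matrices and
whose prediction is the Gaussian-weighted average of training targets. One
shared pattern layer serves all 35 outputs (the kernel weights do not
depend on the output component), which is algebraically identical to 35
per-component estimators but 35× cheaper. The default width δ = 0.001 on
raw harmonic features (amplitudes O(1), phases O(π)) makes the kernel
effectively a nearest-neighbor selector: the model works when the training
set contains a beat morphologically close to the query, which is exactly
the regime of a large curated cohort where each subject contributes
several near-identical beats.

### Numerical stabilization

At δ = 0.001 the raw exponentials exp(−‖x−μ_i‖²/2δ²) underflow to zero for
*every* training sample, making the weight ratio 0/0. The implementation
subtracts the per-query maximum exponent before exponentiating — exact
algebra, identical to the textbook formula at any δ, and never all-zero.
Exact distance ties in the small-δ regime average the tied targets
symmetrically. Predicted BP amplitude components can carry small negative
excursions (averages of training codes); the decoder folds a negative
amplitude to positive with a π phase flip, which leaves the waveform
unchanged.

## Preprocessing chain

- **Band-pass**: third-order Butterworth, 0.5–8 Hz, applied zero-phase
  (forward–backward with `sosfiltfilt`). Zero-phase application preserves
  foot and peak timing, which both segmentation and the harmonic phase fit
  depend on; the effective magnitude response is the square of the designed
  filter's. Only the PPG channel is filtered: the BP range rule and the
  B0 term need absolute mmHg, so the BP channel keeps its DC. Records carry
  a `filtered` flag and the range filter refuses a band-passed BP beat.
- **Segmentation**: systolic peaks are maxima of contiguous runs where the
  signal exceeds its 0.75 s moving mean (runs shorter than 40 ms are noise
  blips; peaks closer than the minimum beat duration are merged keeping the
  taller). Each foot is the minimum in the preceding inter-peak interval;
  beats run foot-to-foot and must last 0.3–1.5 s (40–200 bpm). BP feet are
  located within ±250 ms of each PPG foot, so pairs align one-to-one.
- **Quality rules**: a beat is dropped if its range is degenerate
  (< 1e−12), its maximum sits on the beat boundary (no interior systolic
  peak), or its peak-to-foot amplitude is below 10% of the cohort median.
  Pairs are dropped unless SBP lies strictly inside (80, 180) mmHg and DBP
  strictly inside (60, 130) mmHg (strict inequalities). Finally, pairs are
  grouped by recording segment and a whole group is removed when its mean
  PPG–BP Pearson r falls below 0.8; "mean r" is interpreted per segment,
  the natural unit of a recording. Setting `r_min <= 0` disables the
  correlation filter entirely rather than removing negatively correlated
  groups.

## Synthetic data

The generator emulates the curated data regime the method targets, not raw
monitor output:

- Each subject is a base PPG code: fundamental frequency uniform in
  0.8–1.5 Hz, amplitudes a1·n^(−1.5) with per-subject lognormal shape
  jitter (σ = 0.2) and a1 uniform in 0.7–1.3 a.u., phases uniform. The
  code's phases are shifted so the decoded wave starts at its minimum,
  matching the foot-to-foot convention. Beats are 1%-jittered variants of
  the base (amplitude, phase, period) — beat-to-beat variability of a
  short resting segment. Periods snap to the 125 Hz grid so noise-free
  beats lie exactly on the truncated-series manifold (the encoder then
  recovers the generating code to machine precision, which several tests
  use as an oracle).
- The BP code is a deterministic function of the PPG code: one cohort base
  gain in 5–20 mmHg per unit PPG amplitude with ±20% per-harmonic
  modulation, per-harmonic phase shifts within ±π/8, a small decaying
  residual tail on harmonics 10–17 (BP structure absent from the PPG
  band), and mean-arterial/pulse-pressure targets affine in the PPG
  fundamental amplitude, mapped onto 70–110 and 35–55 mmHg. A
  deterministic fix-up keeps every clean beat strictly inside the
  admissible SBP/DBP windows. Determinism of the map is essential: it is
  what makes the task learnable by a kernel regressor, and it mirrors the
  physiologic assumption that a stable vascular transfer links the two
  waveforms within a cohort.
- Subjects whose base morphology correlates with its BP image below
  r = 0.85 are redrawn (the gain/phase structure above makes this rare).
  This emulates a cohort that has *already passed* the r ≥ 0.8 correlation
  QC — as any curated paired dataset has by construction — so clean
  synthetic beats survive the QC chain by design.
- Abnormal beats are injected at an exact count (rate × n, rounded),
  cycling four kinds: BP shifted so SBP ≈ 190 mmHg, BP shifted so DBP ≈
  50 mmHg, flat PPG, and PPG attenuated to 1% of its amplitude. Each kind
  is deterministically caught by exactly one QC rule, so filter precision
  and recall can be asserted exactly. Noise, transfer jitter and abnormal
  injection draw from RNG streams spawned separately from the base cohort
  stream, so enabling one does not perturb the others.

What the generator does **not** emulate: motion artifacts with realistic
spectra, baseline wander, inter-subject variation of the vascular transfer
(available only as an option), drug-induced hemodynamic drift, or
measurement quantization. Passing tests therefore demonstrate correctness
of the algorithmic chain and its behavior in the intended near-neighbor
regime — not clinical accuracy on monitor data, which depends on cohort
curation beyond any synthetic model.

## Splits and evaluation

The default split is 70/15/15 at the subject level, which prevents a
subject's beats from leaking across splits. A fully random division of
signal groups (individual beat pairs) is available as
`split_level="segment"`, and a `--paper-split` flag selects 75/12.5/12.5 —
provided because a 75/15/15 split is arithmetically impossible and both
readings are defensible. The validation split is reserved for δ-sensitivity
inspection; the canonical configuration fixes δ = 0.001 and tunes nothing.

Error conventions: errors are signed (predicted − target) mmHg, pooled over
beats. The error STD and the Bland–Altman σ use the sample (n−1)
denominator — at realistic n the n vs n−1 choice is invisible. BHS
cumulative thresholds are inclusive (|d| ≤ 5/10/15 mmHg), per standard BHS
practice. The AAMI check requires mean absolute error < 5 mmHg, error
STD < 8 mmHg and more than 85 subjects. Percentiles of the waveform
correlation use linear interpolation between order statistics.

## Problem sizes

The acceptance script and tests run the end-to-end recovery at 60 subjects
× 10 beats (500 training / 100 test beats after a 5/6–1/6 segment-level
split), the codec round-trip at 1000 random beats, the regressor-vs-oracle
comparison at 100 instances of up to 50 training samples, and the QC
exactness check at 200 beats with 20% abnormal — sizes at which every
quantity of interest is stable across seeds while the whole suite runs in
seconds.

## Known limitations

- With δ = 0.001 the model is a nearest-neighbor lookup; it cannot
  extrapolate to morphologies absent from training, and its accuracy
  degrades gracefully but noticeably for test subjects with no close
  training neighbor (visible as occasional low-r outliers in the worked
  example).
- The BP DC term is predicted like any other component; absolute-pressure
  calibration therefore depends entirely on the training cohort covering
  the query's pressure range.
- The foot detector assumes a dominant periodicity in 40–200 bpm; heavily
  arrhythmic signals yield few or no beats (by design, as a QC outcome).
- The `standardize` option re-interprets δ on the z-scored feature scale;
  it is off by default because the canonical configuration applies δ to
  raw features.
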