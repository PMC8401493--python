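# Methods

## Model and premise

The package treats cardiac electrical activity as a single time-varying
dipole **H**(t) = (X, Y, Z); the voltage of any lead is the projection
V(t) = a·X + b·Y + c·Z onto a fixed lead direction.  Under this premise the
multichannel ECG is a rank-3 signal, and any lead is an exact linear
combination of any three linearly independent leads.  Real torsos violate
the premise (multipolar components, inhomogeneous conduction), which is why
the package also provides nonlinear reconstruction models and a synthetic
preset that deliberately breaks linearity.

All models are **per patient**: coefficients or network weights are fitted
to a training prefix of the same record they later reconstruct.  No
population/general coefficient mode is provided.

## Reconstruction models

**Linear regression** (control).  For each target lead, ordinary least
squares of the target on the three input leads, no intercept (the signals
are high-pass filtered, and the dipole projection has no offset term; an
intercept can be enabled per model).  The solver is a QR/SVD least-squares
factorisation (`numpy.linalg.lstsq`); its equivalence with the explicit
normal-equations (Gram-inverse) solution is asserted in tests rather than
used as the implementation.  Inputs whose Gram matrix condition number
exceeds 1e10 (configurable) are rejected as rank deficient.

**P-wave-segmented linear regression.**  R peaks are detected on a
designated lead (default: the first input lead); each RR interval
contributes a P-wave window `[R_i + round(0.575·RR), R_i + round(0.92·RR))`
anchored to the interval's *preceding* R peak, so the window sits just
before the next QRS where the P wave physiologically lies.  Fractions are
applied with round-half-away-from-zero; windows are clipped at record
edges; samples before the first and after the last R peak belong to the
"rest" buffer.  Two coefficient sets are fitted — β0 on the pooled P-wave
samples of all beats, β1 on the rest — and predictions are re-interleaved
exactly.  A buffer that is empty, smaller than three samples or rank
deficient falls back to the unsegmented fit with a warning, so degenerate
segmentations degrade gracefully to plain linear regression.

**MLP reconstruction.**  One-hidden-layer feed-forward perceptrons with
hyperbolic-tangent hidden units and a linear output layer, in two
strategies: `per_lead` (one single-output network per target lead) and
`all_leads` (one network with 12 output neurons); both use the same hidden
size (default 10, configurable; `sweep_hidden` reproduces an empirical
layer-size sweep over {2, 5, 10, 15, 20}).  Inputs and targets are
standardized to zero mean / unit variance computed **on the training
segment only** and frozen into the model; without this, millivolt-scale
signals sit deep in the tanh tail and training stalls.  Initial weights are
uniform in [−0.5, 0.5] with a Nguyen–Widrow-style rescaling of the hidden
rows (common norm 0.7·H^(1/3)) and spread hidden biases, reproducible for a
fixed seed.

**Levenberg–Marquardt training.**  The loss is the sum of squared errors on
standardized targets.  Each epoch solves (JᵀJ + µI)δ = Jᵀr with the
Jacobian computed analytically by backpropagation and accumulated in
4096-sample chunks (memory stays flat in the record length; for the
12-output network the residuals of all outputs are stacked into one
vector).  µ starts at 1e-3, is multiplied by 10 after a rejected step and
by 0.1 after an accepted one, interpolating between Gauss–Newton and
gradient descent.  Training stops at 200 epochs, when max|Jᵀr| < 1e-7,
when an accepted step improves the loss by less than 1e-9, or when no µ up
to 1e10 yields a decrease.  The recorded loss history contains the initial
loss and every accepted step, hence is non-increasing, and is bitwise
reproducible for a fixed seed.  There is no early-stopping validation
split: the short (16 s) training segment is used in full.

## Figures of merit

With x the original and x̃ the reconstructed lead (both mV, N test
samples):

* RMS (µV) = 1000·√(Σ(x̃−x)²/N)
* CC (%) = 100·(1/(N−1))·Σ[(x−μx)/σx]·[(x̃−μx̃)/σx̃], i.e. Pearson r with
  (N−1)-normalised standard deviations
* MAD (µV) = 1000·max|x̃−x|, over the complete test segment (not per cycle)
* SSD (mV²) = Σ(x̃−x)²
* SNR (dB) = 10·log10(Σ(x−x̄)² / Σ(x−x̃)²)

SNR is reported **signal power over error power**, so larger is better and
a good reconstruction yields positive dB; the inverse orientation (error
over signal, which yields negative dB for good reconstructions) is
available via a flag for comparison with sources that print the ratio that
way.  A perfect reconstruction reports +∞.  CC and SNR are undefined
(raised as errors) for constant signals.  The identities
SSD = N·(RMS/1000)² and SNR = 10·log10(centered signal power/SSD) are
asserted on every report in the test suite.

Metrics are computed per lead over the full test segment; aggregation
across leads uses means (tables) and boxplots (plotting helper).  Method
comparison pools each FoM's per-lead values and applies a two-sided
Wilcoxon rank-sum test against the control method: exact enumeration over
all rank assignments (mid-ranks for ties) when the pooled size is ≤ 20,
otherwise the normal approximation with continuity correction and
tie-corrected variance.  p-values below 1e-16 print as "<1e-16".

## Preprocessing

Two 4th-order Butterworth filters, applied sequentially (0.67 Hz high-pass,
then 150 Hz low-pass), each forward-backward (`sosfiltfilt`, second-order
sections) so the net phase is zero.  Edge transients are mitigated by
**even**-reflection padding of ≈3 high-pass impulse-response lengths
(3·fs/0.67 samples).  Even rather than odd reflection is a deliberate
numerical choice: when a record is truncated mid-QRS, an anti-symmetric
extension fabricates millivolt-scale spurious transients in the last tens
of milliseconds (measured against filtering a longer record and cropping),
whereas the symmetric extension completes the truncated peak naturally and
bounds the worst-case edge error at a few tens of µV.  Because filtering is
linear, either choice preserves the rank-3 structure, but spurious edge
excursions push MLP inputs outside the training range where tanh networks
extrapolate poorly.  Records shorter than the padding are rejected.  No
50/60 Hz notch is applied.

## R-peak detection

A Pan–Tompkins-style pipeline: 5–15 Hz band-pass emphasis, derivative,
squaring, 150 ms moving-window integration, peak picking at 25 % of the
maximum integrated energy with a 200 ms refractory period, then refinement
to the local maximum of the input signal within ±100 ms.  The detector is
intentionally simple; it is validated against the synthetic generator's
ground-truth annotations (every beat within ±20 ms, no extras) and is not
tuned for pathological rhythms beyond the PVC preset.

## Synthetic records

The generator emulates multichannel recordings for which no public data
with all three montages exist.  Per beat, each of P/Q/R/S/T contributes a
Gaussian bump in beat phase (R at phase 0; the P bump at 75 % of the RR
interval, inside the 57.5–92 % segmentation window) on each dipole axis;
beat-to-beat variability enters through log-free Gaussian RR variation
(default heart rate 60 bpm, fractional RR std 0.05).  The dipole is
projected through fixed electrode lead-field vectors and the named leads
are formed with the textbook algebra (Einthoven, Goldberger, Wilson central
terminal, EASI differences, P8−P7/V2−B8/P8−B8), so the limb-lead identities
hold exactly and every noiseless channel is exactly rank-3.  The dipole is
scaled so the lead-II R peak is 1.0 mV; lead-II RMS is then ≈0.15 mV, so
µV-scale error metrics are meaningful.

The lead-field constants are fixture values chosen for realistic relative
morphologies (positive R in I/II/V4–V6, rS in V1, negative aVR); they are
**not** calibrated against any torso model.  PVC beats (preset `"pvc"`,
probability 0.1/beat) have no preceding P wave, QRS width ×2.5, R amplitude
×1.3 and a ×1.5 compensatory pause — fixture constants, not fitted to
clinical ectopy.  Preset `"nonlinear"` applies a saturating distortion
v ↦ 0.5·tanh(v/0.5) mV to the derived precordial channels, breaking the
linear premise while leaving limb leads exact — it exists to separate
nonlinear from linear reconstruction performance.  Disturbances are
per-channel white Gaussian noise (default 5 µV) and a 0.25 Hz sinusoidal
baseline wander with random per-channel phase (default 30 µV), both seeded.

What the generator does **not** reproduce: real morphology diversity
between patients, respiration-driven amplitude modulation, electrode
motion artifacts, non-stationary myoelectric noise, conduction
abnormalities other than the stylised PVC.  Passing the packaged
experiments therefore demonstrates correctness of the pipeline and its
behaviour under the dipole premise plus small additive noise — not
clinical-grade performance on real patients.

## Experiment protocol and problem sizes

`run_experiment` filters the record, trains every requested method on the
first 16 s (default) and computes all FoMs on the remainder; for the
segmented method, R peaks and P windows are computed independently on the
training and test portions.  Everything is deterministic given the
configuration seed.  The headline experiment (scripts/acceptance.py) uses a
120 s record at 1 kHz — 16 000 training and 104 000 test samples — with the
default noise model, EASI inputs, and 12 per-lead MLPs with 10 hidden
units; it completes in well under a minute on one CPU.  Unit and property
tests use 10–60 s records and 2–5 hidden units so the full suite runs in
about half a minute.

## Known limitations

* The dipole premise makes reconstruction intentionally easy; real-data
  accuracy will be worse and montage-dependent.
* The segmented method shares the detector's failure modes: missed beats
  shift P windows into neighbouring waves.  PVC beats get the same
  fractional window even though they lack a P wave.
* LM training of the 12-output network is noticeably slower to converge
  than the 12 single-output networks and occasionally needs its full epoch
  budget; both observations motivated making the hidden size and epoch
  budget configurable.
* WFDB support is a minimal single-segment format-16 subset (sufficient to
  exchange records with standard tools), not a full header parser;
  multi-segment records, annotations and compressed formats are out of
  scope.
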