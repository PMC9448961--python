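# Methods

This note records the models, parameter choices and numerical decisions
behind papwave, and what the synthetic experiments do and do not
demonstrate.

## The synthetic cohort

The simulator generates the six bedside channels from one latent state per
subject:

* **Beat process.** RR intervals are i.i.d. Gaussian around 60/HR,
  truncated at ±3 SD and floored at 300 bpm equivalents.  The heart-rate
  SD maps to the RR scale through the local derivative of 60/HR.
* **Pressure pulses.** Each cardiac cycle is a fixed template — a
  raised-cosine upstroke over the first 30 % of the cycle, then an
  exponential decay (rate 4 per cycle) pulled down to a floor of 0.08 at
  the cycle end — affinely rescaled *on the sampled grid* by a convex
  combination of the cycle's systolic and diastolic targets.  Because the
  rescale uses the sampled extrema and exact endpoint arithmetic, the
  per-beat maximum and minimum of the waveform equal the recorded ground
  truth bit-for-bit.  The decay floor keeps a cycle's tail strictly above
  the next onset, so every boundary valley is a strict local minimum at
  exactly the diastolic value.
* **Respiratory modulation** is pulse-pressure variation: per beat
  ``sys_i = dia + (sys − dia) · (1 + f · sin(ω_resp t_i))`` with the
  diastolic baseline constant per subject and ``f ∈ [0, 0.5)``.
  Modulating the pulse rather than both extremes is what keeps the
  per-beat extrema exactly recoverable for *every* parameter draw: a
  modulated diastolic baseline can undercut the neighbouring cycle's
  valley, and a modulated systole alone inverts the pulse when a subject
  draws a near-zero pulse pressure.
* **ECG** is a train of Gaussian deflections (P, Q, R, S, T) with a
  dominant ~1 mV R wave at each beat time.  **RESP** is a unit sinusoid at
  the respiratory rate.  **PPG** is the pulmonary pulse delayed by the
  pulse-arrival time and passed through one *global* affine map to
  arbitrary units (identical for all subjects).
* **Noise** is additive i.i.d. Gaussian per channel.

Default parameters and cohort ranges follow the vitals of the ICU
population this method targets: heart rate 89 ± 17 bpm, respiration
~20/min, PAP 42/22 mmHg, ABP 117/60 mmHg; ranges span roughly ±1 SD.
The pulse-arrival delay is drawn from 0.15–0.25 s.

**What the simulator does and does not show.**  The global PPG→PAP affine
map makes PAP a deterministic function of the state visible in the
noninvasive channels, so the regression task is learnable by construction
— deliberately: passing tests demonstrate that the *pipeline* (windowing,
features, fitting, reconstruction, beat extraction, metrics) is correct
and leak-free, not that PAP is physically recoverable from PPG at these
accuracies.  Real photoplethysmography does not encode absolute pulmonary
pressure; real data adds sensor artifacts, arrhythmia, missing segments
and pathophysiology the simulator does not model.

## Preprocessing

The conditioning filter is a 4th-order Butterworth bandpass, 0.5–50 Hz,
applied forward–backward (zero phase) identically to all channels.  At
125 Hz sampling the digital design attenuates 60 Hz by far more than
20 dB (bilinear warping compresses the response near Nyquist), while a
10 Hz passband tone is preserved within 5 %.  The synthetic pipeline runs
unfiltered by default (`apply_bandpass: false`): simulated records contain
no baseline wander or mains noise, and the highpass would strip the DC
pressure level that per-beat extraction needs.  The operation itself is
fully tested against its designed frequency response.

Windows are cut in integer sample units (starts at multiples of
``round(125·step)``), eliminating float accumulation.  Windows touching a
flagged (missing-data) sample are dropped.  Splits are by patient with
``round(n·fraction)`` held-out sizes, remainder to train, and every part
at least one subject.

## Wavelet stages

*MODWT.*  The coefficient-domain target is the maximal-overlap DWT with
Symlet-4 at level 6 — seven bands of full window length (D1…D6 + A6),
1,750 values for a 2-s window.  The pyramid uses circular boundary
handling implemented by FFT circular convolution with 1/√2-rescaled,
upsampled filters; this makes the transform exact for *any* window
length (PyWavelets' undecimated transform requires power-of-two multiples)
and energy-preserving, with round-trip error at round-off (~1e-12
relative, asserted < 1e-8).  Windows shorter than 2^level are rejected
with a suggestion to lower the level.

*Scattering.*  Inputs in scattering mode are order-1..4 Gabor scattering
coefficients: cascaded analytic-wavelet modulus operators with quality
factors (8, 1, 1, 1), a frequency-decreasing path rule, and a final
Gaussian low-pass whose standard deviation is the invariance scale
(default: half the window), sampled every quarter of that scale.  Channel
*c* of the feature tensor holds the order-(c+1) paths, zero-padded to the
maximum path count; the order-0 low-pass is prepended to channel 0.  The
transform is deterministic, positively homogeneous, non-negative beyond
order 0, and its dimension depends only on window length and
configuration.  Feature-tensor shape is therefore configuration-dependent
and reported at run time rather than hard-coded.

A consequence worth stating plainly: at the default invariance scale the
features are nearly shift-invariant, which *discards within-window beat
phase*.  Reconstructing a time-resolved waveform from them is then
ill-posed at small training scale — scattering-mode ridge reaches R² ≈ 0.3
on the desk-scale cohort, and the corresponding test asserts a
learnability floor (R² > 0.15), not waveform-grade accuracy.  The raw-mode
pipeline is the accurate one at this scale (below).

## Regression models

Ten classical families are scikit-learn / xgboost estimators behind one
interface (flattened feature vectors; single-output estimators wrapped per
output).  Two defaults deserve mention:

* **Gaussian process**: RBF kernel with the length scale fixed at twice
  the median pairwise training distance (median heuristic), white-noise
  level 1e-4, targets normalized.  Fixing the kernel avoids
  marginal-likelihood optimisation, keeps the fit deterministic and
  O(n³) once, and — because the per-subject pulse-arrival delay enters
  the input–output map multiplicatively — lets the kernel smoother
  interpolate across delays where linear families cannot: ridge plateaus
  near R² 0.79 on the desk-scale task, the GP reaches 0.82–0.97 across
  seeds.
* **Residual CNN**: a 1-D bottleneck ResNet — stem convolution (stride 2),
  stages (3, 4, 6, 3) of 1×1/3/1×1 bottleneck blocks with parameter-free
  shortcuts (stride subsampling + zero channel padding), a 1×1 pre-head
  convolution, and a linear readout of the flattened final feature map.
  That is exactly 16 residual blocks and 50 convolutional layers,
  verifiable by introspection.  The head reads the *flattened* map rather
  than a pooled vector because the output is itself a time-resolved
  window.  Forward/backward passes are explicit numpy (im2col); training
  is minibatch SGD with momentum, inverted dropout before the head, MSE
  loss, deterministic per seed.  The backward pass is verified against
  finite differences with identity activations (ReLU kinks make naive
  finite-difference checks of the full net unreliable).  A reduced
  profile (one block per stage, width 8) is the training default; the
  full 16-block network is constructed and introspected, and trains, but
  at desk scale it generalises across subjects worse than the kernel
  family (test R² ≈ 0.67 after 60 epochs) — small-cohort optimisation of
  a deep network is simply data-starved here, and we report that rather
  than tune around it.

Coefficient-mode training decomposes the target windows with the MODWT
and reconstructs predictions through the exact inverse, so both output
modes produce waveforms; with an oracle that emits the true coefficients
the two modes agree to 1e-8.  For linear ridge the two modes are
mathematically identical (the transform is linear and exactly inverted).

Grid search maximizes validation R², ties broken by lower MSE then grid
order.  Training records the subject ids it saw; the pipeline refuses
train/validation overlap and audits that no test subject entered fitting.

## Per-beat pressures

QRS detection is the classic energy pipeline: 5–15 Hz bandpass,
derivative, squaring, 150 ms moving integration, a threshold at 15 % of
the peak energy, and a 200 ms refractory period; amplitude is normalized
first, so rescaling the ECG changes nothing.  Extraction takes the *n*
highest strict local maxima and *n* lowest strict local minima of the PAP
segment (plateaus resolve to their leftmost sample), re-sorted into time
order.  "Highest valleys" would be meaningless for diastole; lowest is
the only reading under which valley amplitudes are diastolic pressures.
When fewer extrema exist than beats, all available are returned with a
warning — the equality of counts is an assumption, not a guarantee.  The
returned lists are time-ordered but not claimed to be aligned one-to-one
with specific QRS complexes.

On noiseless simulated records this recovers the ground-truth per-beat
SBP/DBP exactly (asserted over ≥ 50 cohorts and 200 seeds during
development).

## Evaluation

Waveform metrics use the standard definitions (sklearn.metrics), MAPE as
a percentage with zero targets excluded under a warning.  R² ≤ EV always
(EV ignores bias).  Per-beat agreement reports MAD, MAPD, MD, SD and CP₅
(< 5 mmHg).  Confidence intervals are percentile bootstrap; the
resampling unit defaults to the window (the model's sampling unit), with
per-sample and per-patient units available.  The reference replication
count is 20,000; interactive paths use fewer.  Calibration: on a Gaussian
toy the empirical 95 % CI coverage over 300–500 Monte-Carlo repeats sits
within 92–97 %.

## Problem sizes

The canonical desk-scale experiment is 20 noiseless subjects × 60 s,
2-s windows at 0.5-s step, three noninvasive input channels, patient
split 16/2/2 — small enough that the full pipeline (simulation through
bootstrap) completes in well under a minute on one CPU, large enough
that the held-out test set has ~230 windows from unseen subjects.  The
comparison harness and examples use 6–12 subjects at 20–40 s.

## Known limitations

* The simulator's PPG–PAP coupling is information-preserving by design;
  accuracy numbers characterize the pipeline, not clinical feasibility.
* Respiratory modulation is piecewise-constant per beat (evaluated at the
  R peak), not continuous within the cycle.
* The scattering configuration reproduces the *structure* of the feature
  stage (paths × frames × channels), not any specific published feature
  count; the exact configuration behind shapes like 5 × 1008 × 4 is not
  recoverable and is treated as documentation, not contract.
* The WFDB reader handles single-segment, format-16, six-channel records
  — enough to round-trip the package's own writer and read
  similarly-shaped archive records, not a general WFDB implementation.
* The full residual network is faithful in architecture but is not the
  strongest model at desk scale; no claim is made about its behaviour
  under large-scale training.
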