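# papwave

Noninvasive estimation of the pulmonary-artery-pressure (PAP) waveform
from bedside monitoring signals.

Pulmonary artery pressure is normally measured with a pulmonary artery
catheter — an invasive procedure with real risk.  The pipeline implemented
here estimates the continuous PAP waveform, and from it per-beat systolic
and diastolic pressures, from signals that are routinely available without
catheterisation: the respiration waveform (RESP), the photoplethysmogram
(PPG) and ECG lead II, optionally augmented by the invasively measured
arterial (ABP) and central venous (CVP) pressures.  It is aimed at
researchers in physiological signal processing who want a fully testable,
dependency-light reimplementation of this class of waveform-to-waveform
regression pipeline.

## The method

Six channels synchronized at 125 Hz are processed in five stages:

1. **Preprocessing** — a 0.5–50 Hz zero-phase Butterworth bandpass, then
   sliding-window segmentation: windows of length *w* ∈ [0.5, 5] s move by
   a step *s* ∈ [0.1, *w*] s.  Dataset splits are at the **patient** level
   (80/10/10), so no subject contributes windows to two partitions.
2. **Features** — either the raw windows, or a 1-D Gabor wavelet
   scattering transform (cascaded wavelet modulus + low-pass averaging),
   producing an *m* × *n* × *c* tensor per signal (*m* scattering paths,
   *n* time frames, *c* filterbank channels).
3. **Regression** — eleven model families map input windows to the PAP
   target: generalized linear, ridge, lasso, SGD, support-vector,
   nearest-neighbour, Gaussian-process, random-forest, extremely
   randomized trees, gradient-boosted trees, and a 1-D residual CNN with
   16 bottleneck blocks and 50 convolutional layers.  In *coefficient
   mode* the target is the level-6 Symlet-4 MODWT of the PAP window —
   seven undecimated bands (D1…D6, A6), 7 × 250 = 1,750 coefficients for a
   2-s window — inverted exactly after prediction; in *waveform mode* the
   PAP window is predicted directly.
4. **Per-beat pressures** — a Pan–Tompkins-style QRS detector counts the
   beats in the ECG; the *n* highest peaks and *n* lowest valleys of the
   (predicted or observed) PAP segment are the per-beat SBP and DBP.
5. **Evaluation** — R², MSE, MAE, MAPE and explained variance for the
   waveform; MAD, MAPD, MD, SD and CP₅ (share of beats within 5 mmHg) for
   per-beat pressures; 95 % percentile-bootstrap confidence intervals with
   the window as the resampling unit.

Because real catheterisation data cannot ship with a package, papwave
includes a **coupled-hemodynamics simulator**: beat-synchronous pressure
pulse trains, ECG and PPG driven by one latent heart-rate process, with
respiratory pulse-pressure modulation and exact per-beat ground truth.
Every stage of the pipeline is tested against that ground truth, most of
it to machine precision.

## Worked example

`examples/train_and_evaluate.py` simulates a 20-subject cohort (60 s per
record, noiseless), splits it 16/2/2 by patient, trains a Gaussian-process
regressor on raw (RESP, PPG, ECG) windows of 2 s, and evaluates on the
held-out patients:

```
patients: 16 train / 2 val / 2 test
test windows: 234
R2  = 0.9533  (95% CI 0.9509-0.9555)
MSE = 2.484 mmHg^2   MAE = 1.217 mmHg   MAPE = 4.05%   EV = 0.9533
SBP agreement on 99 beats: MAD = 1.44 mmHg, CP5 = 100%
```

R² is the fraction of PAP sample variance explained on patients never
seen in training; the CI comes from 500 bootstrap resamples of test
windows.  MAD is the mean absolute difference between predicted and
observed per-beat systolic pressure; CP5 = 100 % means every beat's
predicted SBP lay within 5 mmHg of the observed value.

The other examples each exercise one capability and print what they
compute: `simulate_cohort_records.py` (simulation + exact ground truth),
`wavelet_representations.py` (MODWT round-trip at ~1e-13 relative error,
scattering tensor layout), `extract_beat_pressures.py` (QRS timing and
exact SBP/DBP recovery), `compare_models.py` (the model × window ×
signal-set comparison table).

A thin CLI mirrors the pipeline for shell use:

```sh
papwave simulate --n-subjects 5 --out cohort/
papwave run --config run.yaml --out results/
papwave extract-bp --pap rec.tsv --ecg rec.tsv --out beats.tsv
```

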