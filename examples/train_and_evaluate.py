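"""End-to-end desk-scale experiment: noninvasive channels -> PAP waveform.

Simulates a small cohort, splits it at the patient level, trains a
Gaussian-process regressor on raw (RESP, PPG, ECG) windows, and evaluates
the predicted PAP waveform and per-beat pressures on held-out patients.
"""

import numpy as np

from papwave import (
    detect_qrs, extract_sbp_dbp, metric_report_with_ci, simulate_cohort,
    split_by_patient,
)
from papwave.metrics import bp_agreement
from papwave.models import ModelSpec, predict_pap, train
from papwave.preprocess import segment, segment_cohort

cohort = simulate_cohort(20, seed=3, duration_s=60.0)
records = [rec for rec, _ in cohort]
ids = [rec.subject_id for rec in records]
train_ids, val_ids, test_ids = split_by_patient(ids, seed=3)
print(f"patients: {len(train_ids)} train / {len(val_ids)} val / "
      f"{len(test_ids)} test")

windows = segment_cohort(records, 2.0, 0.5,
                         input_signals=("RESP", "PPG", "ECG"))
spec = ModelSpec("gaussian_process", input_mode="raw",
                 output_mode="waveform")
fitted = train(spec, windows.for_subjects(train_ids),
               windows.for_subjects(val_ids), config={"seed": 3})

te = windows.for_subjects(test_ids)
pred = predict_pap(fitted, te)
report = metric_report_with_ci(
    te.target_windows.ravel(), pred.ravel(), n_reps=500, seed=3,
    unit_ids=np.repeat(np.arange(te.n_windows), te.window_samples))
print(f"test windows: {te.n_windows}")
print(f"R2  = {report.r2:.4f}  (95% CI {report.ci_low['r2']:.4f}"
      f"-{report.ci_high['r2']:.4f})")
print(f"MSE = {report.mse:.3f} mmHg^2   MAE = {report.mae:.3f} mmHg   "
      f"MAPE = {report.mape:.2f}%   EV = {report.ev:.4f}")

# per-beat agreement on one test record, tiled without overlap
rec = next(r for r in records if r.subject_id == test_ids[0])
tiles = segment(rec, 2.0, 2.0, input_signals=("RESP", "PPG", "ECG"))
wave = predict_pap(fitted, tiles).ravel()
obs = tiles.target_windows.ravel()
qrs = detect_qrs(rec.channels["ECG"][:len(wave)])
bp_pred = extract_sbp_dbp(wave, len(qrs))
bp_obs = extract_sbp_dbp(obs, len(qrs))
k = min(len(bp_pred.sbp_mmHg), len(bp_obs.sbp_mmHg))
agree = bp_agreement(bp_obs.sbp_mmHg[:k], bp_pred.sbp_mmHg[:k])
print(f"SBP agreement on {k} beats: MAD = {agree['mad']:.2f} mmHg, "
      f"CP5 = {agree['cp5']:.0f}%")
# R2 is the fraction of PAP sample variance explained on unseen patients;
# CP5 is the share of beats whose predicted systolic pressure lies within
# 5 mmHg of the observed one.
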