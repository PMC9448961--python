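"""Wavelet stages: 7-band MODWT target and scattering input features.

The regression target in coefficient mode is the Symlet-4 MODWT of a PAP
window at level 6 (six detail bands + one approximation, each of window
length), inverted exactly after prediction.  The inputs in scattering mode
are Gabor-wavelet scattering coefficients: shift-stable multiscale
envelopes of the raw channels.
"""

import numpy as np

from papwave import (
    ScatteringConfig, SubjectParams, modwt_decompose, modwt_reconstruct,
    scattering_features, segment, simulate_record,
)

record, _ = simulate_record(SubjectParams(seed=2), duration_s=20.0)
window = record.channels["PAP"][:250]  # one 2-s window

coeffs = modwt_decompose(window)
print(f"MODWT bands: {coeffs.bands.shape}  "
      f"(flattened target length {coeffs.flatten().shape[0]})")
back = modwt_reconstruct(coeffs)
rel = np.linalg.norm(back - window) / np.linalg.norm(window)
print(f"round-trip relative error: {rel:.2e}")
energy_ratio = (coeffs.bands ** 2).sum() / (window ** 2).sum()
print(f"band energy / signal energy: {energy_ratio:.12f}")

windows = segment(record, 2.0, 1.0, input_signals=("RESP", "PPG", "ECG"))
feats = scattering_features(windows, ScatteringConfig())
print(f"scattering tensor: {feats.values.shape}  "
      f"(windows x signals x paths*frames x channels)")
print(f"paths per channel: {feats.paths_per_channel}, "
      f"{feats.n} frames per path")
# The MODWT is exactly invertible (error at round-off); the scattering
# tensor's shape depends only on the window length and configuration.
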