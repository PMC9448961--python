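"""Per-beat systolic/diastolic pressure extraction.

The beat count comes from the ECG: an energy-threshold QRS detector
(band-limit, differentiate, square, moving-window integrate, adaptive
threshold with a 200 ms refractory period — the classic Pan–Tompkins
pipeline).  Systolic and diastolic pressures then come from the pressure
waveform: all strict local maxima and minima are located, the n highest
peaks and n lowest valleys are selected where n is the QRS beat count,
and their amplitudes — re-sorted into time order — are the per-beat SBP
and DBP values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .exceptions import InputError
from .simulate import FS

REFRACTORY_S = 0.2
_INTEGRATION_S = 0.15


@dataclass
class BeatPressures:
    """Time-ordered per-beat pressures extracted from one waveform segment."""

    sbp_mmHg: np.ndarray
    dbp_mmHg: np.ndarray
    peak_indices: np.ndarray
    valley_indices: np.ndarray

    @property
    def n_beats(self) -> int:
        return len(self.sbp_mmHg)


def detect_qrs(ecg: np.ndarray, fs: float = FS) -> np.ndarray:
    """Detect R-peak sample indices in an ECG segment.

    Amplitude-normalized, so rescaling the ECG leaves detections unchanged.
    A flat or non-finite signal yields an empty result with a warning.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs:
        raise InputError(f"ECG shorter than 2 s: {len(ecg)} samples")
    if not np.all(np.isfinite(ecg)) or np.ptp(ecg) == 0:
        warnings.warn("flat or non-finite ECG; no beats detected")
        return np.array([], dtype=int)

    sos = butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, ecg)
    x = x / (np.max(np.abs(x)) or 1.0)
    d = np.gradient(x)
    sq = d * d
    win = max(int(_INTEGRATION_S * fs), 1)
    energy = np.convolve(sq, np.ones(win) / win, mode="same")

    thresh = 0.15 * np.max(energy)
    above = energy > thresh
    refractory = int(REFRACTORY_S * fs)
    peaks = []
    i = 0
    n = len(ecg)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            # R peak = maximum of the band-limited signal in the burst,
            # with a margin for the integration-window smear.
            lo = max(i - win // 2, 0)
            hi = min(j + win // 2, n)
            peak = lo + int(np.argmax(x[lo:hi]))
            if not peaks or peak - peaks[-1] >= refractory:
                peaks.append(peak)
            elif x[peak] > x[peaks[-1]]:
                peaks[-1] = peak
            i = j
        else:
            i += 1
    return np.asarray(sorted(set(peaks)), dtype=int)


def find_extrema(x: np.ndarray):
    """Strict local maxima and minima; plateau ties resolve leftmost.

    Returns ``(peak_indices, valley_indices)``.  A plateau counts as one
    extremum at its leftmost sample; series endpoints are never extrema.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise InputError("need at least 3 samples")
    peaks, valleys = [], []
    i = 1
    n = len(x)
    while i < n - 1:
        if x[i] == x[i - 1]:
            i += 1
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1  # plateau [i, j]
        if j + 1 >= n:
            break
        if x[i] > x[i - 1] and x[i] > x[j + 1]:
            peaks.append(i)
        elif x[i] < x[i - 1] and x[i] < x[j + 1]:
            valleys.append(i)
        i = j + 1
    return np.asarray(peaks, dtype=int), np.asarray(valleys, dtype=int)


def extract_sbp_dbp(pap: np.ndarray, n_beats: int) -> BeatPressures:
    """Per-beat SBP/DBP from a PAP segment given the ECG beat count.

    SBP values are the amplitudes of the ``n_beats`` highest peaks, DBP the
    amplitudes of the ``n_beats`` lowest valleys, each re-sorted into time
    order.  If fewer extrema exist than beats, all available are returned
    with a warning.
    """
    if n_beats < 1:
        raise InputError("n_beats must be >= 1")
    pap = np.asarray(pap, dtype=float)
    peaks, valleys = find_extrema(pap)
    if len(peaks) < n_beats or len(valleys) < n_beats:
        warnings.warn(
            f"beat-count mismatch: {n_beats} beats but only {len(peaks)} "
            f"peaks / {len(valleys)} valleys; returning all available"
        )
    top = peaks[np.argsort(pap[peaks], kind="stable")[::-1][:n_beats]] \
        if len(peaks) else np.array([], dtype=int)
    bot = valleys[np.argsort(pap[valleys], kind="stable")[:n_beats]] \
        if len(valleys) else np.array([], dtype=int)
    top = np.sort(top)
    bot = np.sort(bot)
    return BeatPressures(
        sbp_mmHg=pap[top], dbp_mmHg=pap[bot],
        peak_indices=top, valley_indices=bot,
    )


def beats_from_record(pap: np.ndarray, ecg: np.ndarray,
                      fs: float = FS) -> BeatPressures:
    """ECG-constrained extraction: count beats, then pick pressure extrema."""
    qrs = detect_qrs(ecg, fs)
    if len(qrs) == 0:
        return BeatPressures(
            np.array([]), np.array([]),
            np.array([], dtype=int), np.array([], dtype=int),
        )
    return extract_sbp_dbp(pap, len(qrs))
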