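"""Filtering, sliding-window segmentation and patient-level splits.

The conditioning filter is a 0.5–50 Hz zero-phase Butterworth bandpass
applied identically to every channel, the standard passband for bedside
ECG/pressure conditioning: it removes baseline wander below 0.5 Hz and
mains/measurement noise above 50 Hz without introducing group delay
between channels.

Segmentation slides a fixed-length window over the record in integer
sample steps (start indices ``k * round(125 * step_s)``), pairing the
selected input channels with the PAP target over identical sample ranges.
Dataset splits are always at the patient level so no subject contributes
windows to more than one of train/validation/test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt, sosfreqz

from .exceptions import InputError, ParameterError
from .records import WaveformRecord
from .simulate import CHANNELS, FS

#: Noninvasive input channels (the deployable configuration).
THREE_SIGNALS = ("RESP", "PPG", "ECG")
#: All five candidate inputs, including the invasively measured ABP/CVP.
FIVE_SIGNALS = ("ABP", "CVP", "RESP", "PPG", "ECG")

BAND_HZ = (0.5, 50.0)
FILTER_ORDER = 4

WINDOW_RANGE_S = (0.5, 5.0)
STEP_MIN_S = 0.1


def _design_sos():
    return butter(FILTER_ORDER, BAND_HZ, btype="bandpass", fs=FS, output="sos")


def filter_response_db(freq_hz: float) -> float:
    """Magnitude response (dB) of the zero-phase conditioning filter.

    Zero-phase filtering applies the filter forwards and backwards, so the
    effective magnitude is the squared single-pass response.
    """
    sos = _design_sos()
    _, h = sosfreqz(sos, worN=[2 * np.pi * freq_hz / FS])
    return float(20.0 * np.log10(np.abs(h[0]) ** 2))


def bandpass(record: WaveformRecord) -> WaveformRecord:
    """Apply the 0.5–50 Hz zero-phase bandpass to every channel."""
    if record.fs != FS:
        raise InputError(f"expected fs={FS}, got {record.fs}")
    min_len = 3 * 8 * FILTER_ORDER  # comfortably above the filtfilt pad
    if record.n_samples < min_len:
        raise InputError(
            f"record too short to filter: {record.n_samples} < {min_len} samples"
        )
    sos = _design_sos()
    channels = {ch: sosfiltfilt(sos, record.channels[ch]) for ch in CHANNELS}
    return WaveformRecord(
        subject_id=record.subject_id, fs=record.fs, channels=channels,
        units=dict(record.units),
        quality_mask=None if record.quality_mask is None
        else record.quality_mask.copy(),
    )


@dataclass
class WindowSet:
    """Paired (input, target) windows cut from one or more records.

    ``input_windows`` has shape (n_windows, n_input_signals, window_samples)
    and ``target_windows`` (n_windows, window_samples); the target is always
    the PAP channel.  ``subject_ids`` records provenance per window so the
    train/test discipline can be audited downstream.
    """

    window_s: float
    step_s: float
    input_signals: tuple[str, ...]
    input_windows: np.ndarray
    target_windows: np.ndarray
    subject_ids: np.ndarray
    start_indices: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.input_windows.shape[0]

    @property
    def window_samples(self) -> int:
        return self.input_windows.shape[2]

    def subset(self, mask) -> "WindowSet":
        mask = np.asarray(mask)
        return WindowSet(
            self.window_s, self.step_s, self.input_signals,
            self.input_windows[mask], self.target_windows[mask],
            self.subject_ids[mask], self.start_indices[mask],
        )

    def for_subjects(self, subject_ids) -> "WindowSet":
        keep = set(subject_ids)
        return self.subset(np.array([s in keep for s in self.subject_ids]))

    @classmethod
    def concatenate(cls, parts: list["WindowSet"]) -> "WindowSet":
        if not parts:
            raise InputError("no window sets to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if (p.window_s, p.step_s, p.input_signals) != (
                first.window_s, first.step_s, first.input_signals
            ):
                raise InputError("window sets have incompatible layouts")
        return cls(
            first.window_s, first.step_s, first.input_signals,
            np.concatenate([p.input_windows for p in parts]),
            np.concatenate([p.target_windows for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
            np.concatenate([p.start_indices for p in parts]),
        )


def window_count(n_samples: int, window_s: float, step_s: float) -> int:
    """Number of windows the segmenter will cut from n_samples."""
    ws = int(round(FS * window_s))
    ss = int(round(FS * step_s))
    if n_samples < ws:
        return 0
    return (n_samples - ws) // ss + 1


def segment(record: WaveformRecord, window_s: float, step_s: float,
            input_signals=THREE_SIGNALS) -> WindowSet:
    """Slide a window over the record, pairing inputs with the PAP target.

    Windows touching any sample flagged in the record's quality mask are
    dropped.  A record shorter than one window yields an empty WindowSet
    with a warning.
    """
    if not (WINDOW_RANGE_S[0] <= window_s <= WINDOW_RANGE_S[1]):
        raise ParameterError(
            f"window_s={window_s} outside the supported "
            f"{WINDOW_RANGE_S[0]}-{WINDOW_RANGE_S[1]} s range"
        )
    if not (STEP_MIN_S <= step_s <= window_s):
        raise ParameterError(
            f"step_s={step_s} must lie in [{STEP_MIN_S}, window_s={window_s}]"
        )
    bad = [ch for ch in input_signals if ch not in CHANNELS]
    if bad:
        raise ParameterError(f"unknown input signals: {bad}")
    ws = int(round(FS * window_s))
    ss = int(round(FS * step_s))
    n = record.n_samples
    inputs = record.stack(input_signals)
    target = record.channels["PAP"]
    mask = record.quality_mask

    starts, xw, yw = [], [], []
    if n < ws:
        warnings.warn(
            f"record {record.subject_id} shorter than one window; empty WindowSet"
        )
    else:
        for start in range(0, n - ws + 1, ss):
            if mask is not None and mask[start:start + ws].any():
                continue
            starts.append(start)
            xw.append(inputs[:, start:start + ws])
            yw.append(target[start:start + ws])
    k = len(input_signals)
    return WindowSet(
        window_s=window_s, step_s=step_s,
        input_signals=tuple(input_signals),
        input_windows=np.array(xw, dtype=float).reshape(len(starts), k, ws),
        target_windows=np.array(yw, dtype=float).reshape(len(starts), ws),
        subject_ids=np.array([record.subject_id] * len(starts), dtype=object),
        start_indices=np.asarray(starts, dtype=int),
    )


def segment_cohort(records, window_s: float, step_s: float,
                   input_signals=THREE_SIGNALS) -> WindowSet:
    """Segment a list of records and concatenate the resulting windows."""
    return WindowSet.concatenate(
        [segment(r, window_s, step_s, input_signals) for r in records]
    )


def split_by_patient(cohort, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Partition subject ids into train/validation/test at the patient level.

    Validation and test sizes are ``round(n * fraction)``; the remainder
    goes to training (a 180-subject cohort at 80/10/10 gives 144/18/18).
    The partition is disjoint, exhaustive, and reproducible given the seed.
    """
    cohort = list(cohort)
    n = len(cohort)
    if n < 3:
        raise InputError(f"need at least 3 subjects to split, got {n}")
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError(f"fractions must sum to 1, got {fractions}")
    # round(n * f) for the held-out parts, remainder to train; every part
    # keeps at least one subject so a 3-subject cohort is still splittable.
    n_val = max(int(np.floor(n * fractions[1] + 0.5)), 1)
    n_test = max(int(np.floor(n * fractions[2] + 0.5)), 1)
    n_train = n - n_val - n_test
    if n_train < 1:
        raise InputError(
            f"split of {n} subjects at {fractions} leaves no training subjects"
        )
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [cohort[i] for i in order]
    train = shuffled[:n_train]
    val = shuffled[n_train:n_train + n_val]
    test = shuffled[n_train + n_val:]
    return train, val, test
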