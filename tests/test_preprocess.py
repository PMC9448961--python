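"""Filtering, segmentation and patient-level split contracts."""

import numpy as np
import pytest

from papwave import (
    CHANNELS, FS, InputError, ParameterError, WaveformRecord, bandpass,
    segment, split_by_patient, window_count,
)
from papwave.preprocess import filter_response_db


def _sine_record(freq_hz, n=2500, offset=0.0):
    t = np.arange(n) / FS
    x = np.sin(2 * np.pi * freq_hz * t) + offset
    return WaveformRecord("sine", FS, {ch: x.copy() for ch in CHANNELS})


def _mid_amp(x):
    core = x[len(x) // 4: -len(x) // 4]  # avoid filter edge transients
    return np.ptp(core) / 2.0


class TestBandpass:
    def test_dc_removed(self):
        rec = WaveformRecord(
            "dc", FS, {ch: np.full(2500, 50.0) for ch in CHANNELS})
        out = bandpass(rec).channels["PAP"]
        assert abs(np.mean(out)) < 1e-6

    def test_passband_10hz_preserved(self):
        rec = bandpass(_sine_record(10.0))
        gain = _mid_amp(rec.channels["PAP"])
        # the designed zero-phase response at 10 Hz is the oracle
        expected = 10 ** (filter_response_db(10.0) / 20.0)
        assert abs(gain - expected) < 0.01
        assert abs(gain - 1.0) < 0.05

    def test_stopband_60hz_attenuated(self):
        rec = bandpass(_sine_record(60.0))
        gain = _mid_amp(rec.channels["PAP"])
        assert 20 * np.log10(max(gain, 1e-12)) < -20.0
        # consistent with the frequency-response oracle
        assert filter_response_db(60.0) < -20.0

    def test_zero_phase_no_lag(self):
        rec = _sine_record(5.0)
        out = bandpass(rec).channels["PAP"]
        x = rec.channels["PAP"]
        core = slice(500, 2000)
        lags = np.arange(-5, 6)
        scores = [np.dot(out[core], np.roll(x, k)[core]) for k in lags]
        assert lags[int(np.argmax(scores))] == 0

    def test_idempotent_up_to_ripple(self):
        rec = _sine_record(10.0)
        once = bandpass(rec)
        twice = bandpass(once)
        a0 = _mid_amp(rec.channels["PAP"])
        a1 = _mid_amp(once.channels["PAP"])
        a2 = _mid_amp(twice.channels["PAP"])
        single_dev = abs(1.0 - a1 / a0)
        # second pass deviates by about the square of the single-pass error
        assert abs(a1 / a0 - a2 / a1) < max(single_dev, 0.05) ** 2

    def test_all_channels_filtered_identically(self, default_record):
        rec, _ = default_record
        out = bandpass(rec)
        assert out.n_samples == rec.n_samples
        # PAP and ABP share beat structure; filtering must not de-align them
        ref = bandpass(
            WaveformRecord("x", FS,
                           {ch: rec.channels["PAP"].copy() for ch in CHANNELS})
        )
        assert np.allclose(ref.channels["ECG"], ref.channels["PAP"])

    def test_too_short_record_rejected(self):
        rec = WaveformRecord("s", FS, {ch: np.zeros(20) for ch in CHANNELS})
        with pytest.raises(InputError):
            bandpass(rec)


def brute_force_window_count(n_samples, window_s, step_s):
    ws = int(round(FS * window_s))
    ss = int(round(FS * step_s))
    count = 0
    start = 0
    while start + ws <= n_samples:
        count += 1
        start += ss
    return count


class TestSegment:
    def test_counts_match_enumeration_examples(self, default_record):
        rec, _ = default_record
        ten_s = WaveformRecord(
            "t", FS, {ch: rec.channels[ch][:1250].copy() for ch in CHANNELS})
        assert segment(ten_s, 2.0, 0.5).n_windows == 17
        assert segment(ten_s, 2.0, 2.0).n_windows == 5
        whole = segment(ten_s, 5.0, 5.0)   # one window spanning half; w=L needs w<=5
        assert whole.n_windows == 2

    def test_single_window_when_window_equals_record(self, default_record):
        rec, _ = default_record
        five_s = WaveformRecord(
            "t", FS, {ch: rec.channels[ch][:625].copy() for ch in CHANNELS})
        assert segment(five_s, 5.0, 5.0).n_windows == 1

    def test_counts_match_enumeration_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(100, 4000))
            w = float(rng.uniform(0.5, 5.0))
            s = float(rng.uniform(0.1, w))
            assert window_count(n, w, s) == brute_force_window_count(n, w, s)

    def test_windows_are_aligned_slices(self, default_record):
        rec, _ = default_record
        ws = segment(rec, 2.0, 1.0, input_signals=("PPG", "ECG"))
        k = 3
        start = ws.start_indices[k]
        assert np.array_equal(ws.input_windows[k, 0],
                              rec.channels["PPG"][start:start + 250])
        assert np.array_equal(ws.input_windows[k, 1],
                              rec.channels["ECG"][start:start + 250])
        assert np.array_equal(ws.target_windows[k],
                              rec.channels["PAP"][start:start + 250])

    def test_masked_windows_dropped(self, default_record):
        rec, _ = default_record
        dirty = WaveformRecord(
            rec.subject_id, FS,
            {ch: rec.channels[ch].copy() for ch in CHANNELS},
            quality_mask=np.zeros(rec.n_samples, dtype=bool),
        )
        dirty.quality_mask[500:510] = True
        clean_count = segment(rec, 2.0, 2.0).n_windows
        dirty_count = segment(dirty, 2.0, 2.0).n_windows
        assert dirty_count == clean_count - 1

    def test_short_record_warns_and_empty(self, default_record):
        rec, _ = default_record
        tiny = WaveformRecord(
            "t", FS, {ch: rec.channels[ch][:100].copy() for ch in CHANNELS})
        with pytest.warns(UserWarning):
            ws = segment(tiny, 2.0, 0.5)
        assert ws.n_windows == 0

    @pytest.mark.parametrize("w,s", [(0.4, 0.1), (6.0, 1.0), (2.0, 0.05),
                                     (2.0, 3.0)])
    def test_window_step_ranges_enforced(self, default_record, w, s):
        rec, _ = default_record
        with pytest.raises(ParameterError):
            segment(rec, w, s)


class TestSplit:
    def test_cohort_of_180_splits_144_18_18(self):
        ids = [f"p{i:03d}" for i in range(180)]
        train, val, test = split_by_patient(ids, seed=0)
        assert (len(train), len(val), len(test)) == (144, 18, 18)

    def test_cohort_of_10_splits_8_1_1(self):
        train, val, test = split_by_patient([str(i) for i in range(10)], seed=1)
        assert (len(train), len(val), len(test)) == (8, 1, 1)

    def test_same_seed_reproduces_partition(self):
        ids = [str(i) for i in range(37)]
        assert split_by_patient(ids, seed=5) == split_by_patient(ids, seed=5)
        assert split_by_patient(ids, seed=5) != split_by_patient(ids, seed=6)

    def test_partition_disjoint_and_exhaustive_randomized(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            n = int(rng.integers(3, 60))
            ids = [f"s{i}" for i in range(n)]
            seed = int(rng.integers(0, 2 ** 31))
            train, val, test = split_by_patient(ids, seed=seed)
            parts = [set(train), set(val), set(test)]
            assert parts[0] | parts[1] | parts[2] == set(ids)
            assert not (parts[0] & parts[1] or parts[0] & parts[2]
                        or parts[1] & parts[2])

    def test_bad_inputs_rejected(self):
        with pytest.raises(InputError):
            split_by_patient(["a", "b"])
        with pytest.raises(ParameterError):
            split_by_patient(list("abcdefghij"), fractions=(0.5, 0.2, 0.2))
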