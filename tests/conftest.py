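import numpy as np
import pytest

from papwave import SubjectParams, simulate_cohort, simulate_record


@pytest.fixture(scope="session")
def metronome_record():
    """Noiseless, unmodulated 60 bpm subject: every beat identical."""
    params = SubjectParams(
        heart_rate_bpm=60.0, hr_sd_bpm=0.0, resp_mod_frac=0.0,
        noise_sd=0.0, pap_sys_mmHg=40.0, pap_dia_mmHg=20.0, seed=1,
    )
    return simulate_record(params, 20.0)


@pytest.fixture(scope="session")
def default_record():
    """One subject at the default (modulated, noiseless) physiology."""
    return simulate_record(SubjectParams(seed=7), 30.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six noiseless subjects, 20 s each."""
    return simulate_cohort(6, seed=11, duration_s=20.0)


def per_beat_extrema(pap, beat_times_s, duration_s, fs=125.0):
    """Max/min of each complete cardiac cycle, scanned from the waveform."""
    maxima, minima = [], []
    for i, t in enumerate(beat_times_s):
        a = int(np.ceil(t * fs))
        t_next = beat_times_s[i + 1] if i + 1 < len(beat_times_s) \
            else duration_s
        b = min(int(np.ceil(t_next * fs)), len(pap))
        if b > a:
            maxima.append(pap[a:b].max())
            minima.append(pap[a:b].min())
    return np.asarray(maxima), np.asarray(minima)
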