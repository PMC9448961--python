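"""Coupled-hemodynamics simulator.

Generates six synchronized bedside waveform channels — pulmonary artery
pressure (PAP), arterial blood pressure (ABP), central venous pressure
(CVP), respiration (RESP), photoplethysmogram (PPG) and ECG lead II — on a
common 125 Hz grid, together with exact ground truth: the R-peak times and
the per-beat systolic/diastolic extremes of every pressure channel.

The channels share one latent state: a beat-time process (i.i.d. Gaussian
RR intervals, truncated at three standard deviations) and a sinusoidal
respiratory phase that amplitude-modulates the pressure pulses.  Each
pressure cycle is a fixed template — raised-cosine upstroke followed by an
exponential decay — affinely rescaled *on the sampled grid* so that the
per-beat sampled maximum and minimum equal the ground-truth systolic and
diastolic values to machine precision.  The PPG is the pulmonary pulse
delayed by the pulse-arrival time and passed through one global affine map
to arbitrary units, so the noninvasive channels (RESP, PPG, ECG) determine
the PAP exactly in the noiseless limit: a regression from them to PAP is
learnable by construction, which is what makes the downstream pipeline
testable without patient data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, ParameterError

FS = 125.0
"""Sampling rate (Hz) shared by all channels."""

PRESSURE_CHANNELS = ("PAP", "ABP", "CVP")
CHANNELS = ("PAP", "ABP", "CVP", "RESP", "PPG", "ECG")

# Pulse template: raised-cosine upstroke over the first UPSTROKE_FRAC of the
# cycle, then an exponential decay (rate DECAY_RATE in cycle-phase units)
# pulled down to DECAY_FLOOR at the cycle end.  The floor keeps the end of a
# cycle strictly above the next cycle's onset so the diastolic valley is a
# strict local minimum at the cycle boundary.
UPSTROKE_FRAC = 0.3
DECAY_RATE = 4.0
DECAY_FLOOR = 0.08

# Global affine map from PAP (mmHg) to PPG arbitrary units; identical for
# every subject so PPG amplitude carries the pressure information.
PPG_OFFSET_MMHG = 10.0
PPG_SCALE_MMHG = 50.0

# ECG template: (time offset s, amplitude mV, width s) per deflection.
_ECG_WAVES = (
    (-0.20, 0.12, 0.025),   # P
    (-0.025, -0.08, 0.010),  # Q
    (0.0, 1.00, 0.012),      # R
    (0.025, -0.12, 0.010),   # S
    (0.25, 0.25, 0.040),     # T
)


@dataclass(frozen=True)
class SubjectParams:
    """Physiological parameters of one simulated subject.

    Defaults are the cohort vitals a pulmonary-catheter ICU population
    presents (heart rate 89 bpm, respiration ~20/min, PAP 42/22 mmHg,
    ABP 117/60 mmHg).
    """

    heart_rate_bpm: float = 89.2
    hr_sd_bpm: float = 3.0
    resp_rate_bpm: float = 19.8
    pap_sys_mmHg: float = 42.25
    pap_dia_mmHg: float = 22.15
    abp_sys_mmHg: float = 116.95
    abp_dia_mmHg: float = 59.91
    cvp_mean_mmHg: float = 8.0
    ppg_delay_s: float = 0.2
    resp_mod_frac: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.pap_sys_mmHg > self.pap_dia_mmHg > 0):
            raise ParameterError(
                f"require pap_sys > pap_dia > 0, got "
                f"{self.pap_sys_mmHg}/{self.pap_dia_mmHg}"
            )
        if not (self.abp_sys_mmHg > self.abp_dia_mmHg > 0):
            raise ParameterError(
                f"require abp_sys > abp_dia > 0, got "
                f"{self.abp_sys_mmHg}/{self.abp_dia_mmHg}"
            )
        for name in ("heart_rate_bpm", "resp_rate_bpm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.hr_sd_bpm < 0 or self.noise_sd < 0:
            raise ParameterError("hr_sd_bpm and noise_sd must be >= 0")
        if not (0.0 <= self.resp_mod_frac < 0.5):
            raise ParameterError(
                f"resp_mod_frac must lie in [0, 0.5), got {self.resp_mod_frac}"
            )
        if self.ppg_delay_s < 0:
            raise ParameterError("ppg_delay_s must be >= 0")
        if self.cvp_mean_mmHg <= 2.0:
            raise ParameterError("cvp_mean_mmHg must exceed the 2 mmHg pulse")


@dataclass
class GroundTruth:
    """Exact beat-level truth for one simulated record.

    ``beat_times_s`` holds the R-peak times of every complete beat; the
    per-beat dicts map each pressure channel name to an array of the same
    length giving that beat's systolic maximum / diastolic minimum (mmHg).
    """

    beat_times_s: np.ndarray
    per_beat_sbp_mmHg: dict[str, np.ndarray]
    per_beat_dbp_mmHg: dict[str, np.ndarray]

    @property
    def n_beats(self) -> int:
        return len(self.beat_times_s)

    def validate(self) -> None:
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise InputError("beat_times_s must be strictly increasing")
        for d in (self.per_beat_sbp_mmHg, self.per_beat_dbp_mmHg):
            for ch, arr in d.items():
                if len(arr) != self.n_beats:
                    raise InputError(f"per-beat list for {ch} has wrong length")


def _pulse_template(u: np.ndarray) -> np.ndarray:
    """Raw pulse shape on cycle phase u in [0, 1): 0 at onset, 1 at peak."""
    s = np.empty_like(u)
    up = u < UPSTROKE_FRAC
    s[up] = 0.5 * (1.0 - np.cos(np.pi * u[up] / UPSTROKE_FRAC))
    tail = np.exp(-DECAY_RATE * (u[~up] - UPSTROKE_FRAC))
    tail_end = np.exp(-DECAY_RATE * (1.0 - UPSTROKE_FRAC))
    s[~up] = DECAY_FLOOR + (1.0 - DECAY_FLOOR) * (tail - tail_end) / (1.0 - tail_end)
    return s


def _beat_times(params: SubjectParams, t_lo: float, t_hi: float,
                rng: np.random.Generator) -> np.ndarray:
    """Beat onsets covering [t_lo, t_hi], extending past both ends."""
    rr_mean = 60.0 / params.heart_rate_bpm
    # Map the heart-rate SD to an RR SD via the local derivative of 60/hr.
    rr_sd = 60.0 * params.hr_sd_bpm / params.heart_rate_bpm ** 2
    times = [rr_mean / 2.0]
    # Walk backwards to cover the lead-in, then forwards past t_hi.
    while times[0] > t_lo:
        times.insert(0, times[0] - _draw_rr(rr_mean, rr_sd, rng))
    while times[-1] <= t_hi:
        times.append(times[-1] + _draw_rr(rr_mean, rr_sd, rng))
    return np.asarray(times)


def _draw_rr(rr_mean: float, rr_sd: float, rng: np.random.Generator) -> float:
    if rr_sd == 0.0:
        return rr_mean
    z = rng.standard_normal()
    z = float(np.clip(z, -3.0, 3.0))
    return max(rr_mean + rr_sd * z, 0.2)  # floor at 300 bpm


def _pressure_train(beats: np.ndarray, sys_per_beat: np.ndarray,
                    dia_per_beat: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Pulse train whose sampled per-cycle max/min equal sys/dia exactly."""
    out = np.empty_like(t_grid)
    idx = np.searchsorted(t_grid, beats[0], side="left")
    out[:idx] = dia_per_beat[0]  # only reached if grid precedes first beat
    for i in range(len(beats) - 1):
        j = np.searchsorted(t_grid, beats[i + 1], side="left")
        if j <= idx:
            idx = j
            continue
        u = (t_grid[idx:j] - beats[i]) / (beats[i + 1] - beats[i])
        s = _pulse_template(u)
        lo, hi = s.min(), s.max()
        if hi > lo:
            s = (s - lo) / (hi - lo)
        # Convex combination hits both endpoints bit-exactly at s = 0 and 1.
        out[idx:j] = sys_per_beat[i] * s + dia_per_beat[i] * (1.0 - s)
        idx = j
    out[idx:] = dia_per_beat[-1]
    return out


def _ecg_train(beats: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    ecg = np.zeros_like(t_grid)
    for t0 in beats:
        for off, amp, width in _ECG_WAVES:
            ecg += amp * np.exp(-0.5 * ((t_grid - t0 - off) / width) ** 2)
    return ecg


def simulate_record(params: SubjectParams, duration_s: float):
    """Simulate one subject's six-channel record.

    Parameters
    ----------
    params
        Subject physiology; validated before use.
    duration_s
        Record length in seconds; must cover at least two beats.

    Returns
    -------
    (WaveformRecord, GroundTruth)
        The record holds all six channels at 125 Hz; the ground truth lists
        every complete beat's R-peak time and per-beat pressure extremes.
        With ``noise_sd = 0`` the record is a deterministic function of
        ``params`` and the per-beat sampled extrema of each pressure channel
        equal the ground-truth entries at machine precision.
    """
    from .records import WaveformRecord  # local import to avoid a cycle

    params.validate()
    if duration_s < 2.0 * 60.0 / params.heart_rate_bpm:
        raise InputError(
            f"duration_s={duration_s} too short: need at least two beats at "
            f"{params.heart_rate_bpm} bpm"
        )
    n = int(round(FS * duration_s))
    rng = np.random.default_rng(params.seed)

    rr_max = 60.0 / params.heart_rate_bpm * 2.0
    pad = params.ppg_delay_s + 2.0 * rr_max
    # Extended grid: integer sample positions from -pad to duration+pad so
    # the PPG delay can be applied as an exact sample shift.
    i_lo = -int(np.ceil(pad * FS))
    i_hi = n + int(np.ceil(rr_max * FS))
    t_ext = np.arange(i_lo, i_hi) / FS

    beats = _beat_times(params, t_ext[0] - rr_max, t_ext[-1] + rr_max, rng)

    # Respiratory modulation acts on the pulse pressure (sys_i = dia +
    # (sys - dia) * m_i), one factor per beat evaluated at the R-peak, so
    # each cycle's extremes stay exactly representable on the grid.  The
    # diastolic baseline is constant per subject and m_i > 0.5, which keeps
    # every cycle's systolic peak strictly above its diastolic valley and
    # the valley at every cycle boundary a strict local minimum at exactly
    # the diastolic value, whatever the modulation depth or pulse pressure.
    omega = 2.0 * np.pi * params.resp_rate_bpm / 60.0
    mod = 1.0 + params.resp_mod_frac * np.sin(omega * beats)

    trains = {}
    extremes = {
        "PAP": (params.pap_sys_mmHg, params.pap_dia_mmHg),
        "ABP": (params.abp_sys_mmHg, params.abp_dia_mmHg),
        "CVP": (params.cvp_mean_mmHg + 2.0, params.cvp_mean_mmHg - 2.0),
    }
    sys_of = {ch: dia0 + (sys0 - dia0) * mod
              for ch, (sys0, dia0) in extremes.items()}
    for ch, (sys0, dia0) in extremes.items():
        dia_arr = np.full(len(beats) - 1, dia0)
        trains[ch] = _pressure_train(beats, sys_of[ch][:-1], dia_arr, t_ext)

    # Complete beats: R-peak inside the record and the cycle's peak sample
    # strictly interior to it (the sampled maximum is then the systolic
    # value AND a detectable strict local maximum).
    beat_sel = []
    for i in range(len(beats) - 1):
        if not (0.0 <= beats[i] < duration_s):
            continue
        a = np.searchsorted(t_ext, beats[i], side="left")
        b = np.searchsorted(t_ext, beats[i + 1], side="left")
        if b <= a:
            continue
        peak = a + int(np.argmax(trains["PAP"][a:b]))
        peak_rec = peak + i_lo  # sample index relative to record start
        if 0 < peak_rec < n - 1:
            beat_sel.append(i)
    beat_sel = np.asarray(beat_sel, dtype=int)

    gt = GroundTruth(
        beat_times_s=beats[beat_sel],
        per_beat_sbp_mmHg={
            ch: sys_of[ch][beat_sel] for ch in PRESSURE_CHANNELS
        },
        per_beat_dbp_mmHg={
            ch: np.full(len(beat_sel), extremes[ch][1])
            for ch in PRESSURE_CHANNELS
        },
    )
    gt.validate()

    rec_slice = slice(-i_lo, -i_lo + n)
    delay_samples = int(round(params.ppg_delay_s * FS))
    ppg_slice = slice(-i_lo - delay_samples, -i_lo - delay_samples + n)

    resp = np.sin(omega * t_ext[rec_slice])
    channels = {
        "PAP": trains["PAP"][rec_slice].copy(),
        "ABP": trains["ABP"][rec_slice].copy(),
        "CVP": trains["CVP"][rec_slice].copy(),
        "RESP": resp,
        "PPG": (trains["PAP"][ppg_slice] - PPG_OFFSET_MMHG) / PPG_SCALE_MMHG,
        "ECG": _ecg_train(beats, t_ext[rec_slice]),
    }
    if params.noise_sd > 0:
        for ch in CHANNELS:
            channels[ch] = channels[ch] + rng.normal(0.0, params.noise_sd, n)

    record = WaveformRecord(
        subject_id=f"synth-{params.seed:08d}",
        fs=FS,
        channels=channels,
    )
    return record, gt


#: Default per-field uniform sampling ranges for cohorts, spanning roughly
#: mean +/- one SD of the target ICU population's vitals.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "heart_rate_bpm": (72.0, 106.0),
    "hr_sd_bpm": (1.0, 4.0),
    "resp_rate_bpm": (13.0, 26.5),
    "pap_sys_mmHg": (29.0, 55.5),
    "pap_dia_mmHg": (14.4, 28.9),
    "abp_sys_mmHg": (94.3, 139.7),
    "abp_dia_mmHg": (45.1, 74.7),
    "cvp_mean_mmHg": (5.0, 11.0),
    "ppg_delay_s": (0.15, 0.25),
    "resp_mod_frac": (0.02, 0.08),
    "noise_sd": (0.0, 0.0),
}


def draw_params(ranges: dict[str, tuple[float, float]],
                rng: np.random.Generator, seed: int) -> SubjectParams:
    """Draw one SubjectParams uniformly from per-field ranges."""
    fields = {}
    for name, (lo, hi) in ranges.items():
        if hi < lo:
            raise ParameterError(f"range for {name} is empty: ({lo}, {hi})")
        fields[name] = lo if hi == lo else float(rng.uniform(lo, hi))
    params = SubjectParams(seed=seed, **fields)
    params.validate()
    return params


def simulate_cohort(n_subjects: int,
                    param_ranges: dict[str, tuple[float, float]] | None = None,
                    seed: int = 0, duration_s: float = 60.0):
    """Simulate a cohort of independent subjects.

    Each subject's parameters are drawn uniformly from ``param_ranges``
    (defaults: :data:`DEFAULT_PARAM_RANGES`; supplied fields override the
    defaults field-by-field).  Fully reproducible given ``seed``.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        for k, v in param_ranges.items():
            if k not in dataclasses.asdict(SubjectParams()):
                raise ParameterError(f"unknown parameter: {k}")
            if len(v) != 2:
                raise ParameterError(f"range for {k} must be (lo, hi)")
            ranges[k] = (float(v[0]), float(v[1]))
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        subject_seed = int(child.generate_state(1, np.uint32)[0] % (2 ** 31))
        params = draw_params(ranges, rng, seed=subject_seed)
        rec, gt = simulate_record(params, duration_s)
        rec.subject_id = f"synth-{seed}-{i:04d}"
        out.append((rec, gt))
    return out


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write per-beat truth as a TSV: one row per beat."""
    import pandas as pd

    cols = {"time_s": gt.beat_times_s}
    for ch in PRESSURE_CHANNELS:
        cols[f"{ch.lower()}_sbp_mmHg"] = gt.per_beat_sbp_mmHg[ch]
        cols[f"{ch.lower()}_dbp_mmHg"] = gt.per_beat_dbp_mmHg[ch]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> GroundTruth:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return GroundTruth(
        beat_times_s=df["time_s"].to_numpy(),
        per_beat_sbp_mmHg={
            ch: df[f"{ch.lower()}_sbp_mmHg"].to_numpy() for ch in PRESSURE_CHANNELS
        },
        per_beat_dbp_mmHg={
            ch: df[f"{ch.lower()}_dbp_mmHg"].to_numpy() for ch in PRESSURE_CHANNELS
        },
    )
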