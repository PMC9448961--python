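"""Waveform record container and file I/O.

A :class:`WaveformRecord` is one subject's six synchronized channels (PAP,
ABP, CVP, RESP, PPG, ECG lead II) on a 125 Hz grid.  Two on-disk layouts
are supported:

* ``columnar`` — the package's own delimited text table, one column per
  channel, with a small ``#``-prefixed header carrying the sampling rate,
  subject id and units.  Missing samples are written as ``nan``.
* ``wfdb`` — a minimal reader/writer for the classic header (``.hea``) plus
  format-16 signal (``.dat``) layout used by bedside-monitor archives:
  16-bit little-endian interleaved integers with per-signal gain/baseline,
  the invalid-sample marker -32768 flagging missing data.  Only the subset
  of the format needed for single-segment six-channel records is handled.

Records whose header states a different sampling rate are resampled to
125 Hz (polyphase); runs of missing samples are carried in a boolean
quality mask so the segmenter can drop affected windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .exceptions import FormatError, InputError
from .simulate import CHANNELS, FS

DEFAULT_UNITS = {
    "PAP": "mmHg",
    "ABP": "mmHg",
    "CVP": "mmHg",
    "RESP": "a.u.",
    "PPG": "a.u.",
    "ECG": "mV",
}

_WFDB_INVALID = -32768
_WFDB_GAIN = 200.0


@dataclass
class WaveformRecord:
    """Six synchronized channels of one subject at 125 Hz."""

    subject_id: str
    fs: float
    channels: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_UNITS))
    quality_mask: np.ndarray | None = None  # True where a sample is missing

    def __post_init__(self):
        missing = [ch for ch in CHANNELS if ch not in self.channels]
        if missing:
            raise FormatError(f"missing channels: {', '.join(missing)}")
        lengths = {len(self.channels[ch]) for ch in CHANNELS}
        if len(lengths) != 1:
            raise FormatError(f"channel lengths differ: {sorted(lengths)}")
        if self.quality_mask is None:
            self.quality_mask = np.zeros(self.n_samples, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.channels["PAP"])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def stack(self, signals=CHANNELS) -> np.ndarray:
        """Channels as a (n_signals, n_samples) array in the given order."""
        return np.stack([self.channels[ch] for ch in signals])


def write_record(record: WaveformRecord, path, format: str = "columnar") -> None:
    if format == "columnar":
        _write_columnar(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise FormatError(f"unknown format: {format!r}")


def read_record(path, format: str = "columnar") -> WaveformRecord:
    """Read a record, resampling to 125 Hz when the header states another rate."""
    if format == "columnar":
        rec = _read_columnar(path)
    elif format == "wfdb":
        rec = _read_wfdb(path)
    else:
        raise FormatError(f"unknown format: {format!r}")
    if rec.fs != FS:
        rec = _resample_to_125(rec)
    return rec


# -- columnar ---------------------------------------------------------------

def _write_columnar(record: WaveformRecord, path) -> None:
    path = Path(path)
    units = ",".join(f"{ch}:{record.units.get(ch, '?')}" for ch in CHANNELS)
    data = {ch: record.channels[ch].astype(float).copy() for ch in CHANNELS}
    if record.quality_mask is not None and record.quality_mask.any():
        for ch in CHANNELS:
            data[ch][record.quality_mask] = np.nan
    with open(path, "w") as fh:
        fh.write("# papwave-record v1\n")
        fh.write(f"# subject_id={record.subject_id}\n")
        fh.write(f"# fs={record.fs:g}\n")
        fh.write(f"# units={units}\n")
        # %.17g preserves doubles exactly, so write -> read is lossless.
        pd.DataFrame(data).to_csv(fh, sep="\t", index=False, float_format="%.17g")


def _read_columnar(path) -> WaveformRecord:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if "fs" not in meta:
        raise FormatError(f"{path}: header missing 'fs'")
    missing = [ch for ch in CHANNELS if ch not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing channels: {', '.join(missing)}")
    units = dict(DEFAULT_UNITS)
    for part in meta.get("units", "").split(","):
        if ":" in part:
            ch, u = part.split(":", 1)
            units[ch.strip()] = u.strip()
    channels = {ch: df[ch].to_numpy(dtype=float) for ch in CHANNELS}
    mask = np.zeros(len(df), dtype=bool)
    for ch in CHANNELS:
        bad = ~np.isfinite(channels[ch])
        mask |= bad
        channels[ch][bad] = 0.0
    return WaveformRecord(
        subject_id=meta.get("subject_id", path.stem),
        fs=float(meta["fs"]),
        channels=channels,
        units=units,
        quality_mask=mask,
    )


# -- minimal WFDB (header + format-16 signal file) --------------------------

def _write_wfdb(record: WaveformRecord, path) -> None:
    path = Path(path)
    base = path.with_suffix("")
    name = base.name
    n = record.n_samples
    sigs = []
    for ch in CHANNELS:
        x = record.channels[ch].astype(float).copy()
        if record.quality_mask is not None:
            x[record.quality_mask] = np.nan
        d = np.round(x * _WFDB_GAIN)
        d[~np.isfinite(d)] = _WFDB_INVALID
        sigs.append(np.clip(d, -32768, 32767).astype("<i2"))
    interleaved = np.stack(sigs, axis=1).ravel()
    with open(base.with_suffix(".dat"), "wb") as fh:
        fh.write(interleaved.tobytes())
    with open(base.with_suffix(".hea"), "w") as fh:
        fh.write(f"{name} {len(CHANNELS)} {record.fs:g} {n}\n")
        for ch in CHANNELS:
            unit = record.units.get(ch, "a.u.")
            fh.write(
                f"{name}.dat 16 {_WFDB_GAIN:g}(0)/{unit} 16 0 0 0 0 {ch}\n"
            )


def _read_wfdb(path) -> WaveformRecord:
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"header not found: {hea}")
    lines = [
        ln.strip() for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    sig_lines = lines[1:1 + n_sig]
    descs, gains, baselines, units, dat_files, fmts = [], [], [], [], [], []
    for ln in sig_lines:
        tok = ln.split()
        dat_files.append(tok[0])
        fmts.append(tok[1])
        gain_spec = tok[2] if len(tok) > 2 else "200"
        unit = "a.u."
        if "/" in gain_spec:
            gain_spec, unit = gain_spec.split("/", 1)
        baseline = 0.0
        if "(" in gain_spec:
            gain_part, base_part = gain_spec.split("(", 1)
            baseline = float(base_part.rstrip(")"))
            gain_spec = gain_part
        gains.append(float(gain_spec) if gain_spec else 200.0)
        baselines.append(baseline)
        units.append(unit)
        descs.append(tok[-1] if len(tok) > 8 else f"sig{len(descs)}")
    if any(f != "16" for f in fmts):
        raise FormatError(f"{hea}: only format 16 is supported, got {set(fmts)}")
    if len(set(dat_files)) != 1:
        raise FormatError(f"{hea}: multi-file records are not supported")
    missing = [ch for ch in CHANNELS if ch not in descs]
    if missing:
        raise FormatError(f"{hea}: missing channels: {', '.join(missing)}")
    raw = np.frombuffer((hea.parent / dat_files[0]).read_bytes(), dtype="<i2")
    raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig)
    channels, unit_map = {}, dict(DEFAULT_UNITS)
    mask = np.zeros(raw.shape[0], dtype=bool)
    for j, ch in enumerate(descs):
        if ch not in CHANNELS:
            continue
        d = raw[:, j].astype(float)
        bad = raw[:, j] == _WFDB_INVALID
        mask |= bad
        x = (d - baselines[j]) / gains[j]
        x[bad] = 0.0
        channels[ch] = x
        unit_map[ch] = units[j]
    return WaveformRecord(
        subject_id=name, fs=fs, channels=channels, units=unit_map,
        quality_mask=mask,
    )


# -- resampling -------------------------------------------------------------

def _resample_to_125(rec: WaveformRecord) -> WaveformRecord:
    frac = Fraction(FS / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    channels = {
        ch: resample_poly(rec.channels[ch], up, down) for ch in CHANNELS
    }
    # Propagate the quality mask: any output sample drawing on a missing
    # input sample is flagged.
    mask_f = resample_poly(rec.quality_mask.astype(float), up, down)
    n_out = len(channels["PAP"])
    mask = np.abs(mask_f[:n_out]) > 1e-9
    return WaveformRecord(
        subject_id=rec.subject_id, fs=FS, channels=channels,
        units=dict(rec.units), quality_mask=mask,
    )
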