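"""Performance metrics, bootstrap confidence intervals and report tables.

Waveform agreement between predicted and observed PAP uses the standard
suite: coefficient of determination R^2, mean squared error, mean absolute
error, mean absolute percentage error (reported as a percentage, zero
targets excluded with a warning) and explained variance (which, unlike
R^2, ignores systematic bias — hence R^2 <= EV always).

Per-beat SBP/DBP agreement uses the clinical difference suite: MAD (mean
absolute difference), MAPD (mean absolute percentage difference), MD (mean
difference, i.e. bias), SD (standard deviation of differences) and CP5
(cumulative percentage of beats within 5 mmHg).

Confidence intervals are percentile bootstrap over resampled windows (the
model's sampling unit); a per-patient resampling unit is available as an
option.  20,000 replications is the reference setting; reduced counts are
used where a computation must stay interactive.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    explained_variance_score, mean_absolute_error, mean_squared_error, r2_score,
)

from .exceptions import CIError, InputError, PairingError

METRIC_ORDER = ("r2", "mse", "mae", "mape", "ev")
BP_METRIC_ORDER = ("mad", "mapd", "md", "sd", "cp5")
CP_THRESHOLD_MMHG = 5.0
DEFAULT_BOOTSTRAP_REPS = 20_000


@dataclass
class MetricReport:
    """Point estimates (and optional bootstrap CIs) of the waveform suite."""

    r2: float
    mse: float
    mae: float
    mape: float
    ev: float
    ci_low: dict = field(default_factory=dict)
    ci_high: dict = field(default_factory=dict)
    n_windows: int = 0
    n_patients: int = 0

    def as_dict(self) -> dict:
        out = {m: getattr(self, m) for m in METRIC_ORDER}
        for m in self.ci_low:
            out[f"{m}_ci_low"] = self.ci_low[m]
            out[f"{m}_ci_high"] = self.ci_high[m]
        return out


@dataclass
class BPAgreementReport:
    """Per-beat SBP and DBP agreement (difference suite)."""

    sbp: dict
    dbp: dict

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(which="SBP", **self.sbp), dict(which="DBP", **self.dbp)]
        )


def _metric(name: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if name == "r2":
        return float(r2_score(y_true, y_pred))
    if name == "mse":
        return float(mean_squared_error(y_true, y_pred))
    if name == "mae":
        return float(mean_absolute_error(y_true, y_pred))
    if name == "ev":
        return float(explained_variance_score(y_true, y_pred))
    if name == "mape":
        keep = y_true != 0
        if not keep.all():
            warnings.warn("zero targets excluded from MAPE")
        if not keep.any():
            return float("nan")
        return float(
            100.0 * np.mean(np.abs(y_pred[keep] - y_true[keep])
                            / np.abs(y_true[keep]))
        )
    raise InputError(f"unknown metric: {name}")


def waveform_metrics(y_true, y_pred, n_windows: int = 0,
                     n_patients: int = 0) -> MetricReport:
    """Compute the five waveform metrics on concatenated samples."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise PairingError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    if len(y_true) < 2:
        raise InputError("need at least 2 samples")
    if np.ptp(y_true) == 0:
        raise InputError("constant y_true: R^2 and EV are undefined")
    return MetricReport(
        r2=_metric("r2", y_true, y_pred),
        mse=_metric("mse", y_true, y_pred),
        mae=_metric("mae", y_true, y_pred),
        mape=_metric("mape", y_true, y_pred),
        ev=_metric("ev", y_true, y_pred),
        n_windows=n_windows, n_patients=n_patients,
    )


def bp_agreement(true_bp, pred_bp) -> dict:
    """Difference suite for one pressure (SBP or DBP), paired by time order."""
    true_bp = np.asarray(true_bp, dtype=float)
    pred_bp = np.asarray(pred_bp, dtype=float)
    if true_bp.shape != pred_bp.shape or true_bp.ndim != 1:
        raise PairingError(
            f"cannot pair {true_bp.shape} with {pred_bp.shape}"
        )
    if len(true_bp) < 1:
        raise InputError("need at least one beat")
    diff = pred_bp - true_bp
    return {
        "mad": float(np.mean(np.abs(diff))),
        "mapd": float(100.0 * np.mean(np.abs(diff) / true_bp)),
        "md": float(np.mean(diff)),
        "sd": float(np.std(diff)),
        "cp5": float(100.0 * np.mean(np.abs(diff) < CP_THRESHOLD_MMHG)),
    }


def bp_agreement_report(true_sbp, pred_sbp, true_dbp, pred_dbp
                        ) -> BPAgreementReport:
    return BPAgreementReport(
        sbp=bp_agreement(true_sbp, pred_sbp),
        dbp=bp_agreement(true_dbp, pred_dbp),
    )


def bootstrap_ci(y_true, y_pred, metric: str,
                 n_reps: int = DEFAULT_BOOTSTRAP_REPS, level: float = 95.0,
                 seed: int = 0, unit_ids=None):
    """Percentile bootstrap CI for one metric.

    ``unit_ids`` assigns each sample to a resampling unit (e.g. its window
    or patient); units are resampled with replacement, keeping all samples
    of a drawn unit together.  ``None`` treats each sample as its own unit.
    """
    if n_reps < 100:
        raise CIError("n_reps must be >= 100")
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise PairingError("length mismatch")
    if unit_ids is None:
        groups = [np.array([i]) for i in range(len(y_true))]
    else:
        unit_ids = np.asarray(unit_ids)
        if len(unit_ids) != len(y_true):
            raise PairingError("unit_ids length mismatch")
        uniq = pd.unique(unit_ids)
        groups = [np.flatnonzero(unit_ids == u) for u in uniq]
    if len(groups) < 2:
        raise CIError("need at least 2 resampling units")

    rng = np.random.default_rng(seed)
    n_units = len(groups)
    stats = np.empty(n_reps)
    same_size = len({len(g) for g in groups}) == 1
    if same_size and unit_ids is None:
        # Fast path: per-sample resampling fully vectorized.
        if metric in ("mse", "mae"):
            per = (y_pred - y_true) ** 2 if metric == "mse" else \
                np.abs(y_pred - y_true)
            idx = rng.integers(0, n_units, size=(n_reps, n_units))
            stats = per[idx].mean(axis=1)
        else:
            idx = rng.integers(0, n_units, size=(n_reps, n_units))
            for r in range(n_reps):
                stats[r] = _metric(metric, y_true[idx[r]], y_pred[idx[r]])
    else:
        for r in range(n_reps):
            draw = rng.integers(0, n_units, size=n_units)
            sel = np.concatenate([groups[d] for d in draw])
            stats[r] = _metric(metric, y_true[sel], y_pred[sel])
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(stats, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def metric_report_with_ci(y_true, y_pred, n_reps: int = 2000, seed: int = 0,
                          unit_ids=None, metrics=METRIC_ORDER) -> MetricReport:
    """Point estimates plus bootstrap CIs for the waveform suite."""
    rep = waveform_metrics(y_true, y_pred)
    for i, m in enumerate(metrics):
        lo, hi = bootstrap_ci(y_true, y_pred, m, n_reps=n_reps,
                              seed=seed + i, unit_ids=unit_ids)
        rep.ci_low[m] = lo
        rep.ci_high[m] = hi
    return rep


# -- report rendering -------------------------------------------------------

def render_comparison_table(rows: pd.DataFrame) -> str:
    """Delimited rendering of a comparison table, metric columns in order."""
    if len(rows) == 0:
        raise InputError("no comparison rows")
    lead = [c for c in rows.columns if c not in METRIC_ORDER
            and not c.endswith("_ci_low") and not c.endswith("_ci_high")]
    ordered = lead + [c for m in METRIC_ORDER
                      for c in (m, f"{m}_ci_low", f"{m}_ci_high")
                      if c in rows.columns]
    return rows[ordered].to_csv(sep="\t", index=False)


def parse_comparison_table(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text), sep="\t")


def render_report(rows: pd.DataFrame,
                  bp_reports: list[BPAgreementReport] | None = None) -> str:
    """Human-readable report: waveform table plus BP agreement tables."""
    parts = ["# Waveform prediction performance\n",
             render_comparison_table(rows)]
    if bp_reports:
        parts.append("\n# SBP/DBP agreement\n")
        for rep in bp_reports:
            parts.append(rep.as_frame().to_csv(sep="\t", index=False))
    else:
        parts.append("\n# SBP/DBP agreement: no reports supplied\n")
    return "".join(parts)
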