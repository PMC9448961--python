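"""End-to-end pipeline: simulate -> preprocess -> features -> train ->
predict -> extract SBP/DBP -> evaluate.

A :class:`RunConfig` captures every axis of a run (cohort size, signal
set, window/step, feature and output mode, model, split fractions, seeds,
bootstrap replications).  ``run_pipeline`` executes the stages in order,
logging each stage and writing the metric and BP-agreement reports into a
run directory stamped with the config hash; the same config and seed
reproduce the reports bit-identically.

Test patients are isolated from the first stage: the patient-level split
happens before any fitting, training sees only train/validation subjects
(audited via the window provenance ids recorded by the trained model), and
the stage log records when the test partition is first touched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beats import detect_qrs, extract_sbp_dbp
from .exceptions import PapwaveError
from .metrics import (
    BPAgreementReport, bp_agreement_report, metric_report_with_ci,
    render_comparison_table, render_report,
)
from .models import (
    MODEL_NAMES, ModelSpec, SIGNAL_SETS, TrainedModel, predict_pap, train,
)
from .preprocess import (
    STEP_MIN_S, WINDOW_RANGE_S, WindowSet, bandpass, segment, segment_cohort,
    split_by_patient,
)
from .scattering import ScatteringConfig
from .simulate import simulate_cohort


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    n_subjects: int = 20
    duration_s: float = 60.0
    signal_set: str = "three"
    window_s: float = 2.0
    step_s: float = 0.5
    feature_mode: str = "scattering"  # raw | scattering
    output_mode: str = "modwt_coeffs"  # waveform | modwt_coeffs
    model: str = "ridge"
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    apply_bandpass: bool = False
    bootstrap_reps: int = 500
    noise_sd: float = 0.0
    n_filterbanks: int = 4
    invariance_scale_s: float | None = None
    train_config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fractions"] = list(self.fractions)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PapwaveError(f"unknown config keys: {sorted(unknown)}")
        if "fractions" in data:
            data["fractions"] = tuple(data["fractions"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of constraint violations (empty if runnable)."""
    v = []
    if config.n_subjects < 3:
        v.append(f"n_subjects={config.n_subjects}: need >= 3 to split")
    if not (WINDOW_RANGE_S[0] <= config.window_s <= WINDOW_RANGE_S[1]):
        v.append(
            f"window_s={config.window_s}: outside the supported "
            f"{WINDOW_RANGE_S[0]}-{WINDOW_RANGE_S[1]} s range"
        )
    if config.step_s > config.window_s:
        v.append(f"step_s={config.step_s} exceeds window_s={config.window_s}")
    if config.step_s < STEP_MIN_S:
        v.append(f"step_s={config.step_s}: below the {STEP_MIN_S} s minimum")
    if config.signal_set not in SIGNAL_SETS:
        v.append(f"signal_set={config.signal_set!r}: not in "
                 f"{sorted(SIGNAL_SETS)}")
    if config.model not in MODEL_NAMES:
        v.append(f"model={config.model!r}: not in the 11-model registry")
    if config.feature_mode not in ("raw", "scattering"):
        v.append(f"feature_mode={config.feature_mode!r}: raw or scattering")
    if config.output_mode not in ("waveform", "modwt_coeffs"):
        v.append(f"output_mode={config.output_mode!r}: waveform or modwt_coeffs")
    if abs(sum(config.fractions) - 1.0) > 1e-9 or len(config.fractions) != 3:
        v.append(f"fractions={config.fractions}: must be 3 values summing to 1")
    if config.invariance_scale_s is not None and \
            config.invariance_scale_s > config.window_s:
        v.append(
            f"invariance_scale_s={config.invariance_scale_s} exceeds the window"
        )
    if config.duration_s < 2 * config.window_s:
        v.append(f"duration_s={config.duration_s}: too short for windows")
    return v


def _bp_stage(records_by_id, gts_by_id, model: TrainedModel,
              config: RunConfig, test_ids, log) -> BPAgreementReport | None:
    """Tile each test record with non-overlapping windows, predict, and
    compare per-beat SBP/DBP of predicted vs observed PAP."""
    t_sbp, p_sbp, t_dbp, p_dbp = [], [], [], []
    for sid in test_ids:
        rec = records_by_id[sid]
        tiles = segment(rec, config.window_s, config.window_s,
                        SIGNAL_SETS[config.signal_set])
        if tiles.n_windows == 0:
            continue
        pred = predict_pap(model, tiles).ravel()
        obs = tiles.target_windows.ravel()
        n = len(pred)
        qrs = detect_qrs(rec.channels["ECG"][:n])
        if len(qrs) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bp_pred = extract_sbp_dbp(pred, len(qrs))
            bp_obs = extract_sbp_dbp(obs, len(qrs))
        k_s = min(len(bp_pred.sbp_mmHg), len(bp_obs.sbp_mmHg))
        k_d = min(len(bp_pred.dbp_mmHg), len(bp_obs.dbp_mmHg))
        t_sbp.append(bp_obs.sbp_mmHg[:k_s])
        p_sbp.append(bp_pred.sbp_mmHg[:k_s])
        t_dbp.append(bp_obs.dbp_mmHg[:k_d])
        p_dbp.append(bp_pred.dbp_mmHg[:k_d])
    if not t_sbp:
        return None
    log("extract-bp", f"pooled beats from {len(t_sbp)} test records")
    return bp_agreement_report(
        np.concatenate(t_sbp), np.concatenate(p_sbp),
        np.concatenate(t_dbp), np.concatenate(p_dbp),
    )


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages; returns the run directory."""
    violations = validate_config(config)
    if violations:
        raise PapwaveError("invalid config: " + "; ".join(violations))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{chash}] {stage}: {msg}")

    try:
        # 1. simulate
        cohort = simulate_cohort(
            config.n_subjects,
            {"noise_sd": (config.noise_sd, config.noise_sd)},
            seed=config.seed, duration_s=config.duration_s,
        )
        records_by_id = {rec.subject_id: rec for rec, _ in cohort}
        gts_by_id = {rec.subject_id: gt for rec, gt in cohort}
        log("simulate", f"{config.n_subjects} subjects x {config.duration_s} s")

        # 2. preprocess: optional filtering, patient split, segmentation
        records = list(records_by_id.values())
        if config.apply_bandpass:
            records = [bandpass(r) for r in records]
            records_by_id = {r.subject_id: r for r in records}
            log("preprocess", "0.5-50 Hz zero-phase bandpass applied")
        train_ids, val_ids, test_ids = split_by_patient(
            list(records_by_id), config.fractions, seed=config.seed
        )
        log("preprocess",
            f"patient split {len(train_ids)}/{len(val_ids)}/{len(test_ids)}")
        signals = SIGNAL_SETS[config.signal_set]
        windows = segment_cohort(records, config.window_s, config.step_s,
                                 signals)
        log("preprocess", f"{windows.n_windows} windows "
            f"(w={config.window_s}s, s={config.step_s}s, {config.signal_set})")

        # 3-4. features + training (train/val subjects only)
        spec = ModelSpec(name=config.model, input_mode=config.feature_mode,
                         output_mode=config.output_mode)
        scat = ScatteringConfig(
            n_filterbanks=config.n_filterbanks,
            invariance_scale_s=config.invariance_scale_s,
        ) if config.feature_mode == "scattering" else None
        tr = windows.for_subjects(train_ids)
        va = windows.for_subjects(val_ids)
        fitted = train(spec, tr, va,
                       config=dict(config.train_config, seed=config.seed),
                       scattering_config=scat)
        leaked = set(fitted.train_subject_ids) & set(test_ids)
        if leaked:
            raise PapwaveError(f"test subjects leaked into training: {leaked}")
        log("train", f"{config.model} on {len(train_ids)} subjects "
            f"({tr.n_windows} windows)")

        # 5. predict + evaluate on held-out patients
        te = windows.for_subjects(test_ids)
        log("predict", f"first access to test partition: {len(test_ids)} "
            f"subjects, {te.n_windows} windows")
        pred = predict_pap(fitted, te)
        report = metric_report_with_ci(
            te.target_windows.ravel(), pred.ravel(),
            n_reps=config.bootstrap_reps, seed=config.seed,
            unit_ids=np.repeat(np.arange(te.n_windows), te.window_samples),
        )
        report.n_windows = te.n_windows
        report.n_patients = len(test_ids)
        bp_report = _bp_stage(records_by_id, gts_by_id, fitted, config,
                              test_ids, log)

        # write artifacts
        row = {"model": config.model, "window_s": config.window_s,
               "step_s": config.step_s, "feature_mode": config.feature_mode,
               "signal_set": config.signal_set, **report.as_dict(),
               "n_windows": report.n_windows,
               "n_patients": report.n_patients}
        rows = pd.DataFrame([row])
        (out / "metrics.tsv").write_text(render_comparison_table(rows))
        (out / "metrics.json").write_text(
            json.dumps(row, indent=2, sort_keys=True) + "\n")
        (out / "report.txt").write_text(
            render_report(rows, [bp_report] if bp_report else None))
        if bp_report is not None:
            bp_report.as_frame().to_csv(out / "bp_agreement.tsv", sep="\t",
                                        index=False)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(dict(self_hash=chash, **config.to_dict()), fh,
                           sort_keys=True)
        log("evaluate", f"R2={report.r2:.4f} on {report.n_windows} test windows")
    except PapwaveError:
        raise
    except Exception as exc:  # annotate with stage context
        stage = log_lines[-1].split("]")[1].split(":")[0].strip() \
            if log_lines else "start"
        raise PapwaveError(
            f"pipeline failed after stage {stage!r} (config {chash}): {exc}"
        ) from exc
    finally:
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
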