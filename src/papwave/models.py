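"""Regression models and the comparison harness.

Eleven model families map bedside input windows to the PAP target:

* ten classical regressors (generalized linear, ridge, lasso, SGD, support
  vector, nearest-neighbour, Gaussian process, random forest, extremely
  randomized trees, gradient-boosted trees), which consume the flattened
  feature vector of each window;
* the residual convolutional network (:mod:`papwave.resnet`), which
  consumes the (signals x features x channels) tensor directly.

Two axes of operation mirror the pipeline design:

* ``input_mode`` — ``raw`` feeds the windows themselves, ``scattering``
  the wavelet scattering features;
* ``output_mode`` — ``waveform`` predicts the PAP window directly,
  ``modwt_coeffs`` predicts the 7-band MODWT coefficient vector of the PAP
  window and reconstructs the waveform through the exact inverse
  transform at prediction time.

Training and selection never see test patients; each trained model records
the subject ids it was fitted on so that discipline is auditable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError
from .modwt import CoeffVector, DEFAULT_LEVEL, modwt_decompose, modwt_reconstruct
from .preprocess import WindowSet
from .resnet import ResNet1D, ResNetConfig, build_resnet
from .scattering import FeatureTensor, ScatteringConfig, flatten_features, \
    scattering_features

MODEL_NAMES = (
    "glm", "ridge", "lasso", "sgd", "svr", "knn", "gaussian_process",
    "random_forest", "extra_trees", "xgboost", "resnet",
)

INPUT_MODES = ("raw", "scattering")
OUTPUT_MODES = ("waveform", "modwt_coeffs")


@dataclass(frozen=True)
class ModelSpec:
    """One point in the model/feature/target comparison space."""

    name: str
    input_mode: str = "scattering"
    output_mode: str = "waveform"
    hyperparams: tuple = ()

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ParameterError(
                f"unknown model {self.name!r}; choose from {MODEL_NAMES}"
            )
        if self.input_mode not in INPUT_MODES:
            raise ParameterError(f"input_mode must be one of {INPUT_MODES}")
        if self.output_mode not in OUTPUT_MODES:
            raise ParameterError(f"output_mode must be one of {OUTPUT_MODES}")
        if isinstance(self.hyperparams, dict):  # allow dict at call sites
            object.__setattr__(
                self, "hyperparams", tuple(sorted(self.hyperparams.items()))
            )

    @property
    def hp(self) -> dict:
        return dict(self.hyperparams)


def _build_sklearn(name: str, hp: dict, seed: int):
    from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.linear_model import Lasso, LinearRegression, Ridge, SGDRegressor
    from sklearn.multioutput import MultiOutputRegressor
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.svm import LinearSVR
    import xgboost as xgb

    if name == "glm":
        return LinearRegression(**hp)
    if name == "ridge":
        return Ridge(alpha=hp.get("alpha", 1.0))
    if name == "lasso":
        return Lasso(alpha=hp.get("alpha", 0.01),
                     max_iter=hp.get("max_iter", 2000))
    if name == "sgd":
        return MultiOutputRegressor(
            SGDRegressor(random_state=seed, **hp)
        )
    if name == "svr":
        return MultiOutputRegressor(
            LinearSVR(random_state=seed, max_iter=hp.get("max_iter", 2000),
                      C=hp.get("C", 1.0), dual="auto")
        )
    if name == "knn":
        return KNeighborsRegressor(n_neighbors=hp.get("n_neighbors", 5))
    if name == "gaussian_process":
        return MedianHeuristicGP(
            alpha=hp.get("alpha", 1e-4),
            length_scale_factor=hp.get("length_scale_factor", 2.0),
            seed=seed,
        )
    if name == "random_forest":
        return RandomForestRegressor(
            n_estimators=hp.get("n_estimators", 50), random_state=seed,
            n_jobs=1,
        )
    if name == "extra_trees":
        return ExtraTreesRegressor(
            n_estimators=hp.get("n_estimators", 50), random_state=seed,
            n_jobs=1,
        )
    if name == "xgboost":
        return xgb.XGBRegressor(
            n_estimators=hp.get("n_estimators", 50),
            max_depth=hp.get("max_depth", 4), random_state=seed,
            n_jobs=1, verbosity=0,
        )
    raise ParameterError(f"not a flat-input model: {name}")


class MedianHeuristicGP:
    """Gaussian-process regression with a median-heuristic RBF kernel.

    The length scale is set to ``length_scale_factor`` times the median
    pairwise distance of (a subsample of) the training inputs — the
    standard heuristic for kernel methods — and then held fixed, which
    avoids the expensive marginal-likelihood optimisation and keeps the
    fit deterministic.
    """

    def __init__(self, alpha=1e-4, length_scale_factor=2.0, seed=0,
                 max_pairs_sample=200):
        self.alpha = alpha
        self.length_scale_factor = length_scale_factor
        self.seed = seed
        self.max_pairs_sample = max_pairs_sample
        self._gp = None

    def fit(self, X, y):
        from scipy.spatial.distance import pdist
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF

        X = np.asarray(X)
        stride = max(1, len(X) // self.max_pairs_sample)
        med = float(np.median(pdist(X[::stride])))
        if not np.isfinite(med) or med <= 0:
            med = 1.0
        self._gp = GaussianProcessRegressor(
            kernel=RBF(self.length_scale_factor * med,
                       length_scale_bounds="fixed"),
            alpha=self.alpha, optimizer=None, normalize_y=True,
            random_state=self.seed,
        )
        self._gp.fit(X, y)
        return self

    def predict(self, X):
        return self._gp.predict(X)


@dataclass
class TrainedModel:
    """A fitted model plus everything needed to predict and audit it."""

    spec: ModelSpec
    estimator: object
    window_samples: int
    seed: int
    history: dict = field(default_factory=dict)
    scattering_config: ScatteringConfig | None = None
    train_subject_ids: tuple[str, ...] = ()
    window_s: float = 0.0
    feature_layout: tuple | None = None  # (n_signals, m*n, n_channels)
    modwt_level: int = DEFAULT_LEVEL


def prepare_inputs(windows: WindowSet, spec: ModelSpec,
                   scattering_config: ScatteringConfig | None = None):
    """Build the model input representation for a window set.

    Returns ``(X, layout)`` where X is 2-D (flat vectors) for classical
    models and 4-D (windows x signals x features x channels) for the
    residual network; ``layout`` records the tensor geometry.
    """
    if spec.input_mode == "scattering":
        feats = scattering_features(windows, scattering_config)
        tensor = feats.values
        layout = tensor.shape[1:]
    else:
        # Raw windows as a (signals x samples x 1) tensor.
        tensor = windows.input_windows[..., None]
        layout = tensor.shape[1:]
    if spec.name == "resnet":
        return tensor, layout
    return tensor.reshape(tensor.shape[0], -1), layout


def prepare_targets(windows: WindowSet, spec: ModelSpec,
                    level: int = DEFAULT_LEVEL) -> np.ndarray:
    if spec.output_mode == "modwt_coeffs":
        return modwt_decompose(windows.target_windows, level=level).flatten()
    return windows.target_windows


def train(spec: ModelSpec, train_windows: WindowSet,
          val_windows: WindowSet | None = None,
          config: dict | None = None,
          scattering_config: ScatteringConfig | None = None) -> TrainedModel:
    """Fit one model on training windows.

    ``config`` carries the optimisation settings for the network
    (``dropout``, ``learning_rate``, ``batch_size``, ``epochs``, ``seed``,
    ``full`` for the 16-block profile); classical models ignore all but
    ``seed``.  Training and validation windows must come from disjoint
    patients.
    """
    config = dict(config or {})
    seed = int(config.get("seed", 0))
    if train_windows.n_windows == 0:
        raise InputError("empty training set")
    if val_windows is not None and val_windows.n_windows:
        overlap = set(train_windows.subject_ids) & set(val_windows.subject_ids)
        if overlap:
            raise InputError(
                f"train/validation subjects overlap: {sorted(overlap)[:5]}"
            )
    level = int(config.get("modwt_level", DEFAULT_LEVEL))
    x_train, layout = prepare_inputs(train_windows, spec, scattering_config)
    y_train = prepare_targets(train_windows, spec, level)
    history: dict = {}

    if spec.name == "resnet":
        net_cfg = ResNetConfig(
            stage_plan=(3, 4, 6, 3) if config.get("full") else (1, 1, 1, 1),
            base_width=int(config.get("base_width", 8)),
            dropout=float(config.get("dropout", 0.0)),
            seed=seed,
        )
        net = ResNet1D(layout, y_train.shape[1], net_cfg)
        x_val = y_val = None
        if val_windows is not None and val_windows.n_windows:
            x_val, _ = prepare_inputs(val_windows, spec, scattering_config)
            y_val = prepare_targets(val_windows, spec, level)
        history = net.fit(
            x_train, y_train,
            epochs=int(config.get("epochs", 1)),
            batch_size=int(config.get("batch_size", 8)),
            learning_rate=float(config.get("learning_rate", 1e-3)),
            seed=seed, x_val=x_val, y_val=y_val,
        )
        estimator = net
    else:
        # config keys that are not optimiser settings are estimator
        # hyperparameters, so one grid can search both kinds
        reserved = {"seed", "epochs", "batch_size", "learning_rate",
                    "dropout", "base_width", "full", "modwt_level"}
        hp = dict(spec.hp)
        hp.update({k: v for k, v in config.items() if k not in reserved})
        estimator = _build_sklearn(spec.name, hp, seed)
        estimator.fit(x_train, y_train)
        resid = estimator.predict(x_train) - y_train
        history = {"train_loss": [float(np.mean(resid ** 2))]}

    return TrainedModel(
        spec=spec, estimator=estimator,
        window_samples=train_windows.window_samples, seed=seed,
        history=history, scattering_config=scattering_config,
        train_subject_ids=tuple(sorted(set(train_windows.subject_ids))),
        window_s=train_windows.window_s, feature_layout=tuple(layout),
        modwt_level=level,
    )


def predict_pap(model: TrainedModel, windows: WindowSet) -> np.ndarray:
    """Predict PAP windows (mmHg), shape (n_windows, window_samples).

    Coefficient-mode predictions pass through the exact inverse MODWT
    before being returned, so both output modes yield waveforms.
    """
    x, layout = prepare_inputs(windows, model.spec, model.scattering_config)
    if tuple(layout) != tuple(model.feature_layout):
        raise InputError(
            f"input layout {tuple(layout)} differs from training layout "
            f"{tuple(model.feature_layout)}"
        )
    raw = model.estimator.predict(x)
    raw = np.asarray(raw)
    if model.spec.output_mode == "modwt_coeffs":
        coeffs = CoeffVector.from_flat(
            raw, model.window_samples, level=model.modwt_level
        )
        return modwt_reconstruct(coeffs)
    return raw


def grid_search(spec: ModelSpec, grid: dict, train_windows: WindowSet,
                val_windows: WindowSet,
                scattering_config: ScatteringConfig | None = None):
    """Exhaustive hyperparameter search scored on validation R^2.

    Returns ``(best_config, table)``: the table has one row per grid point
    with validation R^2 and MSE.  Best = highest R^2, ties broken by lowest
    MSE then first-in-grid order.
    """
    from .metrics import waveform_metrics

    if not grid:
        raise ParameterError("empty grid")
    keys = list(grid.keys())
    rows, best = [], None
    y_val = val_windows.target_windows
    for i, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        config = dict(zip(keys, combo))
        fitted = train(spec, train_windows, val_windows, config=config,
                       scattering_config=scattering_config)
        pred = predict_pap(fitted, val_windows)
        rep = waveform_metrics(y_val.ravel(), pred.ravel())
        row = dict(config)
        row["val_r2"] = rep.r2
        row["val_mse"] = rep.mse
        rows.append(row)
        key = (-rep.r2, rep.mse, i)
        if best is None or key < best[0]:
            best = (key, config, fitted)
    table = pd.DataFrame(rows)
    return best[1], table


SIGNAL_SETS = {"three": ("RESP", "PPG", "ECG"),
               "five": ("ABP", "CVP", "RESP", "PPG", "ECG")}


def run_comparison(records, model_names, window_grid, step_grid,
                   feature_modes=("raw", "scattering"),
                   signal_sets=("three", "five"),
                   output_mode_for=None, seed: int = 0,
                   fractions=(0.8, 0.1, 0.1), train_config=None,
                   scattering_config: ScatteringConfig | None = None
                   ) -> pd.DataFrame:
    """Run the model x window x step x features x signals comparison.

    Each row reports the five waveform metrics of one configuration on the
    held-out test patients.  The patient split is performed once so every
    configuration is scored on the same subjects.
    """
    from .metrics import waveform_metrics
    from .preprocess import segment_cohort, split_by_patient

    subject_ids = [rec.subject_id for rec in records]
    train_ids, val_ids, test_ids = split_by_patient(subject_ids, fractions, seed)
    rows = []
    for window_s, step_s, mode, sig_key, name in itertools.product(
            window_grid, step_grid, feature_modes, signal_sets, model_names):
        if step_s > window_s:
            continue
        signals = SIGNAL_SETS[sig_key]
        windows = segment_cohort(records, window_s, step_s, signals)
        spec = ModelSpec(
            name=name, input_mode=mode,
            output_mode=(output_mode_for or {}).get(
                mode, "modwt_coeffs" if mode == "scattering" else "waveform"
            ),
        )
        tr = windows.for_subjects(train_ids)
        va = windows.for_subjects(val_ids)
        te = windows.for_subjects(test_ids)
        fitted = train(spec, tr, va, config=dict(train_config or {}, seed=seed),
                       scattering_config=scattering_config)
        pred = predict_pap(fitted, te)
        rep = waveform_metrics(te.target_windows.ravel(), pred.ravel())
        rows.append({
            "model": name, "window_s": window_s, "step_s": step_s,
            "feature_mode": mode, "signal_set": sig_key,
            "input_signals": "+".join(signals),
            "output_mode": spec.output_mode,
            "r2": rep.r2, "mse": rep.mse, "mae": rep.mae,
            "mape": rep.mape, "ev": rep.ev,
            "n_test_windows": te.n_windows,
            "train_subjects": len(fitted.train_subject_ids),
        })
    return pd.DataFrame(rows)
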