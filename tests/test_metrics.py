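"""Metric definitions, BP agreement suite, bootstrap CIs, report rendering."""

import numpy as np
import pandas as pd
import pytest

from papwave import (
    CIError, InputError, PairingError, bootstrap_ci, bp_agreement,
    bp_agreement_report, render_comparison_table, render_report,
    waveform_metrics,
)
from papwave.metrics import parse_comparison_table


class TestWaveformMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = waveform_metrics(y, y)
        assert rep.r2 == 1.0 and rep.ev == 1.0
        assert rep.mse == 0.0 and rep.mae == 0.0 and rep.mape == 0.0

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = waveform_metrics(y, np.full(3, y.mean()))
        assert abs(rep.r2) < 1e-12

    def test_hand_computed_values(self):
        rep = waveform_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert np.isclose(rep.mse, 1.0 / 3.0)
        assert np.isclose(rep.mae, 1.0 / 3.0)
        assert np.isclose(rep.mape, 100.0 / 9.0)  # mean(0, 0, 1/3) * 100

    def test_constant_truth_rejected(self):
        with pytest.raises(InputError):
            waveform_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_zero_targets_excluded_from_mape_with_warning(self):
        with pytest.warns(UserWarning, match="MAPE"):
            rep = waveform_metrics([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert np.isclose(rep.mape, 100.0 * (0.0 + 0.5) / 2.0)

    def test_r2_never_exceeds_ev(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            y = rng.normal(size=20)
            p = rng.normal(size=20)
            rep = waveform_metrics(y, p)
            assert rep.r2 <= rep.ev + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        y, p = rng.normal(size=50), rng.normal(size=50)
        perm = rng.permutation(50)
        a = waveform_metrics(y, p)
        b = waveform_metrics(y[perm], p[perm])
        for m in ("r2", "mse", "mae", "mape", "ev"):
            assert np.isclose(getattr(a, m), getattr(b, m))

    def test_length_mismatch_rejected(self):
        with pytest.raises(PairingError):
            waveform_metrics([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBPAgreement:
    def test_identical_beats(self):
        t = np.array([40.0, 41.0, 39.0])
        rep = bp_agreement(t, t)
        assert rep == {"mad": 0.0, "mapd": 0.0, "md": 0.0, "sd": 0.0,
                       "cp5": 100.0}

    def test_constant_offset_two(self):
        t = np.array([40.0, 41.0, 39.0])
        rep = bp_agreement(t, t + 2.0)
        assert np.isclose(rep["md"], 2.0)
        assert np.isclose(rep["mad"], 2.0)
        assert np.isclose(rep["sd"], 0.0)
        assert rep["cp5"] == 100.0

    def test_constant_offset_six_fails_cp5(self):
        t = np.array([40.0, 41.0, 39.0])
        assert bp_agreement(t, t + 6.0)["cp5"] == 0.0

    def test_mapd_is_percentage_of_truth(self):
        rep = bp_agreement(np.array([50.0]), np.array([51.0]))
        assert np.isclose(rep["mapd"], 2.0)

    def test_pairing_errors(self):
        with pytest.raises(PairingError):
            bp_agreement([1.0, 2.0], [1.0])
        with pytest.raises(InputError):
            bp_agreement([], [])


class TestBootstrap:
    def test_degenerate_perfect_prediction_zero_width(self):
        y = np.arange(50.0)
        lo, hi = bootstrap_ci(y, y, "mse", n_reps=200, seed=0)
        assert lo == hi == 0.0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(2)
        y, p = rng.normal(size=100), rng.normal(size=100)
        a = bootstrap_ci(y, p, "mae", n_reps=500, seed=7)
        assert a == bootstrap_ci(y, p, "mae", n_reps=500, seed=7)
        assert a != bootstrap_ci(y, p, "mae", n_reps=500, seed=8)

    def test_width_shrinks_with_more_data(self):
        rng = np.random.default_rng(3)
        sd = 1.0
        y_small = rng.normal(size=100)
        y_big = rng.normal(size=10_000)
        lo_s, hi_s = bootstrap_ci(y_small, y_small + rng.normal(0, sd, 100),
                                  "mse", n_reps=1000, seed=0)
        lo_b, hi_b = bootstrap_ci(y_big, y_big + rng.normal(0, sd, 10_000),
                                  "mse", n_reps=1000, seed=0)
        assert (hi_b - lo_b) < (hi_s - lo_s)

    def test_window_unit_resampling(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=200)
        p = y + rng.normal(0, 0.5, 200)
        units = np.repeat(np.arange(20), 10)
        lo, hi = bootstrap_ci(y, p, "mse", n_reps=300, seed=1, unit_ids=units)
        assert lo <= np.mean((p - y) ** 2) <= hi

    def test_coverage_on_gaussian_toy(self):
        # 95% percentile-bootstrap CI for the MSE of a known-noise model
        rng = np.random.default_rng(5)
        n, sd = 100, 1.0
        true_mse = sd ** 2
        hits = 0
        reps = 500
        for r in range(reps):
            y = rng.normal(size=n)
            p = y + rng.normal(0.0, sd, n)
            lo, hi = bootstrap_ci(y, p, "mse", n_reps=2000, seed=r)
            hits += lo <= true_mse <= hi
        coverage = hits / reps
        assert abs(coverage - 0.95) <= 0.03

    def test_too_few_units_rejected(self):
        with pytest.raises(CIError):
            bootstrap_ci([1.0], [1.0], "mse", n_reps=200)
        with pytest.raises(CIError):
            bootstrap_ci([1.0, 2.0], [1.0, 2.0], "mse", n_reps=10)


class TestReports:
    def _rows(self):
        return pd.DataFrame([
            {"model": "ridge", "r2": 0.9, "mse": 1.0, "mae": 0.5,
             "mape": 2.0, "ev": 0.91},
            {"model": "glm", "r2": 0.8, "mse": 2.0, "mae": 0.8,
             "mape": 3.0, "ev": 0.82},
            {"model": "knn", "r2": 0.7, "mse": 3.0, "mae": 1.0,
             "mape": 4.0, "ev": 0.75},
            {"model": "resnet", "r2": 0.95, "mse": 0.5, "mae": 0.3,
             "mape": 1.0, "ev": 0.96},
        ])

    def test_table_has_metric_columns_in_order(self):
        text = render_comparison_table(self._rows())
        header = text.splitlines()[0].split("\t")
        assert header[-5:] == ["r2", "mse", "mae", "mape", "ev"]
        assert len(text.strip().splitlines()) == 5

    def test_render_parse_round_trip(self):
        rows = self._rows()
        back = parse_comparison_table(render_comparison_table(rows))
        pd.testing.assert_frame_equal(
            back[rows.columns], rows, check_dtype=False)

    def test_report_includes_bp_tables_or_notice(self):
        rows = self._rows()
        bp = bp_agreement_report(
            np.array([40.0, 41.0]), np.array([40.5, 41.2]),
            np.array([20.0, 21.0]), np.array([20.1, 20.8]))
        with_bp = render_report(rows, [bp])
        assert "SBP" in with_bp and "cp5" in with_bp
        without = render_report(rows, None)
        assert "no reports supplied" in without

    def test_empty_rows_rejected(self):
        with pytest.raises(InputError):
            render_comparison_table(pd.DataFrame())
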