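"""Model/feature/signal-set comparison on one synthetic cohort.

Reproduces the shape of the method's central comparison: every row is one
(model, window, step, feature mode, signal set) configuration scored on the
same held-out patients.
"""

from papwave import run_comparison, simulate_cohort

cohort = simulate_cohort(8, seed=4, duration_s=30.0)
records = [rec for rec, _ in cohort]

table = run_comparison(
    records,
    model_names=["glm", "ridge"],
    window_grid=[1.0, 2.0],
    step_grid=[1.0],
    feature_modes=["raw"],
    signal_sets=["three", "five"],
    seed=4,
    fractions=(0.7, 0.15, 0.15),
)
cols = ["model", "window_s", "feature_mode", "signal_set", "r2", "mse", "mae"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Five-signal rows may use the invasive ABP/CVP channels; three-signal rows
# never do.  R2 is computed on test patients only.
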