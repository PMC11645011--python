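"""Export a trained model as embedded C source and verify the translation.

Selects the largest tree count fitting a 1 MB flash budget, emits the
dependency-free conditional-expression source for both targets, and checks
the emitted text against the native model with the built-in interpreter at
double and reduced (32-bit) precision.
"""

import numpy as np

from scalebp.experiments import cohort_experiment
from scalebp.export import degradation_report, export_embedded_source, interpret_exported
from scalebp.model import FEATURE_COLUMNS, GBTHyperparams, estimate_size, max_trees_under_budget

run = cohort_experiment(n_subjects=8, label_noise_sd=2.0, seed=21,
                        duration_s=120.0, repetitions=1)
sel = max_trees_under_budget(run["train_table"], GBTHyperparams(),
                             budget_bytes=1_000_000,
                             candidates=(25, 50, 75, 100), cv_folds=2, seed=21)
print(f"largest tree count fitting 1 MB flash: {sel.chosen_n_estimators}")
print(sel.table[["n_estimators", "total_size_bytes", "sbp_pcc", "sbp_mae"]]
      .to_string(index=False))

model = sel.sbp_model
print(f"\nSBP model: {len(model.trees)} trees, {model.node_count()} nodes, "
      f"~{estimate_size(model) / 1024:.1f} KB estimated flash")

exported = export_embedded_source(model, precision="double")
print("emitted source starts:")
print(exported.source_text[:120] + "...")

X = run["test_table"][FEATURE_COLUMNS].to_numpy()
native = model.predict(X)
interp = interpret_exported(exported, X)
print(f"interpreter vs native, max |diff|: {np.max(np.abs(native - interp)):.2e} mmHg")

deg = degradation_report(model, run["test_table"])
print(f"32-bit precision loss: PCC {deg['loss']['pcc']:.2e}, "
      f"MAE {deg['loss']['mae']:.2e} mmHg "
      "(the microcontroller's float arithmetic costs essentially nothing here)")
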