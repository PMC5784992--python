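"""Cross-validated accuracy and AUC-threshold model selection.

Runs analytic leave-one-out and 20-fold CV on the standard recovery
panel and keeps only cell lines with LOO AUC > 0.8 — the marker-driven
lines survive, the random ones do not.
"""

from cytosar.fixtures import default_panel, panel_training_set
from cytosar.reporting import cv_results_table, summarize_models
from cytosar.validation import kfold_cv, loo_cv, select_models

panel = default_panel(seed=42)
ts = panel_training_set(panel)
loo = loo_cv(ts)
kfold = kfold_cv(ts, k=20, seed=0)

table = cv_results_table(loo, kfold, ts.cell_lines)
print(table.to_string(index=False))

retained, dropped = select_models(loo, threshold=0.8)
print("\nretained:", sorted(retained))
for line, reason in dropped.items():
    print(f"dropped {line}: {reason}")

summary = summarize_models(table)
print("\nper-tissue aggregation:\n", summary.per_organ.to_string(index=False))
print("\ngrand means:", summary.grand_means)
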