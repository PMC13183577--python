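"""Generate labelled microglia masks, classify them, and test group effects.

Cells are drawn from per-(strain, sex, region) morphotype mixtures in
which the SHR strain carries an elevated hypertrophic fraction in the
infralimbic cortex (IL) and dentate gyrus (DG); the per-region 2x2 ANOVA
on percent hypertrophic should flag exactly those regions.
"""

import warnings

warnings.filterwarnings("ignore")

from tspforage.pipeline import RunConfig, run_microglia

report = run_microglia(
    RunConfig(simulate=True, n_per_cell=6, microglia_cells_per_rat=40, seed=2)
)
print(report.summary.to_string(index=False))
print()
truth_vs_pred = report.ground_truth.merge(
    report.cells[["cell_id", "morph_class"]], on="cell_id"
)
acc = (truth_vs_pred["true_class"] == truth_vs_pred["morph_class"]).mean()
print(f"classification accuracy vs. generator labels: {100 * acc:.1f}% "
      f"({len(truth_vs_pred)} cells)")
print("A strain p-value below alpha in IL and DG only reproduces the "
      "intended regional neuroinflammation pattern.")
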