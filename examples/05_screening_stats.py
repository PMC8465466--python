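"""Screening statistics: metrics, regional chi-square, validation sizing.

Recomputes diagnostic metrics from recorded confusion counts, compares
regional feature proportions between groups, and sizes prevalence-based
validation sets with scenario expansion.
"""

from facequant.screenstats import (
    ConfusionMatrix,
    ValidationDesign,
    chi_square_2x2,
    confusion_metrics,
    min_validation_sample,
    scenario_expand,
)

cm = ConfusionMatrix(TP=2637, FN=362, FP=991, TN=4842)
m = confusion_metrics(cm)
print(f"test dataset (N={cm.total}): "
      f"ACC {m.accuracy:.2f}%  SEN {m.sensitivity:.2f}%  SPE {m.specificity:.2f}%")

r = chi_square_2x2(1289, 2999 - 1289, 1693, 5833 - 1693)
print(f"\nnose region, case 1289/2999 vs control 1693/5833: "
      f"chi2={r.statistic:.1f}, p={r.p_value:.2g}, {r.direction}")

design = ValidationDesign(prevalence=0.018, sensitivity=0.9, margin=0.1)
base = min_validation_sample(design)
print(f"\nminimum validation set at 1.8% prevalence (sens 0.9, margin 0.1):")
print(f"  {base[0]} cases, {base[1]} controls")
for factor, scen in zip(design.expansion_factors,
                        scenario_expand(base, design.expansion_factors)[1:]):
    print(f"  x{factor:g}: {scen[0]} cases, {scen[1]} controls")

print("\nThe case count comes from the precision formula for estimating")
print("sensitivity; the control count preserves the population prevalence,")
print("so realistic screening sets are heavily control-dominated.")
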