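"""Paired growing-vs-stable cohort with an injected low-shear-area effect.

Generates 11 matched pairs where the growing member's MTLSA_70 is shifted
by +17.56 percentage points (on top of the default per-metric noise),
screens the paired differences with Shapiro-Wilk, and runs the exact
Wilcoxon signed-rank test on every metric.
"""
from aneushear import cohort_report, make_cohort, shapiro_wilk_gate

cohort = make_cohort(n_pairs=11, effect=("MTLSA_70", 17.56), seed=2)

gate = shapiro_wilk_gate(cohort)
print(f"normality screen on paired differences -> recommended: {gate.recommendation}\n")

report = cohort_report(cohort, alpha=0.1)
cols = ["metric", "stable_mean", "growing_mean", "W", "p_value", "significant"]
print(report[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\np-values are exact (full 2^11 sign enumeration); 'significant' flags "
      "p <= 0.1. With 10 uncorrected tests, occasional null-metric flags are expected.")
print("At this effect/noise ratio (17.56 points vs SD ~23) the test detects the "
      "shift in roughly two of three cohorts; other seeds may miss it.")
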