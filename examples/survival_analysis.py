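"""Progression-free-survival comparison across the three subtypes.

PFS analyses first exclude long outliers (>150 months), then fit per-subtype
Kaplan-Meier curves and run the 3-sample log-rank test. A median of None
means the curve never drops to 0.5; only the lower confidence limit is then
informative.
"""

from ptprmeth import CohortConfig, generate_cohort, pfs_analysis

*_, sheet, truth = generate_cohort(CohortConfig(seed=0))

res = pfs_analysis(sheet)
print(f"excluded {len(res['excluded'])} samples with PFS > 150 months")
for group, fit in res["fits"].items():
    med = "not reached" if fit.median is None else f"{fit.median:.1f} months"
    lo = fit.median_ci[0]
    lo_s = "n/a" if lo is None else f"{lo:.1f}"
    print(f"  {group}: median PFS {med} (95% lower limit {lo_s})")
lr = res["logrank"]
print(f"log-rank: chi2 = {lr.statistic:.2f}, df = {lr.degrees_of_freedom}, "
      f"p = {lr.p_value:.4f}")
# The B2 subtype progresses fastest (planted median 29 months), and the
# k-sample log-rank test detects the difference across subtypes.
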