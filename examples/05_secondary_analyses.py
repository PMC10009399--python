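"""Severity correlations and the two sensitivity re-analyses.

CYBOCS (OCD-severity) correlations are scoped to the OCD group; MASC
(anxiety) to everyone with data.  The generator draws severity scores
independent of connectivity, so correlations should hover near zero.  The
sensitivity modes refit with a depressive-disorder covariate (one fewer
error df) and after excluding subjects older than 18.
"""

from roiconn import (
    SimulationConfig,
    cohort_table,
    run_group_analysis,
    sensitivity,
    severity_correlations,
    simulate_cohort,
)

cohort = cohort_table(simulate_cohort(SimulationConfig(seed=2)))

print("CYBOCS vs the six metrics (OCD group only):")
print(severity_correlations(cohort, "cybocs").round(3).to_string(index=False))
print("\nMASC vs the six metrics (all groups, pairwise deletion):")
print(severity_correlations(cohort, "masc").round(3).to_string(index=False))
print("near-zero r values are expected: severity is generated independent "
      "of connectivity")

primary, _ = run_group_analysis(cohort)
depress, _ = sensitivity(cohort, "add_depress_covariate")
young, _ = sensitivity(cohort, "exclude_over_18")
print(f"\nwithin_CON omnibus p: primary {primary[0].p:.4f} "
      f"(df2={primary[0].df2}), +depress covariate {depress[0].p:.4f} "
      f"(df2={depress[0].df2}), age<=18 only {young[0].p:.4f} "
      f"(df2={young[0].df2})")
print("stable p-values across refits indicate the group effect is not "
      "driven by depression comorbidity or the oldest participants")
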