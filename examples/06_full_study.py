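"""End-to-end simulated severity-correlation study (takes ~1 minute).

Simulates a 21-specimen cohort (5 L / 8 M / 8 H) with the calibrated
grade structure, renders candidate tiles, screens suitability, selects
tiles at random, runs the image pipeline, and reports grade-wise means,
ANOVA and the grading-agreement kappa.
"""

from pulleyquant import CohortConfig, PhantomConfig, PipelineParams, \
    StudyConfig, SuitabilityParams, run_study

cohort = CohortConfig(
    images_per_specimen_candidates=6, images_selected=4,  # desk-scale 49/10
    exact_counts=True,                                    # fixed confusion table
    phantom_template=PhantomConfig(width_px=256, height_px=192,
                                   nucleus_density=6.0),
    seed=1)
config = StudyConfig(
    cohort=cohort,
    pipeline=PipelineParams(suitability=SuitabilityParams(
        min_tissue_fraction=0.5, min_nuclei=12)),
    seed=1)

report = run_study(config)

print("grade-wise means (specimen level):")
print(report.grade_summary[report.grade_summary.grouping
                           == "pathological_grade"].to_string(index=False))
print("\nANOVA:")
print(report.anova[["grouping", "parameter", "f_statistic",
                    "p_value"]].to_string(index=False))
print(f"\ncontingency counts: "
      f"{[list(r) for r in report.contingency.counts]}")
print(f"Cohen's kappa: {report.kappa:.3f} ({report.kappa_category})")
print("\nMonotone grade means and small ANOVA p-values show the pipeline")
print("separating the three severity grades from image content alone.")
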