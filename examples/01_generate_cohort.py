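"""Generate a synthetic endometrial cancer cohort and summarize its counts.

Builds the default three-cohort study (Lynch-associated MMR-deficient n=25,
sporadic MMR-deficient n=33, MMR-proficient n=35, with the matching biopsy/
hysterectomy mix) and prints the per-cohort count summary that the
calibration targets: mean (SE) of the summed 4-ROI counts per marker at the
tumor center (CT) and invasive margin (IM).
"""

import mmrimmune as mi

cohort = mi.generate_cohort(mi.GeneratorConfig(seed=1))
print(f"generated {len(cohort)} tumors:",
      {k.value: v for k, v in cohort.label_counts.items()})

summary = mi.summarize_cohort(cohort)
ct = summary[summary.location == "CT"].pivot(index="marker", columns="cohort", values="mean")
print("\nmean summed tumor-center counts (cells per 4 x 200 um^2 ROIs):")
print(ct.round(0))
print(
    "\nLynch-associated tumors carry the densest infiltrates for most markers;"
    "\nMMR-proficient tumors the sparsest - the gradient the study observed."
)
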