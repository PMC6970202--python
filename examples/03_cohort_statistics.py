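"""Compare immune cell counts across the molecular groups.

Runs the non-parametric battery: Kruskal-Wallis omnibus per marker and
location, Dunn's pairwise post-hoc z tests with Benjamini-Hochberg
adjustment within each marker x location family.
"""

import mmrimmune as mi
from mmrimmune.stats import run_table3

cohort = mi.generate_cohort(mi.GeneratorConfig(seed=1))
table = run_table3(cohort)

overall = table[table.location == "OVERALL"]
print("whole-tumor (CT+IM) comparisons:")
print(overall.pivot(index="marker", columns="comparison", values="p").round(4))
print(
    "\nSmall omnibus p values show the three groups differ for every marker;"
    "\nthe Lynch vs MMR-proficient contrast is the strongest pairwise signal,"
    "\nwhile Lynch vs sporadic-deficient is subtler - visible mostly at the"
    "\ninvasive margin:"
)
im = table[(table.location == "IM") & (table.comparison == "LS_MMRD vs SPORADIC_MMRD")]
print(im[["marker", "p", "adjusted_p"]].round(4).to_string(index=False))
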