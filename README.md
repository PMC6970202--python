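# mmrimmune

Tools for studying the tumor immune microenvironment of endometrial cancer
across mismatch-repair (MMR) states. Around 30% of endometrial cancers are
MMR deficient — most through sporadic *MLH1* promoter hypermethylation, a
minority through Lynch syndrome (an inherited MMR gene variant). Because
MMR deficiency floods the tumor with frameshift neoantigens, these groups
carry very different T-cell infiltrates, with consequences for checkpoint
blockade therapy. `mmrimmune` packages the full analysis workflow for
comparing such cohorts when the data are manual immunohistochemistry (IHC)
cell counts in small regions of interest (ROIs):

- **Data model** — per-tumor counts for five markers (CD3, CD8, CD45RO,
  FoxP3, PD-1) in four 200 µm² ROIs at the tumor center (CT) and invasive
  margin (IM); biopsy specimens have no discernible margin, so IM data is
  *absent*, never zero. Flat CSV I/O with validation.
- **Synthetic cohorts** — a generator whose per-cohort/marker/compartment
  summed counts are moment-matched (rounded lognormal or negative binomial)
  to a packaged calibration table of published means and standard errors,
  with a shared per-tumor latent infiltration factor inducing cross-marker
  correlation.
- **Immune scores** — Immunoscore-style binary (I1:I10) and quaternary
  (Q1:Q10) scores: per-population counts recoded against the pooled median
  (0/1) or quartiles (0–3) and summed over each score's marker×compartment
  panel.
- **Molecular rules** — microsatellite-instability calls from the
  5-mononucleotide-locus panel, *MLH1* methylation from pyrosequencing
  triplicates (>10% at every cytosine in >2/3 of replicates), four-protein
  MMR IHC (>80% expression), PD-L1 positivity, and cohort assignment.
- **Statistics** — Kruskal–Wallis + Dunn post-hoc with Benjamini–Hochberg,
  one-way ANOVA + Tukey HSD, Games–Howell for heteroscedastic designs,
  Levene/Bartlett/Fligner–Killeen screens, Cronbach's α.
- **Classifier harness** — equal-class subsetting (75-obs three-class,
  70-obs two-class), exactly stratified 50/20 splits, cross-validated
  neural-network / linear-SVM / Fisher-discriminant / multinomial-logit
  training, and evaluation with confusion metrics, ROC, rank AUC and the
  Hand–Till multiclass AUC
  `M = 2/(c(c−1)) · Σ_{i<j} [Â(i|j) + Â(j|i)]/2`.

## Worked example

```python
import mmrimmune as mi

cohort = mi.generate_cohort(mi.GeneratorConfig(seed=1))   # 25 + 33 + 35 tumors
design = mi.assemble_design(cohort)                       # raw sums + 20 scores
result = mi.run_experiment(
    design,
    mi.FeatureSet("CD8_CT", ("CD8_CT",)),
    mi.ModelSpec(mi.ModelFamily.FISHER_DISCRIMINANT),
    mode=mi.FeatureMode.TWO_CLASS,
    n_repeats=25,
    seed=9,
)
print(result.summary())
```

prints (among other fields)

```
mean AUC      0.750 (sd 0.116)
mean accuracy 0.650
```

i.e. across 25 balanced-subset train/test repeats, the tumor-center CD8
count alone separates MMR-deficient from MMR-proficient tumors with a mean
rank AUC of 0.75 — well above the chance level of 0.5 — while the same
feature in the three-class problem reaches only ~0.46 accuracy (chance
1/3), because sporadic MMR-deficient tumors overlap both other groups.
The `examples/` directory holds one short narrative script per capability
(generation, scoring, statistics, molecular rules, modeling).

A thin CLI mirrors the library: `mmrimmune generate|score|stats|model|run`
(see `mmrimmune --help`); `mmrimmune run --config cfg.yaml` executes the
whole generate → score → statistics → model pipeline and writes a manifest
with content hashes, reproducible from the master seed.

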