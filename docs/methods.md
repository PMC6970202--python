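# Methods

## The measurement being emulated

Each tumor contributes manual immune cell counts for five markers (CD3,
CD8, CD45RO, FoxP3, PD-1) in four 200 µm² regions of interest (ROIs) at
the tumor center (CT) and — for hysterectomy specimens only — four more at
the invasive margin (IM). The analysis unit throughout is the *summed*
4-ROI count per tumor, marker and compartment; "overall" is CT + IM at the
record level (CT alone for biopsies). A study of 66 hysterectomies and 27
biopsies over 5 markers therefore scores 5 × (8·66 + 4·27) = 3,180 ROIs,
which `expected_roi_count` reproduces.

Missing invasive margins are represented as absent values and propagate as
missingness (scores undefined, model rows dropped and counted); a zero is
always a real observation.

## Synthetic cohort generator

The generator reproduces the study conditions of a three-cohort
endometrial cancer series: Lynch-associated MMR-deficient n=25 (5
biopsies), sporadic MMR-deficient n=33 (12 biopsies), MMR-proficient n=35
(10 biopsies). Its calibration table (packaged CSV) holds, for each of the
30 cohort × marker × compartment cells, the published mean and standard
error of the summed count plus the n used to convert SE to SD.

**SE→SD conversion.** SD = SE·√n with n the number of tumors that can
contribute to the cell: the full cohort for CT cells (25/33/35) and the
hysterectomy count for IM cells (20/21/25). Invasive-margin summaries can
only be computed over tumors that possess a margin, so using the full
cohort n for IM cells would make a cohort-sized simulated IM mean roughly
25% noisier than the printed SE — inconsistent with the calibration the
table is meant to encode.

**Count model.** Default family is a rounded lognormal: from target mean m
and SD s, σ² = log(1+s²/m²), µ = log m − σ²/2, and the draw is
round(exp(µ+σz)) (half-up). The match is exact before rounding and exact
to <0.01% (mean) / <0.1% (SD) after rounding, verified by numerical
integration over the integer support in the test suite. Lognormal was
chosen because such manual counts are right-skewed and non-normal (the
emulated study analyzed them non-parametrically); a negative-binomial
(gamma–Poisson) alternative is available for counts with s² > m, with the
gamma mixing variable coupled through a Gaussian copula.

**Dependence.** A per-tumor latent infiltration factor u ~ N(0,1) enters
every population's log-scale deviate with weight √latent_corr
(z = √ρ·u + √(1−ρ)·ε). ROIs are geographically matched across markers, so
marker counts within a tumor must be positively correlated; the magnitude
is unpublished, and defaults to ρ = 0.7. CT/IM dependence within a marker
arises solely from the same factor. Setting ρ = 0 yields independent
populations.

**ROI split.** The summed count is distributed over the 4 ROIs by a
symmetric multinomial, so ROI counts are non-negative integers summing
exactly to the total. No spatial structure is modeled.

**Labels.** Age, grade, stage and histology are sampled from the emulated
study's frequency table but do not drive counts (no published dependence).
PD-L1 percentage fields and immune-staining patterns are plausible
placeholders — the pattern frequencies are skewed so the MMR-proficient
group contributes most negative results, but no published calibration
exists for them, and no test asserts their distribution.

**Determinism.** One `numpy` Generator seeded from the config; a fixed
seed yields a bit-identical cohort. Specimen counts are fixed at
round(size × biopsy fraction) (matching the emulated specimen table
exactly) with assignment shuffled.

What passing calibration tests show: cohorts whose first two moments and
ordering match the published summaries, with realistic skew and
cross-marker dependence. What they do not show: real spatial ROI
heterogeneity, inter-observer noise, zero-inflation, or any
count–covariate dependence; classifier performance on real data may
differ, and depends materially on the unpublished inter-marker
correlation.

## Immune scores

A score is a set of marker × compartment populations with a resolution.
Per population, tumors' summed counts are recoded against the *pooled*
study population (thresholding per molecular group would make scores
incomparable across groups): binary 0/1 around the median, quaternary 0–3
at the 25/50/75th percentiles. Percentiles use linear interpolation
between order statistics (midpoint median for even n) — conventions
differ across software, so this is fixed and documented. Values equal to
a cut point take the higher code, which guarantees non-empty "high"
groups, makes constant input code 3 (flagged with a warning), and makes
quaternary codes median-consistent with binary ones (code ≥ 2 ⇔ binary 1).
The score is the sum of codes over the panel — the published Immunoscore
construction — so binary scores range over [0,k] and quaternary over
[0,3k] for k populations.

The packaged registry defines I1/I2 from CD3/CD8 (I1 tumor-center only,
I2 both compartments) and extends I3:I10 with CD45RO, PD-1 and FoxP3,
alternating tumor-center-only and both-compartment panels; Qk always has
Ik's panel. The original figure enumerating the panels is not available
in machine-readable form, so the registry is data (CSV) and every
downstream computation treats it as such.

## Statistics battery

Non-parametric route (default): tie-corrected Kruskal–Wallis omnibus,
Dunn's pairwise z tests
(z = (R̄ᵢ−R̄ⱼ)/√[(N(N+1)/12 − T)(1/nᵢ+1/nⱼ)], T = Σ(t³−t)/(12(N−1))),
Benjamini–Hochberg step-up adjustment applied within each marker ×
location family (matching how such tables are presented; configurable in
principle by calling the pieces directly). Parametric route: one-way
ANOVA, Tukey HSD, and Games–Howell (per-pair Welch–Satterthwaite df,
studentized-range reference with k groups) with BH. Heteroscedasticity
screens: Levene with median centering (the Brown–Forsythe variant, chosen
for robustness; the centering is not otherwise determined), Bartlett,
Fligner–Killeen. Cronbach's α = k/(k−1)·(1 − Σ item variances / total
variance) for inter-observer agreement. All p values are two-sided;
routing between routes is an explicit caller flag, never an automatic
normality decision. Degenerate inputs (constant groups, zero total
variance) raise a dedicated error rather than returning a silent number.

Omnibus tests, screens and Tukey delegate to scipy and BH to statsmodels;
Dunn and Games–Howell are implemented here (cross-checked against an
independent implementation in the tests). Monte-Carlo checks note: the
variance screens are asymptotic and conservative at small n, so their
type-I calibration is tested at n=100 per group; Tukey/Games–Howell
per-pair error equals the nominal level only at k=2 (they control
family-wise error for k>2), so their null simulations use two groups.

## Molecular rules

All thresholds are strict inequalities, following the wording of the
underlying laboratory criteria. MSI: ≥4 of 5 mononucleotide loci matching
→ MSS; >2 discrepant → MSI; exactly 2 discrepant satisfies neither
condition and returns INDETERMINATE (a flag switches to the common ≥2 →
MSI criterion). Methylation: a replicate passes if every cytosine is
strictly >10%; methylated iff passing/total > 2/3 as an *exact* fraction,
so 2-of-3 fails — "66%" is read as a colloquial print of 2/3, and the
strict reading is the only self-consistent exact rule (the fraction is
configurable). MMR IHC: proficient iff all four proteins expressed in
>80% of tumor. PD-L1 tumor: positive iff (2+ plus 3+ percent) > 5%;
immune: focal or diffuse staining. Cohort assignment never guesses:
evidence patterns outside the triage flow return UNRESOLVED.

## Classifier harness

Balanced subsetting takes m tumors per class (m = minimum class size):
75 observations for the three molecular classes at 25/33/35, 70 for the
pooled deficient-vs-proficient design. Partitioning is exactly stratified
and errors when the requested sizes cannot stratify exactly; the
three-class default split is (51, 24) — the nearest exactly stratified
analogue of the two-class 50/20 — and experiment runs scale the split to
the nearest per-class integer when missing-margin exclusions shrink the
subset. Train and test sets are asserted disjoint on every repeat.

Model families are scikit-learn estimators behind a uniform scorer
interface: single-hidden-layer MLP (grid over hidden size {4, 8} and
weight decay {1e-4, 1e-1}), linear SVC (grid over C), linear discriminant
analysis, multinomial logistic regression. Hyperparameters are selected
by 5-fold cross-validation *inside the training subset only*. Features
are standardized with training-set statistics for the MLP and SVM, raw
for the discriminant and logit (all overridable). The tuning grids are
deliberately small: the design has 50 training observations.

Evaluation: confusion matrix; sensitivity, specificity, PPV, NPV with
zero-denominator metrics reported as undefined rather than 0; ROC points;
binary AUC as the Mann–Whitney rank statistic (ties count ½); multiclass
AUC by Hand–Till, M = 2/(c(c−1)) Σ_{i<j} ½[Â(i|j)+Â(j|i)], where Â(i|j)
is the rank AUC of the class-i score separating classes i and j on those
observations only — reducing exactly to the binary rank AUC at c=2.

All experiment randomness derives from one master seed via
`numpy.random.SeedSequence` spawning (one child per repeat; derived seeds
stay below 2³¹), so each repeat is independently reproducible.

## Pipeline

`run_pipeline` executes generate → score → statistics → model from a
single config, fanning the master seed out per stage by name
(CRC32-mixed, documented in `stage_seed`), and writes a manifest with a
SHA-256 per artifact and a config hash: identical config + seed ⇒
identical manifest. Warnings, exclusion counts (missing-margin drops) and
stage seeds are logged rather than silently absorbed.

## Problem sizes in the test suite

The suite verifies generator calibration with one 10,000-tumor cohort per
group plus 200 study-sized replicates; type-I error calibration uses
2,000 null replicates per test; the classifier checks use 50
balanced-subset repeats with the (fast, deterministic) discriminant
family. These sizes keep the full suite to a few minutes on one CPU while
leaving Monte-Carlo error well inside the asserted bands — with one
documented exception: for calibration cells whose coefficient of
variation approaches 1, a 10,000-draw empirical mean has a sampling error
of ~1% of the mean, the same order as the asserted band, so that single
simulation assertion can fail by sampling noise alone even though the
underlying moment match is exact (the integration-based oracle test
proves the latter deterministically).

## Known limitations

- The generator models neither spatial ROI structure, observer effects,
  nor covariate-dependent counts; PD-L1 fields are uncalibrated
  placeholders.
- The true cross-marker correlation is unknown; downstream classifier
  metrics shift with `latent_corr`.
- Score-panel memberships beyond I1/I2 and the raw-count feature-set
  enumerations are editable registry data, not ground truth.
- Real-data AUCs cannot be reproduced (patient-level data were never
  deposited); synthetic-cohort behavior is the test surface, and only
  qualitative orderings (e.g. tumor-center CD8 as the best single
  discriminator) are asserted.
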