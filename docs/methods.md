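# Methods

## Marker discovery from a block-level methylation atlas

The atlas is a matrix of beta values (methylation fractions in [0, 1])
over genomic blocks (0-based half-open intervals, BED convention) and
samples, each sample a replicate of one of ~21 anatomical groups
(kidney subcompartments — tubular and glomerular epithelium, podocytes,
peritubular and glomerular endothelium — five blood cell types, and
eleven other organs). Missing betas are `NA` on disk and masked in
memory; a beta of 0 is data, never missingness. Betas are written with
fixed 6-decimal precision so write→read→write is byte-stable.

**Replication filter.** A block is a screening candidate only if it has a
non-missing beta in at least `min_replicates` (default 2) samples of
*every* required group. The filter is idempotent and monotone in
`min_replicates`.

**Specificity screen.** Scoring works on per-(block, group) mean betas.
For a compartment with target group set T, blood set B and non-blood
background set G:

- `target_min_beta` = min over T of group mean;
- `background_max_beta` = max over G (blood is excluded here because it
  has its own stricter criterion — with τ_blood ≤ τ_background the overall
  pass set is identical to folding blood into the background, but the
  failure attribution is cleaner);
- `blood_max_beta` = max over B;
- `margin` = `target_min_beta` − `background_max_beta`.

A block passes iff `target_min_beta ≥ τ_target` (default 0.5),
`background_max_beta ≤ τ_background` (0.15), `blood_max_beta ≤ τ_blood`
(0.05) and `margin ≥ m_min` (0.3). The thresholds are config-exposed;
the defaults encode the assay's physics — probes count *methylated*
copies, so a usable marker must be strongly methylated in its target
compartment and near-zero in blood, the overwhelming background of
plasma cfDNA. Only hypermethylated-in-target markers are panel-eligible;
a direction field is reported for completeness. The ranking statistic is
the margin (worst-case separation), because a single-locus assay is
limited by its worst background tissue, not the average; ties break by
block id. Background specificity is enforced against each group's mean
separately (per-group max), the stricter of the plausible readings.
Group means are the scoring unit; replicates enter only through the mean
and the replication filter.

**Panel assembly.** Top-ranked passing markers are taken per compartment
with quota 1 pan-renal + 6 endothelial + 2 epithelial; a block passing
two screens is assigned to the compartment where its margin is larger
(tie → pan-renal); the albumin internal control is appended and channel
ids are assigned in declaration order. "Pan-renal" is a screen whose
target set is the union of all kidney subcompartment groups.

## Digital-PCR quantification

With k positive of N partitions, p̂ = k/N, λ = −ln(1 − p̂) copies per
partition, copies/reaction = λ·N, copies/µL = λ / v with v the partition
volume in µL. The 95% CI is a Wilson interval on p̂ transformed through
−ln(1 − ·): it behaves at k = 0 (lower bound exactly 0, informative upper
bound) and is monotone, so the bounds bracket the point estimate.
Saturation (k = N) is an error, not +∞ — the sample must be diluted, and
silently returning infinity would poison downstream ratios. Marker
levels are reported as 100 × marker copies / albumin copies; the ratio
may exceed 100% (flagged, not clipped — e.g. amplified loci or copy-number
variation). Per-assay positive counts are the input; fluorescence
declustering of multiplexed channels is upstream wet-lab territory and
is carried as metadata only.

**Controls.** Fully methylated control DNA must show a methylation rate —
operationalised as the ratio to albumin — inside [58%, 98%]; fully
unmethylated control DNA must show at most a configurable false-positive
allowance (default 0 partitions) per marker.

**Reproducibility.** `replicate_sd` reports the per-assay sample SD of
repeated ratio measurements and their mean across assays, in percentage
points. Under counting noise alone (triplicates, N = 20 000, low-copy
markers against an abundant albumin signal) the mean SD is ≈ 0.04
percentage points.

**Input mass and limit of detection.** One haploid genome ≈ 3.3 pg, so
copies = mass_ng × 1000 / 3.3 (0.03 ng ≈ 9.09 copies). Bisulfite
conversion destroys a fraction ℓ of input (historically 0.67–0.80); each
copy independently survives with r = 1 − ℓ and is detected with per-copy
efficiency q, so P(detect) = 1 − (1 − r·q)^n₀ and the expected surviving
copies are n₀·r·q (10 copies at 67% loss → 3.3). The LoD at target
probability π is ⌈ln(1 − π)/ln(1 − r·q)⌉ (14 copies at ℓ = 0.8, π = 0.95),
cross-checked by Monte-Carlo dilution series.

## Diagnostic models

`DiagnosticModel` wraps a maximum-likelihood logistic regression
(statsmodels `Logit`, Newton iterations, parameter-change tolerance
1e-8, max 100 iterations). Marker levels enter as log10(x + δ) with δ
defaulting to half the smallest nonzero level of that marker — cfDNA
levels are right-skewed with true zeros; eGFR enters per-unit with an
additional per-10-unit odds ratio in the summary for readability. Tube
type (EDTA/PAXgene) is carried as a covariate but not in default models.
Quasi-complete separation is flagged when any slope exceeds 15 on the
transformed scale or the fitter reports perfect prediction; flagged fits
suppress their confidence intervals rather than reporting meaningless
ones.

The **univariate screen** fits one single-predictor model per candidate
and reports raw (uncorrected) p-values sorted ascending — deliberately no
multiplicity correction, as conventional for exploratory biomarker
association tables; downstream users should treat the table as
hypothesis-generating. Per-predictor failures (constant predictor,
separation) are recorded in the table, never fatal.

The **epigenetic signature** takes the markers with univariate p < α
(default 0.05) and fits one joint logistic model of those members only;
the signature score is its linear predictor. α = 1 gives the include-all
variant (useful, e.g., under permutation nulls where nothing passes).

**ROC/AUC**: AUC by Mann–Whitney rank statistics with ties counted ½ —
identical to exhaustive pair counting — and the curve by a threshold
sweep over unique scores; the trapezoidal area of the stored curve
equals the rank AUC to 1e-12. AUC is invariant under strictly monotone
score transforms.

**Model comparison** fits, in-sample: eGFR + DSA + signature, eGFR + DSA,
and signature alone; for the any-lesion outcome additionally all-markers
and DSA-only. All reported AUCs are apparent (the models are evaluated on
the data they were fitted to); optional k-fold cross-validation
(`cross_validated_auc`) is provided but off by default, since the
reference presentation this mirrors is in-sample.

## Synthetic data

The generators are pure functions of (spec, seed) and emit truth tables
(YAML) recording every planted parameter.

**Atlas** (`AtlasGenSpec`): 21 groups × 3 replicates; 2000 null blocks
plus 9 planted markers (1 pan-renal, 6 endothelial, 2 epithelial).
Planted blocks draw target-group betas from Beta(50, 2) (mean 0.96),
non-blood background from Beta(2, 50) (mean 0.04), and blood groups from
a stricter Beta(1, 199) (mean 0.005) — real panel markers are *selected
for* blood negativity, so planted truth must be reliably below the 0.05
blood cap; Beta(2, 50) group means would cross it in ~20% of groups and
no deterministic recovery statement could hold. Null blocks share one
per-block Beta (mean uniform on [0.05, 0.95], concentration 52) across
all samples, so they carry no compartment contrast. Missingness is
uniform at rate 0.05 (mild, as in block-level atlas data); recovery
statements are therefore made against planted blocks that *survive* the
replication filter — a block unobservable in ≥ 2 replicates of some group
is not screenable, by design.

**Plate**: positives ~ Binomial(N, 1 − e^(−copies/N)) independently per
assay; control wells on request.

**Cohort** (`CohortGenSpec`): 170 patient-biopsy pairs with exactly 44
rejections (24 ABMR / 13 TCMR / 7 mixed) and biopsy contexts 89
indication / 76 surveillance (34 and 10 of the rejections respectively);
the five remaining records are context-unlabeled, absorbing the
bookkeeping mismatch between the context split and the total. Marker
levels are log-normal (baseline median ≈ 0.32% of albumin, σ_log10 =
0.35 — levels well above single-copy noise yet far below genomic
abundance); rejection multiplies endothelial markers ×3 in ABMR/mixed
(microvascular endothelial injury), the pan-renal marker ×2 in any
rejection, and epithelial markers ×1.5 in TCMR/mixed (tubulitis) — the
endothelial and pan-renal folds chosen so the qualitative findings
(endothelial markers associate with rejection; the combined model
dominates) emerge reproducibly, the epithelial fold deliberately weak.
eGFR is Gaussian (50 vs 40 mL/min/1.73 m², SD 15, floored at 5); DSA is
Bernoulli (60% in ABMR/mixed vs 15% otherwise). 35% of non-rejection
biopsies carry another lesion with a milder ×1.5 marker elevation,
feeding the any-lesion outcome. Optional dPCR counting noise
(off by default) lets tests separate biological from measurement
variance.

With `effect_scope="any_rejection"` and the other-lesion channel off,
every covariate is class-conditionally homogeneous and the implied
logistic slopes have closed forms (Gaussian discriminant: shift/σ² for
log10 markers and eGFR; the log odds ratio of the two rates for DSA),
which the truth table exposes — the oracle for coefficient-recovery
tests. Under the default subtype-dependent effects the case class is a
mixture and no single "true" coefficient exists, so defaults are used
only for ordering/dominance checks.

What the generators do **not** emulate: real methylomes' marginal beta
distributions, inter-block or inter-marker correlation, batch and tube
effects, eGFR's dependence on age/sex, or longitudinal structure.
Passing recovery tests therefore demonstrates the correctness of the
computations under the stated statistical model, not clinical
performance on real cohorts.

## Numerical and design choices

- Problem sizes in tests: atlases of ≤ ~2000 blocks, cohorts of n = 170,
  100-seed Monte-Carlo loops — small enough to run the whole suite in a
  few minutes while keeping Monte-Carlo error well below the asserted
  tolerances.
- Wilson-then-transform CI (rather than a Wald CI on λ): exact behaviour
  at k = 0 and guaranteed bracketing of the point estimate.
- Screen determinism: margin-descending, block-id-ascending ordering;
  results invariant to block and sample permutations.
- The reproducibility statistic fixes N = 20 000 partitions and
  triplicate wells; the replicate count at which the reference value was
  measured is not public, so this choice is pinned and documented here.
- Degenerate inputs: empty atlases round-trip as header-only files;
  all-missing (block, group) cells are flagged missing, never coerced to
  0; saturated dPCR wells and zero-albumin ratios are hard errors.

## Known limitations

- Apparent AUCs overstate out-of-sample performance; the CV option is the
  honest alternative and will read lower.
- The screen treats group means as exchangeable evidence regardless of
  replicate coverage; no shrinkage or coverage weighting is applied.
- The LoD model assumes independent per-copy survival and detection; real
  bisulfite loss may be fragment-length dependent.
- The signature's member selection (univariate p < α) is a simple filter;
  no penalised or stability selection is attempted.
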