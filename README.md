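# nephromark

Non-invasive detection of kidney-allograft injury from plasma cell-free
DNA (cfDNA) methylation. Dying cells shed DNA into plasma carrying the
methylation pattern of their tissue of origin, so a genomic block that is
methylated in kidney cells but unmethylated everywhere else — above all in
blood cells, the dominant cfDNA source — reports kidney injury when its
methylated copies appear in a transplant recipient's plasma.

`nephromark` implements the full analysis chain behind such an assay:

1. **Marker discovery** (`nephromark.atlas`, `nephromark.screen`) — from a
   block-level methylation atlas (beta-value matrix over ~21 anatomical
   groups in triplicate, e.g. a reanalysis of a public whole-genome
   bisulfite atlas), keep blocks observed in ≥ 2 replicates of every
   group, then screen each block for compartment-specific
   hypermethylation: min target-group mean beta ≥ τ_target, every
   non-blood background group ≤ τ_background, every blood group ≤ τ_blood,
   and a worst-case margin ≥ m_min. Passing blocks are ranked by margin
   and assembled into a 10-plex panel (1 pan-renal + 6 renal-endothelial +
   2 renal-epithelial markers + an *ALB* internal control).
2. **Digital-PCR quantification** (`nephromark.dpcr`) — Poisson partition
   statistics: with k of N partitions positive, the mean copies per
   partition is λ = −ln(1 − k/N), copies per reaction λ·N, with a 95% CI
   from a Wilson interval on k/N pushed through the same transform. Marker
   levels are reported as a percentage of albumin copies (genomes).
   Detection-limit arithmetic models bisulfite conversion as binomial
   thinning: P(detect) = 1 − (1 − r·q)^n₀ for n₀ input copies, retention
   r = 1 − loss and per-copy efficiency q; 0.03 ng of gDNA ≈ 9.1 haploid
   genome copies.
3. **Diagnostic modelling** (`nephromark.cohort`) — statsmodels-style
   `DiagnosticModel.fit() → DiagnosticResults` logistic regression of
   biopsy outcomes (rejection; any histological lesion) on eGFR, DSA and
   log10 marker levels; a univariate odds-ratio screen; an *epigenetic
   signature* (a logistic score over the markers univariately associated
   with the outcome); ROC curves with Mann–Whitney AUC; and the standard
   in-sample comparison combined vs clinical-only vs signature-only.
4. **Synthetic data** (`nephromark.synthetic`) — seeded generators for all
   three inputs with emitted truth tables, so every stage can be tested by
   planted-truth recovery.

## Worked example

```python
from nephromark.synthetic import CohortGenSpec, gen_cohort
from nephromark.cohort import compare_models, fit_logistic
from nephromark.screen import DEFAULT_PANEL

df, truth = gen_cohort(CohortGenSpec(seed=1))   # 170 biopsies, 44 rejections
res = fit_logistic(df, "rejection", predictors=("egfr", "dsa"),
                   marker_predictors=("LOC124903692",))
print(res.summary())
```

```
Diagnostic logistic model: outcome = rejection
n = 170, log-likelihood = -74.887, converged = True
                       coef      se  odds_ratio  or_ci95_low  or_ci95_high  p_value
const                 2.022  0.7163       7.553        1.855         30.75 0.004759
egfr               -0.06626 0.01515      0.9359       0.9085        0.9641 1.23e-05
dsa                   1.061  0.4683       2.889        1.154         7.235  0.02349
log10_LOC124903692    1.434  0.5651       4.194        1.386          12.7  0.01118
eGFR odds ratio per 10 mL/min/1.73m2: 0.516
```

Each unit of eGFR lowers the rejection odds (OR 0.94 per mL/min/1.73 m²),
DSA positivity nearly triples them, and a ten-fold rise of the
endothelial marker multiplies them by ~4.2 — lower kidney function,
donor-specific antibodies and circulating methylated endothelial DNA each
independently signal rejection in this synthetic cohort.

```python
comp = compare_models(df, "rejection", DEFAULT_PANEL.marker_names)
print(comp.table().to_string(index=False))
```

```
             model      auc
egfr_dsa_signature 0.884380
          egfr_dsa 0.789592
         signature 0.830087
```

Adding the epigenetic signature to the clinical predictors raises the
apparent AUC from 0.79 to 0.88: the methylation markers carry diagnostic
information beyond eGFR and DSA.

A CLI mirrors the library
(`nephromark all --seed 1 --out runs/demo` chains
simulate-atlas → screen → simulate-cohort → diagnose).

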