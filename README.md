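# ihc-autoscore

Fully automated PTEN immunohistochemistry (IHC) scoring on whole-slide
images of prostate tissue, together with the survival statistics needed to
evaluate the score — alone and combined with DNA ploidy status — as a
prognostic biomarker for biochemical recurrence (BCR) after radical
prostatectomy.

It is aimed at computational-pathology and biostatistics users who want an
exercisable, end-to-end reimplementation of this kind of scoring pipeline:
every stage runs on synthetic slides and simulated cohorts generated by the
package itself, with exact per-cell ground truth, so the whole chain is
testable on a single CPU without access to clinical images or patient data.

## The method

**Scoring pipeline.** Each slide (RGB raster at 0.227 µm/pixel) is
partitioned into non-overlapping 800 × 800 pixel tiles; right/bottom
remainders are dropped. A tile is a *tumor tile* iff its center point lies
inside (boundary included) a tumor annotation polygon — or, at inference
time, iff a tile classifier's tumor probability reaches the decision
threshold (default 0.5). Cells in tumor tiles are detected, segmented and
classified into four classes: tumor/non-tumor × PTEN-positive (DAB staining
present) / PTEN-negative (staining absent). The slide score is

```
score = n(tumor, PTEN+) / [ n(tumor, PTEN+) + n(tumor, PTEN−) ]
```

— non-tumor cells never enter the ratio, and a slide with no tumor cells
has an *undefined* score. A patient's score is the unweighted mean of their
defined slide scores; patients are **PTEN-low** when the score is strictly
below 50%. Ploidy dichotomizes as non-diploid = {tetraploid, aneuploid};
the combined marker counts adverse statuses (0/1/2). CAPRA-S integration
adds 1 point for PTEN-low and 1 for non-diploid; risk groups are Low (0–2),
Intermediate (3–5), High (≥ 6).

**Endpoint and statistics.** BCR is a single post-operative PSA
≥ 0.4 ng/mL; time to BCR runs from surgery to the first such measurement or
is censored at the last PSA registration. The package implements
Kaplan–Meier curves, the Mantel–Cox log-rank test, Cox proportional-hazards
fits (Efron ties, Wald inference, categorical covariates with a reference
level), Harrell's c-index, ROC AUC and Pearson r. Interval estimates for
c-index and AUC are bias-corrected and accelerated (BCa) bootstrap
percentile intervals (default 10,000 resamples, patients as the resampling
unit). Two c-indices on the same patients are compared by a paired
bootstrap whose two-sided p-value is 1 minus the confidence level of the
largest BCa interval that still excludes 0.

**Backends.** The tumor-tile classifier and the cell detector are
pluggable, sklearn-style estimators. The bundled reference backends are
classical and deterministic: stain-channel statistics + logistic regression
for tiles, and color deconvolution → calibrated thresholding → watershed →
per-instance classification for cells. CNN backends can stand behind the
same `fit`/`detect` contracts.

## Worked example

Score forty single-slide synthetic patients end to end with the oracle
detector and run the survival analyses:

```python
import ihc_autoscore as ia
from ihc_autoscore.pipeline import RunConfig, SlideRecord, run_pipeline

cohort = ia.generate_cohort(ia.CohortParams(n_patients=40, seed=11,
                                            prevalence_pten_low=0.4))
records = []
for i, row in enumerate(cohort.itertuples()):
    image, gt = ia.generate_slide(ia.SlideSpec(
        width_px=1600, height_px=1600, seed=100 + i,
        positive_fraction=float(row.pten_score_true),
        tumor_cell_density=80.0))
    records.append(SlideRecord(f"{row.patient_id}-0", row.patient_id,
                               image, gt))
out = run_pipeline(records, cohort, RunConfig(seed=7, n_bootstraps=2000))
print(out["patient_markers"].head(4))
print(out["statistics"]["pten"])
```

The marker table couples each patient's computed score with the
dichotomies:

```
patient_id    score pten_status    ploidy     combined  capra_s_integrated
     P0000 0.114943    PTEN-low aneuploid both-adverse                   8
     P0001 0.630952   PTEN-high aneuploid  one-adverse                   3
     P0002      NaN        None   diploid         None                   3
     P0003 0.156250    PTEN-low   diploid  one-adverse                   7
```

(`P0002`'s only slide landed no tumor tile, so its score is undefined and
its status missing.) The PTEN analysis block reports the univariable Cox
hazard ratio of PTEN-low vs PTEN-high for time to BCR, the log-rank test,
and Harrell's c-index with its BCa interval:

```
hr        4.352   (95% CI 1.717 – 11.032)
logrank   chi2 11.444, p 0.000717
cindex    0.698   (95% BCa CI 0.589 – 0.785)
```

With this simulated cohort (planted PTEN-low hazard ratio 3.32, n = 40) the
estimate is noisy but covers the planted effect; at n = 2000 the fit
recovers it closely. The `auto_vs_manual` block compares the pipeline's
scores with the cohort's emulated manual consensus scores (AUC against the
50%-dichotomized manual score, Pearson r), and the `capra_s` block reports
the c-index difference test for CAPRA-S with vs without the added marker
points.

The same pipeline is scriptable from a shell:

```bash
ihc-autoscore synth-cohort --params params.json --seed 5 --out cohort.csv
ihc-autoscore synth-slide  --spec spec.json --seed 3 --out slides/s0
ihc-autoscore run  --manifest manifest.csv --cohort cohort.csv --out results/
ihc-autoscore stats --cohort cohort.csv --out stats.json
```

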