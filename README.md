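# ebqspine

Cervical **Endplate Bone Quality (EBQ)** scoring and cage-subsidence
analysis for anterior cervical discectomy and fusion (ACDF) research.

Cage subsidence — the interbody cage sinking into the adjacent vertebral
endplates after ACDF — is strongly driven by the quality of the subchondral
bone supporting the cage. The EBQ score measures that bone directly on a
routine preoperative mid-sagittal T1-weighted MRI slice:

```
EBQ = ((SI_upper_endplate + SI_lower_endplate) / 2) / SI_CSF
```

where `SI_upper_endplate` and `SI_lower_endplate` are the mean signal
intensities of the 3-mm-deep subchondral bands adjacent to the two
endplates bounding the operated disc space, and `SI_CSF` is the mean signal
of a cerebrospinal-fluid reference region at the T1 vertebral station. On
T1-weighted images marrow fat is bright and dense bone dark, so **higher
EBQ means fattier, mechanically weaker subchondral bone** and a higher
subsidence risk.

The package provides the full measurement and analysis pipeline for
researchers who want to apply, validate, or simulate this workflow:

- `ebqspine.phantom` — synthetic mid-sagittal phantoms with exact
  ground-truth geometry, tissue intensities, and optional Schmorl-node
  lesions: an oracle for the EBQ estimator.
- `ebqspine.ebq` — band extraction from endplate polylines (exact
  point-to-segment geometry, pixel-centre rasterization), exclusion-aware
  ROI means, the EBQ score, and the two-reader-plus-arbiter reconciliation
  rule (discrepancy threshold 2.0 EBQ units).
- `ebqspine.subsidence` — segmental height from radiograph landmarks and
  the subsidence rule: height loss strictly exceeding 2 mm, or cage
  migration.
- `ebqspine.cohort` — a cohort simulator calibrated to the two-group
  moments of the motivating 158-patient ACDF cohort (subsidence prevalence
  23/158, group EBQ means 4.13 / 5.38, T-score means −0.84 / −1.62,
  EBQ–height-loss correlation 0.798).
- `ebqspine.stats` — the inference chain: Shapiro-gated t / Mann–Whitney /
  chi-square group comparisons with t-based 95% CIs, Pearson correlation,
  ROC with rank-based AUC, DeLong CI and Youden-index cutoff, and IRLS
  logistic regression with Wald odds ratios.
- `ebqspine.io` / `ebqspine.cli` — PNG/TIFF/NIfTI images, annotation JSON,
  cohort CSV, deterministic result writers, and an umbrella `ebqspine`
  command (`simulate-phantom`, `simulate-cohort`, `measure`, `reconcile`,
  `subside`, `analyze`, `end-to-end`).

## Worked example

```python
from ebqspine import (PhantomConfig, generate_phantom, measure_phantom,
                      CohortConfig, simulate_cohort)
from ebqspine.stats import analyze_cohort

# a noisy phantom whose configured band/CSF ratio is 170/40 = 4.25
img, gt = generate_phantom(PhantomConfig(noise_sd=5.0, seed=7))
for m in measure_phantom(img, gt):
    print(m.level, m.ebq_display)

# a simulated 158-patient cohort at the reference moments
cohort, _ = simulate_cohort(CohortConfig(), seed=7)
res = analyze_cohort(cohort)
print(res["roc"].auc, res["roc"].cutoff, res["correlation"].r)
```

prints (exactly, for these seeds):

```
C3/4 4.25
C4/5 4.25
C5/6 4.25
C6/7 4.25
0.7165217391304348 4.4288... 0.7282...
```

The phantom recovers its configured EBQ of 4.25 at every level despite the
noise (the bands average 480 pixels each). The simulated cohort shows the
qualitative picture the measurement is designed for: subsided patients have
a higher mean EBQ (4.95 vs 4.16 in this draw), EBQ discriminates subsidence
well above chance (AUC 0.72 with a Youden-optimal cutoff of 4.43 for this
seed), and preoperative EBQ correlates strongly with subsequent segmental
height loss (r = 0.73). Any single n = 158 draw scatters around the
calibrated population values; the test suite checks the calibration itself
over hundreds of replicates.

Or from the shell:

```
ebqspine end-to-end --seed 1 --out run/
cat run/report.md
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline from scratch: it generates a phantom, measures its EBQ
against the ground truth, simulates a 158-patient cohort at the reference
moments, runs the full analysis chain (group comparison, ROC, correlation,
logistic model), logs a one-line summary of each stage to stderr, and
writes the summary JSON to `--out`. All randomness derives from `--seed`.

## Methods

See `docs/methods.md` for the model, calibration details, numerical
conventions, and known limitations.
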