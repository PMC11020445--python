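# Methods

This note documents the science and the numerical conventions implemented
in `ebqspine`: what is modelled, how the synthetic data are calibrated,
which choices were genuinely open, and what a green test does and does not
establish.

## The EBQ measurement

The endplate bone quality score of an operated cervical disc level is

```
EBQ = ((SI_u + SI_l) / 2) / SI_csf
```

with `SI_u`, `SI_l` the mean T1-weighted signal intensities of the two
subchondral bands — the strips of bone within 3 mm of the endplates
bounding the disc space — and `SI_csf` the mean signal of an annotated CSF
polygon at the T1 vertebral station. The numerator averages the two
*per-band means* with equal weight, not a pooled pixel mean; the two differ
when the band areas differ, and a pooled variant is available behind a
non-default flag.

Because EBQ is a ratio of means on the same image, it is exactly invariant
under global intensity rescaling. It is **not** invariant under additive
intensity offsets; this is a property of the score itself, not an artifact,
and is covered by a dedicated test.

### Band geometry

All annotations live in continuous mm coordinates; pixel `(i, j)` has its
centre at `((j+0.5)s, (i+0.5)s)` for spacing `s`, and a pixel belongs to a
region iff its centre passes the test. A pixel is in an endplate band iff
its centre:

1. lies strictly within `depth_mm` of the endplate polyline (exact
   point-to-segment Euclidean distance; no distance-transform
   approximation — the bands are small and exactness is cheap);
2. projects orthogonally onto the polyline. Points past the free ends
   (which would form rounded end caps) are excluded: the band is the strip
   *under* the endplate span, matching the anatomical subchondral region.
   Interior joints of a curved polyline keep their wedge regions via the
   nearest-vertex rule;
3. sits on the same side of the polyline as the `body_side_hint`, decided
   by the sign of the 2-D cross product against the nearest segment.
   Pixels exactly on the polyline belong to neither side.

The strict inequality in (1) makes the degenerate case unambiguous: a
polyline lying on a pixel boundary with `depth` equal to the half-spacing
yields an empty band (and an explicit error) rather than a
rounding-dependent sliver.

Schmorl nodes are excluded by annotation (a polygon subtracted from the
band masks), never by automatic detection — exclusion is a reader decision
in practice.

### Rater reconciliation

Two primary readers measure each level; if their EBQ values differ by more
than 2.0 the arbiter's confirmatory re-measurement is adopted, otherwise
the final score is the mean of the two. The threshold is interpreted in
EBQ units (the natural reading of a bare "threshold of 2" for a score with
values around 4–5) and is configurable.

## The phantom

The phantom is a geometry oracle, not an MRI simulation. It rasterizes a
column of rectangular vertebral bodies separated by 2-mm disc gaps, a
posterior CSF column, and subchondral bands of the configured depth,
painting each tissue class from the *same annotations stored in the ground
truth*. Consequently, with all standard deviations at zero, the measured
EBQ equals `tissue_means[endplate_band] / tissue_means[csf]` to machine
precision — the estimator and the generator cannot drift apart silently.

Deliberate simplifications, and what they imply:

- **Noise** is additive Gaussian, clipped at zero — not Rician. Adequate
  for validating a ratio of means at SNRs where clipping is negligible; a
  green noise test says nothing about low-SNR Rician bias.
- **Endplates** are straight by default, with an optional sinusoidal
  curvature amplitude (the mask oracle is exercised on both). Real
  endplate shapes, partial-volume effects, and bias fields are not
  emulated.
- **Default spacing** is 0.5 mm/px so the 3-mm band is 6 pixel rows deep:
  coarse enough for fast tests, fine enough for geometry checks.
- Default tissue means (band 170, CSF 40, marrow 140, disc 60, background
  5) put the true EBQ at 4.25, mid-range for the clinical score.
- Lesion pixels from `inject_schmorl` take the lesion intensity exactly
  (no added noise), so exclusion tests are sharp; the recorded exclusion
  polygon is a circumscribed 64-gon that covers every lesion pixel at the
  cost of a sliver of over-exclusion, which is harmless for a mean.

## Subsidence

Segmental height is the Euclidean distance between the superior-endplate
midpoint of the upper vertebra and the inferior-endplate midpoint of the
lower vertebra, in calibrated mm. Subsidence is a loss strictly exceeding
2 mm between the week-1 postoperative film and the final follow-up
("exceeding" ⇒ a loss of exactly 2.0 mm is not subsidence), or
reader-adjudicated cage migration regardless of the height change.
Negative losses (apparent height gain under measurement noise) are retained
unclamped so they flow into means and CIs.

## The cohort simulator

Per patient the generator draws demographics (age 54.15 ± 9.36 y, BMI
23.56 ± 2.76, 55% male, 15% smokers, level frequencies 13/25/99/20 across
C3/4–C6/7), an EBQ ~ N(4.31, 1.15²) (optionally shifted per level), and
then three structurally linked quantities:

- **T-score** = `a_t + b_t·EBQ + ε_t` with negative slope — more marrow
  fat, less mineral density;
- **subsidence** ~ Bernoulli(expit(`c0 + c1·EBQ + c2·T-score`)) with
  `c2 = −0.4` (denser bone protects);
- **height loss** = `a_h + b_h·EBQ + ε_h`, with the preoperative segmental
  height ~ N(38, 3²) mm (a typical fused-segment span; the source cohort
  does not publish this moment) and the final height derived by
  subtraction. Migration is drawn with probability 0.2 given subsidence
  (the migration split is likewise unpublished; migration-only subsidence
  is assumed the minority mode).

**Calibration.** The defaults are solved once from the reference cohort's
published two-group moments, not hand-tuned:

- The height-loss model is closed-form: the marginal loss mean is fixed at
  1.31 mm, the marginal exceedance `P(loss > 2 mm)` at the prevalence
  23/158 (these two pin the marginal loss SD at 0.654 mm — consistent with
  the observed 1.31 ± 0.66), and the EBQ–loss correlation at 0.798. A
  pleasant consequence: the 2-mm classification rule applied to the
  simulated heights reproduces the configured prevalence by construction.
- The outcome intercept, the outcome EBQ coefficient, and the T-score
  slope are solved jointly by Gauss–Hermite quadrature so that the model's
  prevalence is 23/158, the subsided-group EBQ mean is 5.38, and the
  subsided-group T-score mean is −1.62, with the marginal T-score held at
  −0.95 ± 1.40. Joint solving matters: the logistic outcome tilts the
  T-score *residual* within the subsided group, which a closed-form moment
  match misses by ≈ 0.35 SD.

What the simulator does **not** reproduce: the published group-specific
SDs of EBQ (1.14 vs 0.47) and of height loss, and the published
group-conditional loss means (1.05 / 2.82 mm). A single-normal EBQ
population selected through a logistic link cannot produce a subsided
group three times tighter than the non-subsided group, and the published
group-loss CIs are not reproducible from their own printed summary
statistics under either t or z conventions. The simulator therefore
matches prevalence, group means, marginal moments and the correlation —
the quantities the downstream estimators are validated against — and
treats the group SD structure as unattainable from the published record.
Tests accordingly assert calibrated group *means* (over ≥ 200 replicates,
at n = 2000 where the small-sample ratio bias of a group mean is
negligible), never group SDs.

## Statistics

- **CIs for means** use the t quantile with `n − 1` df:
  `mean ± t·sd/√n`. This convention was identified by reverse-engineering
  the reference tables' printed bounds, which a z quantile does not
  reproduce.
- **Group comparisons** gate on Shapiro–Wilk (α = 0.05 per group): both
  normal → pooled-variance Student t (Welch behind a flag); otherwise
  Mann–Whitney U with the tie-corrected normal approximation and no
  continuity correction (the large-sample convention of mainstream
  clinical software). Categorical variables use Pearson chi-square without
  Yates correction. No multiplicity adjustment is applied, matching the
  descriptive-table practice the chain reproduces.
- **ROC**: thresholds at midpoints between consecutive distinct scores
  plus ∓∞ sentinels; positive call at `score ≥ threshold` (higher EBQ
  predicts subsidence). AUC is the rank statistic `U/(n₀n₁)` with ties
  counted ½ — exactly the Mann–Whitney U equivalence, which the tests
  verify against an O(n²) pair-count oracle. The AUC CI is DeLong's via
  midrank placements. The cutoff maximizes Youden's J; J ties break toward
  higher specificity (the conservative operating point), then toward the
  lower threshold. With midpoint thresholds a J-and-specificity tie forces
  an identical (sens, spec) pair, so the last tie-break is a safety net.
- **Logistic regression**: IRLS to the maximum likelihood, converged when
  the max absolute score drops below 1e-8 (cap 100 iterations); Wald SEs
  from the inverse observed information; `OR = exp(B)` with
  `exp(B ± 1.96·se)` CIs. Rank-deficient designs fail with the collinear
  columns named. Separation is flagged when the fit fails to converge with
  `max|B| > 15`; a transient excursion beyond 15 during iteration is not
  separation (true intercepts near −14 occur in legitimate rare-event
  models and must fit cleanly).

## Determinism

Every stochastic artifact is driven by one integer seed through a single
`numpy` Generator with a fixed draw order; identical config + seed gives
bit-identical images and tables. The result writers use sorted JSON keys
and a fixed float format, so repeated analyses of the same CSV are
byte-identical. Display rounding (2 dp for EBQ, 3 dp for ORs) happens only
in the human-readable report; all machine outputs keep full precision.

## Known limitations

- The CSF reference is whatever polygon is annotated; the package does not
  verify its anatomical station.
- 2-D only: mid-sagittal slice selection from a volume, 3-D ROIs, and
  DICOM handling are out of scope.
- The phantom validates geometry and estimator statistics, not MRI
  physics; transferring EBQ thresholds across scanners or sequences
  remains an open clinical question the package cannot settle.
- The published operating point (AUC, cutoff, sensitivity/specificity)
  and fitted odds ratios of the motivating study depend on its
  patient-level data and are reproduced only qualitatively by the
  calibrated simulator, never asserted numerically.
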