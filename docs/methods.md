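# Methods

This note records the models, defaults, numerical choices and limitations of
`metabotime`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and design

The unit of analysis is a strictly positive feature × sample intensity
matrix paired with a design mapping each sample to
(condition ∈ {untreated, treated}, time in hours, replicate). Both
conditions must share an identical, strictly increasing time axis, every
(condition, timepoint) cell needs ≥ 2 replicates, and each replicate id must
appear at every timepoint so that replicate *profiles* (k-vectors over the
time axis) are well defined. Raw tables must be complete: how non-detections
were coded upstream is generally unknown, so the default is strict failure,
with an explicit opt-in (`impute_missing`) that floors blank/zero cells at
half the smallest positive value of the same feature.

## Synthetic data generator

The generator emulates a two-condition, triplicate, five-timepoint
({3, 12, 18, 24, 48} h) untargeted LC-MS study with 125 (or 124) features.

* **Noise model.** Log-normal intensities: a per-feature baseline log-mean is
  drawn once (`baseline_log_mean` 8.0, between-feature spread 1.5 natural-log
  units, giving a few orders of magnitude of dynamic range — real metabolome
  abundances span far more, but only relative structure matters here), then
  per-cell replicate noise `baseline_log_sd` 0.35 (≈ 36 % CV, typical of
  biological replicates in LC-MS). A fraction `outlier_fraction` = 0.02 of
  cells is multiplied by `outlier_scale` = 10, reproducing the narrow-peaked,
  long-tailed marginal shape of real intensity data; kurtosis of the pooled
  log-intensities strictly increases with the contamination fraction.
* **Effect archetypes**, planted on the log scale in treated samples only,
  with `effect_size` in units of `baseline_log_sd`: `early` (first timepoint
  only), `late` (last timepoint only), `constant_shift` (all timepoints), and
  `absent_in_treated`, which replaces the treated intensity by a jittered
  `baseline × 10⁻⁶` floor at all timepoints — "total absence" of a compound
  consumed under treatment, kept positive so power-transforms stay defined.
* **Study-mimic default** (`study_mimic_config`): 16 differential features
  cycled through (early, late, absent) — the three temporal response patterns
  of the emulated study — at 3 σ, on evenly spaced feature indices, seed 42.
* **Determinism.** Output is a pure function of the configuration, seed
  included; column order is fixed (condition-major, then timepoint, then
  replicate) so files reproduce byte-for-byte.

What the generator does **not** emulate: m/z or retention-time structure,
isotope patterns, missingness mechanisms beyond the absent archetype,
correlated features (each feature is independent), or batch effects. Tests
passing on this generator therefore demonstrate the statistical machinery
under its stated noise model, not performance on any particular instrument's
quirks.

## Normalization

One transform is fitted per dataset on the pooled vector of all matrix cells
and applied elementwise (per-feature fitting is behind a flag): differential
statistics downstream compare features to each other, and a single monotone
map keeps those comparisons on one scale while removing the leverage of the
raw intensity tails.

* **Box-Cox**: y = (x^λ − 1)/λ (log at λ = 0), λ by profile maximum
  likelihood searched on [−2, 2] to 10⁻⁵. The shift is 0 for positive data,
  else −min + 10⁻⁶·range (defensive; raw intensities should be positive).
* **Ordered Quantile (ORQ)**: ranks (ties averaged) mapped to normal
  quantiles at r/(n+1) — the offset avoids infinite scores at the extremes.
  Out-of-sample values are transformed by linear interpolation on the fitted
  (value, score) reference, with linear extrapolation past the ends.
* **Auto-selection**: Pearson χ² / df against the normal in ⌈√n⌉ equiprobable
  bins, estimated by 5 × 10-fold cross-validation with folds shared across
  candidates, smallest mean wins, ties broken by the fixed candidate order
  (identity, log, boxcox, orq). The statistic must be out-of-sample: ORQ
  maps any tie-free training sample onto deterministic, essentially perfect
  normal scores, so an in-sample criterion would select it unconditionally;
  out of sample its tail extrapolation costs it against a well-matched
  parametric transform. Candidates whose domain a dataset violates (e.g. log
  on non-positive values, any transform on constant input) are skipped with
  a note; if all are skipped the selector raises.

Normalization happens once, before both statistics; both therefore see the
same scale.

## Moderated Hotelling T²

Summaries per feature: d = treated − untreated mean profile; S = pooled
within-condition covariance of replicate profiles, f = n₁ + n₂ − 2. With
k = 5 > f = 4 the per-feature S is always singular — the reason the
classical statistic is unusable at this design and moderation is essential,
not cosmetic.

* Λ̂ = across-feature average of S (keeps the average temporal correlation;
  positive-definiteness enforced with a single ridge repair of
  10⁻⁸·tr(Λ)/k before failing).
* ν̂ by method of moments on the diagonals: under a scaled-inverse-χ²(ν)
  prior, s/λ ~ F(f, ν) with squared CV c = 2(f + ν − 2)/(f(ν − 4));
  inverting the observed c gives ν̂ = (4cf + 2f − 4)/(cf − 2), capped at 10⁶
  when the observed dispersion is within pure χ²_f sampling noise (the
  ν → ∞ limit) and floored at k + 1 so S̃ is always positive definite. The
  diagonal-only estimator is deliberate: at F ≈ 125 features a full
  matrix-variate moment fit is noisier than it is worth.
* T̃² = (n₁n₂/(n₁+n₂)) dᵀS̃⁻¹d via Cholesky solve, never an explicit inverse.
  ν = 0 recovers the textbook two-sample Hotelling T² exactly (tested against
  a brute-force oracle); ν → ∞ gives the fixed-metric distance dᵀΛ⁻¹d.
* Selection: dense ranking by T̃², top ⌈fraction·F⌉ with boundary ties
  included — the inclusive ceiling is the documented reading of "top 10 %"
  (13 of 125); remaining ties break by input feature order.

Scale behaviour: with ν = 0 the statistic is scale-equivariant per feature;
with ν > 0, multiplying one feature's values by c > 1 *increases* its T̃²
because the fixed Λ shrinks relative to the scaled feature covariance — one
more reason normalization precedes testing.

## PCA distance test, Rayleigh null

Difference profiles are centered across features; loadings are the top-q
right singular vectors (deterministic sign: largest-magnitude element
positive). Distances are Euclidean norms of the centered projections in the
retained subspace. Defaults and their rationale:

* **q = 2**: the Rayleigh distribution is exactly the norm of a 2-D isotropic
  Gaussian — the only dimension at which this null is coherent. For other q
  the correct null is a chi distribution with q degrees of freedom
  (`--null chi`); fitting a Rayleigh to q = 5 null data is visibly wrong in
  the always-reported KS diagnostic (several-fold larger statistic than at
  q = 2 in the seeded tests).
* **Scale**: Rayleigh MLE σ̂ = √(Σd²/2N) on *all* features, responders
  included — a single-pass procedure with no iterative trimming. True effects
  therefore inflate σ̂ and make the test conservative; the test still ranks
  large sustained effects strictly above nulls (seeded check), and an
  optional robust refit excluding current rejections exists behind a flag,
  off by default.
* **Threshold**: p = exp(−d²/2σ̂²) < 10⁻⁴, strictly — the boundary value is
  not significant. No multiple-testing correction is applied; the fixed
  conservative α plays that role by design, and on a 10⁴-feature isotropic
  null the test admits ≲ a handful of rejections with uniform p-values.

## Consensus and heat map

`combine_selections` always computes both Venn sets over the input feature
order: the **consensus** flag is the intersection (what both approaches
agree on — the only null-safe notion, since the top-decile ranking returns
⌈0.1·F⌉ features even on pure-null data), while the **combined** list that
feeds the heat map defaults to the union (the final displayed set is
naturally larger than either single approach's ~13). Heat-map rows are the
selected features in matrix order (the deterministic tie-break), per-row
z-scaled (constant rows map to zero), clustered with Euclidean distance and
complete linkage; columns stay in design order. Rendering is optional so the
pipeline runs headless; the leaf order is always written as text.

Every run writes a manifest with all tunable flags, the generator seed and
library versions, and no timestamps — two runs from one configuration are
byte-identical.

## Detection boundary and known limitations

At triplicate scale a 3 σ effect confined to a single timepoint of five sits
near the information-theoretic boundary of this design: the expected
mean-profile difference at the affected timepoint (≈ 0.68 normalized units)
competes with the upper tail of ~110 null features' T̃² scores and with
outlier-induced single-coordinate spikes of comparable size, which the
feature's own inflated covariance only partially discounts. On the packaged
study-mimic conditions the union selection typically recovers 9–12 of the 16
planted responders with ~1–4 false positives (the acceptance script reports
the exact numbers for its seed); the vanished-compound archetype is
recovered essentially always, single-timepoint archetypes are the marginal
cases. Sustained (constant-shift) effects of the same size are comfortably
detected. Users designing real studies should read this as: with n = 3,
profile-level inference is reliable for sustained or drastic changes and
only suggestive for one-timepoint excursions of moderate size.

Other limitations: no batch correction, no correlated-feature structure in
the generator, dataset-level normalization cannot remove within-feature
outliers, and the distance test's null is fitted in-sample over contaminated
data (conservative by construction).

## Problem sizes in tests

The test suite and acceptance script run the full 125 × 30 mimic pipeline,
10⁵-draw scale recovery, a 10⁴-feature null calibration, and 2 000-point
normalization recoveries; everything completes in well under a minute on one
CPU.
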