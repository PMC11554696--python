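# Methods

## Constitutive model and its uniaxial reduction

Ocular tissue is modelled as hyperelastic, homogeneous, isotropic, and
incompressible, with the reduced-polynomial strain-energy density

U = Σᵢ₌₁ᴺ C_i0 (Ī₁ − 3)ⁱ + Σᵢ₌₁ᴺ (1/D_i)(J_el − 1)²ⁱ.

Order 1 is neo-Hookean; this package supports order selection over
N ∈ {1, 2}, with order 2 the working default for ocular tissue.  Tensile
data are reduced under full incompressibility: the transverse stretches are
λ^(−1/2), J_el ≡ 1, the volumetric series drops out of the stress, and the
nominal (engineering) stress is T(λ) = 2(λ − λ⁻²) Σ i C_i0 (Ī₁ − 3)^(i−1)
with Ī₁ = λ² + 2/λ.  The volumetric coefficient is *derived afterwards*
from an assumed near-incompressible Poisson ratio (ν = 0.49, the standard
assumption for eye tissue) through the small-strain identities μ₀ = 2C₁₀,
K₀ = 2/D₁: D₁ = 3(1 − 2ν)/(2C₁₀(1 + ν)), and D_i = 0 for i ≥ 2.  This is
the only convention under which a slightly-compressible parameter table
(C₁₀, C₂₀, D₁, 0) follows consistently from an incompressible curve fit,
and it reproduces the published glaucomatous parameter table's D₁ values
from its C₁₀ values to better than 2%.

Engineering stress and strain are used throughout (force over undeformed
area, elongation over undeformed clamp-to-clamp gauge length); there is no
true-stress option in the core.  Material stability is checked in the
Drucker sense restricted to uniaxial tension: the analytic tangent
dT/dε = 2(1 + 2λ⁻³)g + 4(λ − λ⁻²)²g′, g(x) = Σ i C_i0 x^(i−1), must be
positive on a strain grid of step 10⁻³ over the range of interest (fine
enough to resolve any sign change at the scale of these curves).

## Preprocessing

The chain mirrors the bench protocol: preload re-referencing, removal of
five 5%-strain preconditioning cycles, conversion to stress–strain, and
truncation at the ultimate stress.

* **Preload zeroing.**  The 0.05 N preload eliminates slack; the first
  upward force crossing of the preload defines displacement zero and the
  gauge length.  Detection is noise-adaptive: the trace's force-noise SD is
  estimated robustly from successive differences over the trace head, the
  force is smoothed accordingly, and the crossing is interpolated at the
  last sub-preload sample before clear engagement.  When the noise is of
  the order of the preload itself (for the stiffest regions the default
  synthetic noise is tenfold the preload) the crossing is unidentifiable,
  and the routine instead extrapolates the first clean engaged band
  linearly back to the preload level — slightly late on a convex toe
  (≈1% strain) but consistent across specimens, which is what matters for
  downstream statistics.  Records are shifted, never truncated, so the
  preconditioning structure survives re-referencing.
* **Cycle removal.**  Preconditioning cycles are located as local maxima of
  the clamp displacement (displacement is machine-controlled and
  noise-free); the test ramp starts at the displacement minimum after the
  last peak.  A cycle-count mismatch is a structural error reporting the
  detected count.
* **Conversion and truncation.**  σ = F/A₀ (MPa), ε = d/L₀; sub-zero
  strains are dropped with an interpolated sample at exactly ε = 0;
  non-increasing strain samples are discarded.  Failure is the global
  stress maximum; everything after it is discarded and the failure point
  recorded.  Mean curves interpolate linearly onto a common grid (step
  10⁻³ strain, below experimental resolution) from 0 to the least failure
  strain of the group.

## Fitting and tangent moduli

Because T is linear in the coefficients, fitting is bounded linear least
squares (C₁₀ ≥ 10⁻¹²; other coefficients free), unweighted, with R²
computed against the mean stress of the fitted points.  Order selection
returns the lowest order that is Drucker-stable over the fitted range and
within 0.005 R² of the best order (the tolerance is configurable; no
numeric criterion is standard).  Pipeline fits are applied to per-region,
per-group mean curves, but the operation accepts any curve.

Windowed tangent moduli follow the experimental definition exactly: OLS
slope of stress on strain at the 8 strains centre ± 0.007 in steps of
0.002, stresses linearly interpolated from the curve.  On noise-free model
curves this estimator differs from the instantaneous analytic tangent by
the third-derivative window bias (f‴/6)·(Σx⁴/Σx²) ≈ 0.9% at the 3% centre
for the strongly stiffening regions (≈0.2% at 7%); the bias comes from the
±0.7% window itself and does not shrink with finer sampling.  The tests
treat the analytic-tangent-plus-bias expression as the oracle.

## Cohort statistics

* **CV** = SD/mean (n−1 denominator).
* **Two-sample tests** accept raw samples or printed (n, mean, SD)
  summaries.  Welch (Satterthwaite df) is the default: recomputing the
  published between-cohort p-values from the printed summaries matches the
  Welch results (sheath 3%: 0.033) and not the pooled-variance Student
  ones (0.008); Student remains available.  No multiplicity adjustment.
* **Regional correlations**: pairwise-complete Pearson r of eye-level 3%
  moduli between regions, with pair counts, significance via
  t = r√((n−2)/(1−r²)), cells with fewer than 3 complete eyes flagged
  undefined, and the verbal scale strong ≥ 0.5 / moderate 0.3–0.5 / weak
  < 0.3.  Both r and r² are reported (r itself is not a proportion of
  variance).
* **GEE curve comparison**: marginal Gaussian model
  stress ~ strain + strain² + group + age, exchangeable working
  correlation clustered on donor (two eyes per donor), Wald p-values.  The
  quadratic mean model is a package choice (the regression specification
  is not standardized) and is configurable.  With only ~13 donor clusters
  the uncorrected sandwich is anticonservative (measured null rejection
  0.12–0.16 at α = 0.05), so the default covariance is the bias-reduced
  Mancl–DeRouen sandwich (measured 0.07–0.09); the plain estimator is
  available via `cov_type="robust"`.  p < 0.001 is printed as "0.000",
  matching common clustered-regression software output.

## Synthetic cohort generator

The generator emulates the study conditions so every pipeline stage is
testable without donor data.

* **Protocol** (defaults): 0.05 N preload, 5 preconditioning cycles to 5%
  strain, 0.1 mm/s displacement-controlled ramp to failure, strain
  sampling step 10⁻³.  Records contain a slack region (force ≈ 0 until the
  specimen is taut; slack default 0.1 mm), elastic load–unload cycles, the
  ramp, and a sharp post-failure force drop to ~30% of ultimate.  The toe
  region arises from slack plus preload re-referencing rather than a
  collagen-crimp model — the minimal mechanism that exercises the
  preprocessing contracts.
* **Ground truth**: per-region second-order models from the published
  glaucomatous coefficient table.  Control-group models are synthetic
  stand-ins — the same models scaled by the ratio of the two cohorts'
  printed mean 3% tangent moduli per region (anterior 1.09, equatorial
  0.83, posterior 0.94, peripapillary 0.47, sheath 1.85, nerve 2.69) —
  implementing the reported stiffness ordering; they are not the control
  study's own coefficients.
* **Variability**: per donor, an age (glaucoma 86 ± 7 y, control 84 ± 8 y)
  and a shared lognormal stiffness multiplier (CV 0.15, a documented
  assumption — no inter-eye ICC is published) carrying the inter-eye
  correlation; per eye × region, a lognormal multiplier applied jointly to
  C₁₀ and C₂₀ (preserving curve shape) with CV set to the cohort's printed
  3% tangent-modulus CV for that region.  Failure strain ~ N(0.20, 0.03);
  force noise i.i.d. Gaussian with SD 1% of each specimen's ultimate
  force.  Specimen counts per eye mirror the preparation scheme (8 per
  scleral region split by orientation, 2 peripapillary, 4 sheath, 1
  nerve).  Scleral strips use the printed mean caliper dimensions with a
  nominal 0.8 mm thickness (0.4 mm sheath) because strip thickness is not
  published; the sheath uses its OCT cross-section (1.78 mm²) directly and
  the nerve its cohort-specific diameter (3.30 / 3.86 mm).
* **Determinism**: a single seed drives a fixed draw order; identical
  seeds give identical datasets, and a ground-truth manifest accompanies
  every cohort.

### What the generator does and does not emulate

It reproduces the protocol structure, region stiffness ordering, donor
clustering, scatter magnitudes, and failure truncation.  It does **not**
reproduce the *structure* of real biological variability: a whole-curve
multiplicative scatter calibrated to the printed 3% CVs puts far more
between-donor variance across the entire curve than real tissue shows
(where much of the 3% CV is toe-region variability).  Consequences worth
knowing:

* At the default noise (1% of ultimate force), the 3%-strain stress of the
  strongly stiffening regions is itself only ~1% of ultimate, so 3%
  windowed moduli of synthetic anterior/equatorial/sheath/nerve specimens
  are noise-dominated; peripapillary (3% stress ≈ 4% of ultimate) is the
  meaningful probe for modulus-level calibration checks.
* The donor-clustered GEE detects the peripapillary glaucoma-vs-control
  contrast only with modest power at α = 0.001 under this generative
  model, despite the twofold mean difference — the between-donor curve
  scatter implied by a CV of 1.09 overwhelms an 11-donor contrast.  A
  highly significant group effect on real curves is therefore *not*
  evidence the synthetic power should be high, and vice versa.
* Re-referencing strain to the preload state shifts the strain origin by
  the preload take-up (e.g. ~0.5% strain for anterior).  Fits to such
  curves remain excellent (R² > 0.99) but the fitted C₁₀ of C₂₀-dominated
  models is not a reliable estimate of the generating C₁₀ — the offset
  residual swamps C₁₀'s small basis contribution in an absolute
  least-squares fit.  Coefficient-recovery checks therefore run at the
  generator's strain reference.

## Numerical choices

Strains are dimensionless fractions internally (percent only at
presentation).  Stability grid step 10⁻³; mean-curve grid step 10⁻³;
analytic-vs-numeric tangent agreement verified to 10⁻⁶ relative with a
10⁻⁶ central-difference stencil.  Cycle-detection ties break toward the
later sample (the ramp start is the displacement minimum *after* the last
peak).  Output tables use one CSV dialect (comma, UTF-8, "." decimal,
header row) with 6-significant-digit formatting, making pipeline reruns
byte-identical under a fixed seed and configuration.  Monte-Carlo problem
sizes in the tests and the reproduction script — 100-replicate GEE
operating-characteristic runs on single-region cohorts, 50-seed recovery
runs — are sized to give stable rates while keeping the whole suite fast.

## Known limitations

Uniaxial, isotropic, time-independent modelling only: no anisotropy,
viscoelasticity, biaxial states, or image-based strain.  The control-group
generator models are scaled stand-ins, not measured parameters.  The
preload strain offset is inherent to clamp-to-clamp strain referencing;
fitted coefficients are conditional on that reference, exactly as in the
bench workflow.  GEE inference relies on ~13 clusters; even with the
bias-reduced covariance, p-values near the threshold should be read with
small-sample caution.
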