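# oculomech

Uniaxial tensile analysis of ocular soft tissue — sclera, optic nerve (ON),
and ON sheath — built around the workflow used to characterize glaucomatous
versus healthy donor eyes: raw force–displacement records are converted to
engineering stress–strain curves, fitted with reduced-polynomial
hyperelastic models, summarized as windowed tangent moduli, and compared
across cohorts with donor-clustered statistics.

## Who this is for

Tissue biomechanics groups running displacement-controlled uniaxial tests
on soft ocular (or similar) specimens who want a scriptable, tested path
from load-cell traces to finite-element-ready material parameters and
cohort-level statistics — plus a synthetic-cohort generator with known
ground truth for validating every stage.

## The model

Specimens are treated as hyperelastic, homogeneous, isotropic, and
incompressible.  The reduced-polynomial strain-energy density of order N is

    U = Σᵢ C_i0 (Ī₁ − 3)ⁱ + Σᵢ (1/D_i)(J_el − 1)²ⁱ,   i = 1..N

with Ī₁ the first deviatoric invariant of the right Cauchy–Green tensor.
Under incompressible uniaxial extension (stretch λ = 1 + ε, J_el = 1):

    Ī₁ = λ² + 2/λ
    T(λ) = 2 (λ − λ⁻²) Σᵢ i C_i0 (Ī₁ − 3)^(i−1)      (nominal stress)
    E(ε→0) = 6 C₁₀                                     (initial modulus)

T is linear in the coefficients, so fitting is bounded linear least squares
(C₁₀ > 0) — no initialisation or convergence concerns.  D₁ is derived
afterwards from an assumed Poisson ratio ν = 0.49 via
D₁ = 3(1 − 2ν)/(2 C₁₀ (1 + ν)); D₂ = 0 at order 2.

Experimental tangent moduli follow the bench definition: the OLS slope of
stress on strain over 8 points spaced 0.2% strain apart spanning the centre
± 0.7% (2.3–3.7% for the "3%" modulus, 6.3–7.7% for "7%").  Cohort
statistics cover coefficients of variation, Welch/Student two-sample tests
(from raw samples or printed n/mean/SD summaries), pairwise-complete
regional Pearson correlation matrices, and generalized estimating equations
(GEE) over complete curves, clustered on donor with a donor-age covariate
and a small-sample-corrected sandwich covariance.

## Worked example

```python
import oculomech as om
from oculomech import reference as ref

model = ref.glaucoma_model("anterior")        # C10 = 1.06, C20 = 149.8 MPa
print(om.nominal_stress(model, 0.03))         # 0.32395676264685663  (MPa)
print(om.tangent_modulus_analytic(model, 0.03))  # 19.645381595663203 (MPa)
print(om.volumetric_coefficient(1.06, 0.49))  # 0.01899455489426366  (1/MPa)
print(om.cross_section_ratio(3.30, 3.86))     # 73  (% — glaucomatous ON
                                              #  cross-section vs control)
```

A full synthetic study from the shell:

```sh
oculomech simulate --out cohort --seed 1 --donors-glaucoma 6 --donors-control 7
oculomech report --in cohort --out results
```

`results/` then contains tidy curve tables, the per-region hyperelastic
parameter table (region, group, C10, C20, D1, D2, R²), eye-level tangent
moduli, the two-sample comparison table, GEE p-values per region, the
regional correlation table, and a plain-text report.  Reruns with the same
seed and configuration are byte-identical.

Library equivalents live in `oculomech.pipeline` (`run_pipeline`,
`preprocess_cohort`, `fit_region_models`, `eye_moduli`, ...) and the
synthetic generator in `oculomech.synthetic`.

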