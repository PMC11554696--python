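"""Published reference values for glaucomatous and control ocular tissue.

These constants transcribe the summary tables of the tensile study the
package analyses: second-order reduced-polynomial coefficients fitted to the
mean curve of each tissue region in the glaucomatous cohort, eye-level
tangent-modulus summary statistics for both cohorts, specimen dimensions,
and optic-nerve calibre.  They serve two roles:

* calibration of the synthetic-cohort generator (region stiffness, scatter,
  ages, geometry), and
* worked-example inputs for the statistics utilities (coefficient of
  variation and two-sample tests can be driven directly from printed
  ``(n, mean, SD)`` summaries).
"""

from __future__ import annotations

import pandas as pd

from .hyperelastic import ReducedPolynomialModel

#: Tissue regions in anatomical order, anterior to optic nerve.
REGIONS = ("anterior", "equatorial", "posterior", "peripapillary", "sheath", "nerve")

#: Second-order reduced-polynomial coefficients (MPa) fitted to the mean
#: glaucomatous curve per region, with the published D_1 (1/MPa) alongside.
#: D_2 is identically zero at order 2.
GLAUCOMA_HYPERELASTIC = {
    "anterior": {"C10": 1.06, "C20": 149.8, "D1": 1.90e-2},
    "equatorial": {"C10": 0.62, "C20": 137.6, "D1": 3.26e-2},
    "posterior": {"C10": 0.55, "C20": 68.7, "D1": 3.67e-2},
    "peripapillary": {"C10": 0.78, "C20": 15.4, "D1": 2.59e-2},
    "sheath": {"C10": 0.24, "C20": 32.6, "D1": 8.26e-2},
    "nerve": {"C10": 4.23e-2, "C20": 7.5, "D1": 0.48},
}

#: Poisson ratio assumed for all ocular tissues.
POISSON_RATIO = 0.49

# Eye-level tangent-modulus summaries (MPa) at 3% and 7% strain:
# (region, group, n eyes, mean3, sd3, cv3, mean7, sd7, cv7).
_TANGENT_ROWS = [
    ("anterior", "control", 9, 31.0, 12.8, 0.41, 52.8, 15.7, 0.30),
    ("anterior", "glaucoma", 12, 28.5, 7.3, 0.26, 63.0, 25.6, 0.41),
    ("equatorial", "control", 10, 19.5, 9.0, 0.46, 30.0, 11.8, 0.39),
    ("equatorial", "glaucoma", 12, 23.4, 7.6, 0.32, 34.9, 10.4, 0.30),
    ("posterior", "control", 10, 13.3, 5.3, 0.40, 20.3, 6.1, 0.30),
    ("posterior", "glaucoma", 12, 14.2, 5.0, 0.35, 25.6, 8.0, 0.31),
    ("peripapillary", "control", 10, 3.5, 1.4, 0.40, 7.4, 3.3, 0.44),
    ("peripapillary", "glaucoma", 12, 7.4, 8.0, 1.09, 14.0, 9.7, 0.69),
    ("sheath", "control", 8, 10.9, 5.3, 0.49, 22.7, 10.0, 0.44),
    ("sheath", "glaucoma", 12, 5.9, 2.0, 0.33, 18.4, 5.8, 0.32),
    ("nerve", "control", 6, 3.5, 2.3, 0.66, 6.2, 3.5, 0.56),
    ("nerve", "glaucoma", 11, 1.3, 1.0, 0.77, 3.9, 2.1, 0.54),
]

#: Tangent-modulus summary statistics per region and cohort.
TANGENT_SUMMARY = pd.DataFrame(
    _TANGENT_ROWS,
    columns=[
        "region",
        "group",
        "n",
        "mean_3pct",
        "sd_3pct",
        "cv_3pct",
        "mean_7pct",
        "sd_7pct",
        "cv_7pct",
    ],
)

#: Published two-sample p-values (glaucoma vs control tangent moduli).
PRINTED_T_P = {
    "anterior": {0.03: 0.598, 0.07: 0.273},
    "equatorial": {0.03: 0.294, 0.07: 0.317},
    "posterior": {0.03: 0.670, 0.07: 0.097},
    "peripapillary": {0.03: 0.130, 0.07: 0.043},
    "sheath": {0.03: 0.033, 0.07: 0.291},
    "nerve": {0.03: 0.063, 0.07: 0.173},
}

#: Mean rectangular-specimen dimensions (length mm, width mm) per scleral
#: region, measured by digital caliper.
SCLERAL_DIMENSIONS = {
    "anterior": (5.98, 1.88),
    "equatorial": (6.02, 2.03),
    "posterior": (5.88, 2.01),
    "peripapillary": (3.44, 1.98),
}

#: Published mean aspect ratios for the four scleral regions.
PRINTED_ASPECT_RATIOS = {
    "anterior": 3.18,
    "equatorial": 2.97,
    "posterior": 2.93,
    "peripapillary": 1.74,
}

#: Optic-nerve sheath: mean specimen length (mm) and OCT cross-section (mm^2)
#: measured under 0.05 N preload.
SHEATH_LENGTH_MM = 7.21
SHEATH_AREA_MM2 = 1.78

#: Optic nerve tested in native cylindrical form: mean length and diameter.
NERVE_LENGTH_MM = 11.43
NERVE_DIAMETER_MM = {"glaucoma": 3.30, "control": 3.86}

#: Donor age summaries (mean, SD) in years.
AGE_SUMMARY = {"glaucoma": (86.0, 7.0), "control": (84.0, 8.0)}


def glaucoma_model(region: str) -> ReducedPolynomialModel:
    """Reference second-order model for one glaucomatous tissue region."""
    p = GLAUCOMA_HYPERELASTIC[region]
    return ReducedPolynomialModel(c=(p["C10"], p["C20"]), poisson=POISSON_RATIO)


def control_stiffness_scale(region: str) -> float:
    """Stiffness scale mapping the glaucomatous reference model to a
    synthetic control-like model, taken as the ratio of the two cohorts'
    mean 3% tangent moduli (control / glaucoma).

    The control cohort's own coefficient table is not available here, so
    these scaled models are synthetic stand-ins that reproduce the reported
    stiffness ordering: control sheath and nerve markedly stiffer than
    glaucomatous, control peripapillary about half as stiff.
    """
    t = TANGENT_SUMMARY.set_index(["region", "group"])
    return float(
        t.loc[(region, "control"), "mean_3pct"] / t.loc[(region, "glaucoma"), "mean_3pct"]
    )
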