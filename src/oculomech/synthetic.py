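"""Synthetic tensile-test records and two-group cohorts with known truth.

The generator emulates the bench protocol end to end so every pipeline
stage can be exercised without donor data: a slack region (near-zero force
until the specimen is taut, which together with preload re-referencing
produces a toe region), five preconditioning load-unload cycles to 5%
strain, a monotone displacement-controlled ramp at 0.1 mm/s to a drawn
failure strain, a sharp post-failure force drop, and additive Gaussian
force noise scaled to the specimen's ultimate stress.

Cohorts draw, per donor, an age and a shared stiffness multiplier (the
inter-eye correlation the clustered regression exists to absorb) and, per
eye and region, a lognormal coefficient multiplier applied jointly to C_10
and C_20 so each specimen's curve keeps a physically plausible shape.
Region stiffness defaults come from the glaucomatous reference parameter
table; control-group models are synthetic stand-ins obtained by scaling
those references by the ratio of the two cohorts' mean 3% tangent moduli
(control sheath and nerve much stiffer, control peripapillary about half
as stiff).  Multiplier scatter defaults to each cohort's reported 3%
tangent-modulus CV per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import reference as ref
from .errors import ConfigError
from .hyperelastic import ReducedPolynomialModel, nominal_stress
from .preprocess import SpecimenGeometry, SpecimenRecord

__all__ = [
    "LoadingProtocol",
    "CohortConfig",
    "CohortDataset",
    "generate_specimen",
    "generate_cohort",
    "default_geometry",
    "default_models",
]

#: Specimens prepared per eye and region (4 meridional + 4 circumferential
#: strips per scleral region, 2 circumferential peripapillary strips,
#: 2 longitudinal + 2 circumferential sheath strips, 1 native nerve).
DEFAULT_SPECIMENS_PER_EYE = {
    "anterior": 8,
    "equatorial": 8,
    "posterior": 8,
    "peripapillary": 2,
    "sheath": 4,
    "nerve": 1,
}

_ORIENTATIONS = {
    "anterior": ("meridional", "circumferential"),
    "equatorial": ("meridional", "circumferential"),
    "posterior": ("meridional", "circumferential"),
    "peripapillary": ("circumferential", "circumferential"),
    "sheath": ("longitudinal", "circumferential"),
    "nerve": ("native", "native"),
}

#: Nominal strip thicknesses (mm); strip thickness is not part of the
#: reference dimension table, so the generator assumes representative
#: values (0.8 mm sclera, 0.4 mm sheath).
SCLERA_THICKNESS_MM = 0.8
SHEATH_THICKNESS_MM = 0.4


@dataclass(frozen=True)
class LoadingProtocol:
    """Loading protocol parameters (defaults match the bench protocol)."""

    preload_n: float = 0.05
    n_precycles: int = 5
    precycle_strain: float = 0.05
    rate_mm_s: float = 0.1
    strain_step: float = 0.001  # displacement sampling resolution in strain


def default_geometry(region: str, group: str = "glaucoma") -> SpecimenGeometry:
    """Representative specimen geometry for one region.

    Scleral strips use the mean caliper dimensions with a nominal
    thickness; the sheath uses its OCT cross-section directly; the nerve
    is a native cylinder whose diameter depends on the cohort (atrophic
    nerves are thinner).
    """
    if region in ref.SCLERAL_DIMENSIONS:
        length, width = ref.SCLERAL_DIMENSIONS[region]
        return SpecimenGeometry(
            gauge_length=length, width=width, thickness=SCLERA_THICKNESS_MM
        )
    if region == "sheath":
        return SpecimenGeometry(gauge_length=ref.SHEATH_LENGTH_MM, area=ref.SHEATH_AREA_MM2)
    if region == "nerve":
        return SpecimenGeometry(
            gauge_length=ref.NERVE_LENGTH_MM, diameter=ref.NERVE_DIAMETER_MM[group]
        )
    raise ConfigError(f"unknown region {region!r}")


def default_models(
    group: str = "glaucoma",
    control_scale: Optional[Dict[str, float]] = None,
) -> Dict[str, ReducedPolynomialModel]:
    """Ground-truth models per region for one cohort.

    Glaucoma: the reference coefficient table.  Control: the same models
    scaled by the reported control/glaucoma 3% tangent-modulus ratio
    (synthetic stand-ins; the control cohort's own coefficients are not
    available here).  ``control_scale`` overrides the ratio per region —
    e.g. 1.0 makes the two groups identical for null simulations.
    """
    models = {r: ref.glaucoma_model(r) for r in ref.REGIONS}
    if group == "control":
        scale = control_scale or {}
        models = {
            r: m.scaled(scale.get(r, ref.control_stiffness_scale(r)))
            for r, m in models.items()
        }
    elif group != "glaucoma":
        raise ConfigError(f"unknown group {group!r}")
    return models


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def _lognormal_unit_mean(rng: np.random.Generator, cv: float) -> float:
    """Lognormal multiplier with mean 1 and the requested CV."""
    if cv <= 0:
        return 1.0
    s = _lognormal_sigma(cv)
    return float(rng.lognormal(mean=-0.5 * s**2, sigma=s))


def generate_specimen(
    model: ReducedPolynomialModel,
    geometry: SpecimenGeometry,
    protocol: LoadingProtocol = LoadingProtocol(),
    noise_sd: float = 0.01,
    failure_strain: float = 0.20,
    slack_mm: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    **metadata,
) -> SpecimenRecord:
    """Synthesize one force-displacement record from a known model.

    The displacement path is slack take-up, ``n_precycles`` load-unload
    cycles to ``precycle_strain``, then a ramp to ``failure_strain``
    followed by a sharp force drop to ~30% of ultimate.  Force is
    ``T(strain) * A0`` plus i.i.d. Gaussian noise with SD ``noise_sd``
    times the ultimate force (zero before the specimen is taut).  The
    record's ``geometry.gauge_length`` refers to the clamp separation at
    the trace origin (the taut length minus ``slack_mm``), so preload
    re-referencing recovers the taut gauge length.  Time follows the clamp
    path length at the constant loading rate.
    """
    if failure_strain <= protocol.precycle_strain:
        raise ConfigError(
            f"failure_strain {failure_strain} must exceed the preconditioning "
            f"strain {protocol.precycle_strain}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    L0 = geometry.gauge_length  # taut gauge length, mm
    area = geometry.cross_section
    step = protocol.strain_step
    h = step * L0  # displacement step, mm

    pieces = [np.array([0.0])]
    if slack_mm > 0:
        pieces.append(np.arange(h, slack_mm, h))
        pieces.append(np.array([slack_mm]))
    up = slack_mm + np.arange(step, protocol.precycle_strain + step / 2, step) * L0
    down = up[-2::-1] if len(up) > 1 else np.array([])
    for _ in range(protocol.n_precycles):
        pieces.append(up)
        pieces.append(down)
        pieces.append(np.array([slack_mm]))
    ramp = slack_mm + np.arange(step, failure_strain + step / 2, step) * L0
    pieces.append(ramp)
    n_post = 6
    post = ramp[-1] + h * np.arange(1, n_post + 1)
    pieces.append(post)
    disp = np.concatenate(pieces)

    strain = np.maximum((disp - slack_mm) / L0, 0.0)
    force = nominal_stress(model, strain) * area
    ultimate = float(nominal_stress(model, failure_strain) * area)
    drop = ultimate * np.array([0.70, 0.55, 0.45, 0.38, 0.33, 0.30])
    force[-n_post:] = drop[:n_post]
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd * ultimate, size=len(force))

    path = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(disp)))])
    time = path / protocol.rate_mm_s

    return SpecimenRecord(
        time=time,
        displacement=disp,
        force=force,
        geometry=geometry.with_gauge_length(L0 - slack_mm),
        **metadata,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic two-group cohort.

    Defaults emulate the published cohorts: 6 glaucoma donors (12 eyes,
    ages 86 +/- 7 y) vs 7 control donors (14 eyes, 84 +/- 8 y), two eyes
    per donor, region stiffness from the reference table (control scaled),
    per-eye-per-region lognormal coefficient multipliers with each
    cohort's reported 3% tangent-modulus CV, a shared donor multiplier
    (CV ``donor_effect_sd``) carrying the inter-eye correlation, failure
    strain ~ N(0.20, 0.03), 0.1 mm slack, and force noise of 1% of each
    specimen's ultimate stress.  ``age_slope`` (log-stiffness per year,
    default 0) lets simulations inject or omit an age effect.
    """

    groups: Tuple[str, ...] = ("glaucoma", "control")
    n_donors: Optional[Dict[str, int]] = None
    eyes_per_donor: int = 2
    regions: Tuple[str, ...] = ref.REGIONS
    specimens_per_eye: Optional[Dict[str, int]] = None
    multiplier_cv: Optional[Dict[Tuple[str, str], float]] = None
    donor_effect_sd: float = 0.15
    age_mean_sd: Optional[Dict[str, Tuple[float, float]]] = None
    age_slope: float = 0.0
    noise_sd: float = 0.01
    failure_mean: float = 0.20
    failure_sd: float = 0.03
    slack_mm: float = 0.1
    protocol: LoadingProtocol = LoadingProtocol()
    control_scale: Optional[Dict[str, float]] = None
    seed: int = 0

    def resolved(self) -> "CohortConfig":
        """Fill None fields with the study-condition defaults and validate."""
        for r in self.regions:
            if r not in ref.REGIONS:
                raise ConfigError(f"unknown region {r!r}")
        for g in self.groups:
            if g not in ("glaucoma", "control"):
                raise ConfigError(f"unknown group {g!r}")
        n_donors = self.n_donors or {"glaucoma": 6, "control": 7}
        spe = self.specimens_per_eye or {
            r: DEFAULT_SPECIMENS_PER_EYE[r] for r in self.regions
        }
        cv = self.multiplier_cv
        if cv is None:
            t = ref.TANGENT_SUMMARY.set_index(["region", "group"])
            cv = {
                (g, r): float(t.loc[(r, g), "cv_3pct"])
                for g in self.groups
                for r in self.regions
            }
        ages = self.age_mean_sd or dict(ref.AGE_SUMMARY)
        for g in self.groups:
            if n_donors.get(g, 0) < 2:
                raise ConfigError(f"need at least 2 donors per group ({g})")
        if self.donor_effect_sd < 0 or self.noise_sd < 0 or self.failure_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        return replace(
            self,
            n_donors=n_donors,
            specimens_per_eye=spe,
            multiplier_cv=cv,
            age_mean_sd=ages,
        )


@dataclass(eq=False)
class CohortDataset:
    """Generated specimen records plus metadata and ground-truth manifests."""

    records: List[SpecimenRecord]
    manifest: pd.DataFrame  # one row per specimen: metadata + geometry
    truth: pd.DataFrame  # one row per specimen: generating coefficients

    def __len__(self) -> int:
        return len(self.records)

    def record(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Generate a full two-group cohort under ``config``.

    The draw order (donor age, donor multiplier, then per eye and region
    the coefficient multiplier, per specimen the failure strain and force
    noise) is fixed, so a seed fully determines the dataset.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    records: List[SpecimenRecord] = []
    manifest_rows = []
    truth_rows = []
    for group in cfg.groups:
        models = default_models(group, control_scale=cfg.control_scale)
        age_mean, age_sd = cfg.age_mean_sd[group]
        for di in range(cfg.n_donors[group]):
            donor_id = f"{group[0].upper()}{di + 1:02d}"
            age = float(rng.normal(age_mean, age_sd))
            donor_mult = _lognormal_unit_mean(rng, cfg.donor_effect_sd)
            age_mult = float(np.exp(cfg.age_slope * (age - age_mean)))
            for ei in range(cfg.eyes_per_donor):
                eye = ("OD", "OS")[ei % 2]
                for region in cfg.regions:
                    eye_mult = _lognormal_unit_mean(
                        rng, cfg.multiplier_cv[(group, region)]
                    )
                    total = donor_mult * eye_mult * age_mult
                    model = models[region].scaled(total)
                    geometry = default_geometry(region, group)
                    n_spec = cfg.specimens_per_eye[region]
                    orients = _ORIENTATIONS[region]
                    for si in range(n_spec):
                        fail = float(
                            np.clip(
                                rng.normal(cfg.failure_mean, cfg.failure_sd),
                                cfg.protocol.precycle_strain + 0.05,
                                None,
                            )
                        )
                        sid = f"{donor_id}-{eye}-{region}-{si + 1}"
                        rec = generate_specimen(
                            model,
                            geometry,
                            protocol=cfg.protocol,
                            noise_sd=cfg.noise_sd,
                            failure_strain=fail,
                            slack_mm=cfg.slack_mm,
                            rng=rng,
                            region=region,
                            orientation=orients[si % len(orients)],
                            donor_id=donor_id,
                            eye=eye,
                            group=group,
                            age=age,
                            specimen_id=sid,
                        )
                        records.append(rec)
                        manifest_rows.append(
                            {
                                "specimen_id": sid,
                                "donor_id": donor_id,
                                "eye": eye,
                                "group": group,
                                "age": age,
                                "region": region,
                                "orientation": rec.orientation,
                                "gauge_length_mm": rec.geometry.gauge_length,
                                "width_mm": geometry.width,
                                "thickness_mm": geometry.thickness,
                                "diameter_mm": geometry.diameter,
                                "area_mm2": geometry.area,
                            }
                        )
                        truth_rows.append(
                            {
                                "specimen_id": sid,
                                "C10": model.c10,
                                "C20": model.c20,
                                "multiplier": total,
                                "donor_multiplier": donor_mult,
                                "failure_strain": fail,
                                "slack_mm": cfg.slack_mm,
                            }
                        )
    return CohortDataset(
        records=records,
        manifest=pd.DataFrame(manifest_rows),
        truth=pd.DataFrame(truth_rows),
    )
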