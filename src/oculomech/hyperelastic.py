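"""Incompressible reduced-polynomial hyperelasticity in uniaxial tension.

The reduced polynomial strain-energy density of order ``N`` is

    U = sum_{i=1}^{N} C_i0 (I1bar - 3)^i  +  sum_{i=1}^{N} (1/D_i) (J_el - 1)^(2i)

where ``I1bar`` is the first invariant of the isochoric right Cauchy-Green
tensor, ``C_i0`` (MPa) are the deviatoric coefficients, ``D_i`` (1/MPa) the
volumetric coefficients, and ``J_el`` the elastic volume ratio.  Order 1 is
the neo-Hookean solid.

Tensile test data are reduced under the fully incompressible uniaxial
assumption: for stretch ``lam = 1 + strain`` the transverse stretches are
``lam**-0.5``, so ``J_el == 1``, the volumetric series drops out, and

    I1bar(lam)  = lam**2 + 2/lam
    T(lam)      = dU/dlam = 2 (lam - lam**-2) * g(I1bar - 3)          [nominal]
    dT/dlam     = 2 (1 + 2 lam**-3) g + 4 (lam - lam**-2)**2 g'

with ``g(x) = sum_i i C_i0 x**(i-1)``.  The volumetric coefficient ``D_1`` is
derived *afterwards* from a near-incompressible Poisson ratio via the
small-strain identities ``mu0 = 2 C_10`` and ``K0 = 2/D_1``:

    D_1 = 3 (1 - 2 nu) / (mu0 (1 + nu))

This is the convention under which a slightly compressible parameter table
(C_10, C_20, D_1, D_2 = 0) is produced from an incompressible curve fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "ReducedPolynomialModel",
    "UniaxialEvaluation",
    "uniaxial_invariant",
    "nominal_stress",
    "tangent_modulus_analytic",
    "strain_energy",
    "volumetric_coefficient",
    "drucker_stable",
    "evaluate",
]


@dataclass(frozen=True)
class ReducedPolynomialModel:
    """Reduced-polynomial hyperelastic material.

    Parameters
    ----------
    c : sequence of float
        Deviatoric coefficients ``C_i0`` in MPa; ``len(c)`` is the order.
        ``C_10`` must be positive (it fixes the small-strain shear modulus
        ``mu0 = 2 C_10``).
    d : sequence of float, optional
        Volumetric coefficients ``D_i`` in 1/MPa.  Only ``D_1`` may be
        nonzero; when omitted, ``D_1`` is derived from ``poisson``.
    poisson : float
        Poisson ratio in (0, 0.5); default 0.49 (near-incompressible, the
        standard assumption for ocular soft tissue).
    """

    c: tuple
    d: tuple = field(default=None)
    poisson: float = 0.49

    def __post_init__(self):
        c = tuple(float(v) for v in np.atleast_1d(self.c))
        if len(c) < 1:
            raise DomainError("at least one deviatoric coefficient required")
        if c[0] <= 0:
            raise DomainError(f"C_10 must be positive, got {c[0]}")
        if not 0.0 < self.poisson < 0.5:
            raise DomainError(f"poisson must lie in (0, 0.5), got {self.poisson}")
        object.__setattr__(self, "c", c)
        if self.d is None:
            d = (volumetric_coefficient(c[0], self.poisson),) + (0.0,) * (len(c) - 1)
        else:
            d = tuple(float(v) for v in np.atleast_1d(self.d))
            if len(d) != len(c):
                raise DomainError("c and d must have equal length")
            if d[0] < 0:
                raise DomainError("D_1 must be non-negative")
            if any(v != 0.0 for v in d[1:]):
                raise DomainError("D_i must be zero for i >= 2")
        object.__setattr__(self, "d", d)

    @property
    def order(self) -> int:
        return len(self.c)

    @property
    def c10(self) -> float:
        return self.c[0]

    @property
    def c20(self) -> float:
        return self.c[1] if self.order >= 2 else 0.0

    @property
    def d1(self) -> float:
        return self.d[0]

    def scaled(self, factor: float) -> "ReducedPolynomialModel":
        """Return a copy with every deviatoric coefficient multiplied by
        ``factor`` (a stiffness scale that preserves curve shape)."""
        if factor <= 0:
            raise DomainError("scale factor must be positive")
        return ReducedPolynomialModel(
            c=tuple(factor * v for v in self.c), poisson=self.poisson
        )

    def to_dict(self) -> dict:
        """Flat key-value form (order, C10, C20, D1, D2, poisson)."""
        return {
            "order": self.order,
            "C10": self.c10,
            "C20": self.c20,
            "D1": self.d1,
            "D2": 0.0,
            "poisson": self.poisson,
        }

    @classmethod
    def from_dict(cls, row: dict) -> "ReducedPolynomialModel":
        order = int(row.get("order", 2 if row.get("C20") else 1))
        c = [float(row["C10"])] + ([float(row.get("C20", 0.0))] if order >= 2 else [])
        return cls(c=tuple(c), poisson=float(row.get("poisson", 0.49)))


@dataclass(frozen=True)
class UniaxialEvaluation:
    """State of the uniaxial model at one engineering strain."""

    strain: float
    stretch: float
    i1bar: float
    energy: float
    nominal_stress: float
    tangent: float


def _as_stretch(strain):
    lam = 1.0 + np.asarray(strain, dtype=float)
    if np.any(lam <= 0):
        raise DomainError("engineering strain must exceed -1 (stretch > 0)")
    return lam


def uniaxial_invariant(stretch):
    """First deviatoric invariant ``I1bar = lam**2 + 2/lam`` for
    incompressible uniaxial extension.  Equals 3 iff ``lam == 1``."""
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise DomainError("stretch must be positive")
    return lam**2 + 2.0 / lam


def _g(model: ReducedPolynomialModel, x):
    """g(x) = sum_i i * C_i0 * x**(i-1)."""
    out = np.zeros_like(np.asarray(x, dtype=float))
    for i, ci in enumerate(model.c, start=1):
        out = out + i * ci * np.asarray(x) ** (i - 1) if i > 1 else out + ci
    return out


def _gprime(model: ReducedPolynomialModel, x):
    """g'(x) = sum_{i>=2} i (i-1) C_i0 x**(i-2)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for i, ci in enumerate(model.c, start=1):
        if i >= 2:
            out = out + i * (i - 1) * ci * x ** (i - 2)
    return out


def nominal_stress(model: ReducedPolynomialModel, strain):
    """Engineering (nominal) uniaxial stress T(strain) in MPa.

    ``T = 2 (lam - lam**-2) * g(I1bar - 3)``; zero at zero strain.
    """
    lam = _as_stretch(strain)
    x = uniaxial_invariant(lam) - 3.0
    T = 2.0 * (lam - lam**-2) * _g(model, x)
    return T if np.ndim(strain) else float(T)


def tangent_modulus_analytic(model: ReducedPolynomialModel, strain):
    """Analytic tangent modulus dT/dstrain (= dT/dlam) in MPa.

    Equals ``6 C_10`` in the zero-strain limit (the initial Young's modulus
    of an incompressible solid with shear modulus ``2 C_10``).
    """
    lam = _as_stretch(strain)
    x = uniaxial_invariant(lam) - 3.0
    dT = 2.0 * (1.0 + 2.0 * lam**-3) * _g(model, x) + 4.0 * (
        lam - lam**-2
    ) ** 2 * _gprime(model, x)
    return dT if np.ndim(strain) else float(dT)


def strain_energy(model: ReducedPolynomialModel, stretch):
    """Strain-energy density U(lam) in MPa; zero at lam = 1 and
    non-negative for positive coefficients."""
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise DomainError("stretch must be positive")
    x = uniaxial_invariant(lam) - 3.0
    U = np.zeros_like(x)
    for i, ci in enumerate(model.c, start=1):
        U = U + ci * x**i
    return U if np.ndim(stretch) else float(U)


def volumetric_coefficient(c10: float, poisson: float) -> float:
    """Volumetric coefficient ``D_1`` (1/MPa) from ``C_10`` and the Poisson
    ratio: ``D_1 = 3 (1 - 2 nu) / (2 C_10 (1 + nu))``.

    Vanishes in the incompressible limit ``nu -> 0.5``; ``nu >= 0.5`` is a
    domain error (no finite bulk compliance exists there).
    """
    if c10 <= 0:
        raise DomainError("C_10 must be positive")
    if not 0.0 < poisson < 0.5:
        raise DomainError("poisson must lie in (0, 0.5)")
    mu0 = 2.0 * c10
    return 3.0 * (1.0 - 2.0 * poisson) / (mu0 * (1.0 + poisson))


def drucker_stable(
    model: ReducedPolynomialModel, strain_max: float, grid_step: float = 1e-3
) -> bool:
    """Uniaxial material stability over (0, strain_max].

    True iff the analytic tangent modulus is positive at every grid point
    (step ``grid_step``, default 1e-3 strain) — incremental stress and
    strain then have positive product everywhere in the tested range.
    """
    if strain_max <= 0:
        raise DomainError("strain_max must be positive")
    grid = np.arange(grid_step, strain_max + grid_step / 2, grid_step)
    grid = np.append(grid, strain_max) if grid[-1] < strain_max else grid
    return bool(np.all(tangent_modulus_analytic(model, grid) > 0))


def evaluate(model: ReducedPolynomialModel, strain: float) -> UniaxialEvaluation:
    """Full uniaxial state (invariant, energy, stress, tangent) at one strain."""
    lam = float(_as_stretch(strain))
    return UniaxialEvaluation(
        strain=float(strain),
        stretch=lam,
        i1bar=float(uniaxial_invariant(lam)),
        energy=strain_energy(model, lam),
        nominal_stress=nominal_stress(model, strain),
        tangent=tangent_modulus_analytic(model, strain),
    )
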