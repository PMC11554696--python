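"""Hyperelastic coefficient estimation and windowed tangent moduli.

The uniaxial nominal stress of a reduced-polynomial solid is *linear* in
its deviatoric coefficients: ``T = sum_i C_i0 * b_i(strain)`` with basis
``b_i = 2 i (lam - lam**-2) (I1bar - 3)**(i-1)``.  Coefficients are
therefore estimated by bounded linear least squares (``C_10 > 0``), with
no initialisation or convergence concerns; ``D_1`` is derived from the
Poisson ratio afterwards and ``D_i = 0`` for ``i >= 2``.

Windowed tangent moduli follow the experimental definition: the ordinary
least-squares slope of stress on strain over 8 points spaced 0.002 strain
apart, spanning the centre +/- 0.007 (2.3-3.7% for the 3% modulus,
6.3-7.7% for the 7% modulus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import lsq_linear

from .errors import DomainError, FitError, WindowCoverageError
from .hyperelastic import (
    ReducedPolynomialModel,
    drucker_stable,
    nominal_stress,
    uniaxial_invariant,
)
from .preprocess import StressStrainCurve

__all__ = [
    "FitResult",
    "TangentModulus",
    "fit_reduced_polynomial",
    "select_order",
    "tangent_modulus_windowed",
    "TANGENT_HALF_WINDOW",
    "TANGENT_WINDOW_STEP",
    "TANGENT_WINDOW_POINTS",
]

TANGENT_HALF_WINDOW = 0.007
TANGENT_WINDOW_STEP = 0.002
TANGENT_WINDOW_POINTS = 8


@dataclass(frozen=True)
class FitResult:
    """Outcome of a reduced-polynomial fit to one stress-strain curve."""

    model: ReducedPolynomialModel
    r_squared: float
    residual_rms: float  # MPa
    stable: bool
    n_points: int


@dataclass(frozen=True)
class TangentModulus:
    """OLS tangent modulus over a symmetric strain window."""

    center_strain: float
    value: float  # MPa
    window: tuple  # (strain_lo, strain_hi)
    n_points: int


def _basis(strain: np.ndarray, order: int) -> np.ndarray:
    lam = 1.0 + strain
    x = uniaxial_invariant(lam) - 3.0
    pre = 2.0 * (lam - lam**-2)
    return np.column_stack([pre * i * x ** (i - 1) for i in range(1, order + 1)])


def fit_reduced_polynomial(
    curve: StressStrainCurve,
    order: int = 2,
    poisson: float = 0.49,
) -> FitResult:
    """Least-squares reduced-polynomial fit of order ``N`` to a curve.

    Minimises ``sum (T_model(strain_i) - stress_i)**2`` over the deviatoric
    coefficients with ``C_10 > 0`` enforced; R^2 is computed against the
    mean-stress baseline of the fitted points.  Duplicate samples and
    sample order do not change the solution.
    """
    if order < 1:
        raise DomainError("order must be >= 1")
    strain = np.asarray(curve.strain, dtype=float)
    stress = np.asarray(curve.stress, dtype=float)
    if len(strain) < 2 * order + 1:
        raise FitError(f"need at least {2 * order + 1} points for order {order}")
    if np.allclose(stress, stress[0]):
        raise FitError("degenerate curve: constant stress")
    A = _basis(strain, order)
    lb = np.full(order, -np.inf)
    lb[0] = 1e-12  # C_10 strictly positive
    sol = lsq_linear(A, stress, bounds=(lb, np.full(order, np.inf)))
    if not sol.success:
        raise FitError(f"linear least squares failed: {sol.message}")
    coeffs = tuple(sol.x)
    model = ReducedPolynomialModel(c=coeffs, poisson=poisson)
    resid = stress - A @ sol.x
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((stress - stress.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("-inf")
    strain_max = float(strain.max())
    return FitResult(
        model=model,
        r_squared=r2,
        residual_rms=float(np.sqrt(ss_res / len(stress))),
        stable=drucker_stable(model, strain_max) if strain_max > 0 else True,
        n_points=len(stress),
    )


def select_order(
    curve: StressStrainCurve,
    max_order: int = 2,
    poisson: float = 0.49,
    r2_tolerance: float = 0.005,
) -> FitResult:
    """Lowest-order stable fit whose R^2 is within ``r2_tolerance`` of the
    best order's R^2 (parsimony with a stability requirement).

    Raises :class:`FitError` (carrying the best unstable fit) when no
    stable order reaches the R^2 band.
    """
    if max_order < 1:
        raise DomainError("max_order must be >= 1")
    fits = [fit_reduced_polynomial(curve, order=n, poisson=poisson)
            for n in range(1, max_order + 1)]
    best_r2 = max(f.r_squared for f in fits)
    for f in fits:
        if f.stable and f.r_squared >= best_r2 - r2_tolerance:
            return f
    best = max(fits, key=lambda f: f.r_squared)
    raise FitError(
        f"no stable order <= {max_order} within {r2_tolerance} of best "
        f"R^2 = {best_r2:.6f} (best fit is order {best.model.order}, unstable)",
        best_fit=best,
    )


def tangent_modulus_windowed(
    curve: StressStrainCurve,
    center: float,
    half_window: float = TANGENT_HALF_WINDOW,
    step: float = TANGENT_WINDOW_STEP,
) -> TangentModulus:
    """Experimental tangent modulus: OLS slope of stress on strain at the
    window points ``center - half_window .. center + half_window`` spaced
    ``step`` apart (8 points at the defaults), stresses taken by linear
    interpolation of the curve."""
    lo, hi = center - half_window, center + half_window
    grid = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    if len(curve.strain) < 2 or curve.strain[0] > lo + 1e-12 or curve.max_strain < hi - 1e-12:
        raise WindowCoverageError(
            f"curve spans [{curve.strain[0] if len(curve.strain) else float('nan'):.4g}, "
            f"{curve.max_strain:.4g}] but the window needs [{lo:.4g}, {hi:.4g}]"
        )
    stresses = curve.interp(grid)
    slope = float(np.polyfit(grid, stresses, 1)[0])
    return TangentModulus(
        center_strain=center, value=slope, window=(lo, hi), n_points=len(grid)
    )


def model_curve(
    model: ReducedPolynomialModel,
    strain_max: float,
    step: float = 0.001,
    start: Optional[float] = None,
) -> StressStrainCurve:
    """Noise-free stress-strain curve sampled from a model (convenience for
    round-trip fitting and oracle comparisons)."""
    s0 = step if start is None else start
    grid = np.arange(s0, strain_max + step / 2, step)
    curve = StressStrainCurve(strain=grid, stress=nominal_stress(model, grid))
    curve.failure_strain = float(grid[-1])
    curve.failure_stress = float(curve.stress[-1])
    return curve
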