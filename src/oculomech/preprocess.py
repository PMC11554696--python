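"""Raw force-displacement records to engineering stress-strain curves.

A tensile record holds a time / clamp-displacement / force trace plus
specimen geometry and donor metadata.  The preprocessing chain mirrors the
bench protocol: the trace is re-referenced to the 0.05 N preload state that
eliminates slack (the clamp-to-clamp distance there defines the gauge
length), the five 5%-strain preconditioning cycles are stripped to leave
the final loading ramp, force and displacement are normalised by the
undeformed cross-section and gauge length, and the curve is truncated at
the ultimate stress where the specimen failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    DomainError,
    GeometryError,
    StructureError,
    UnusableSpecimenError,
)

__all__ = [
    "SpecimenGeometry",
    "SpecimenRecord",
    "StressStrainCurve",
    "MeanCurve",
    "zero_at_preload",
    "extract_test_ramp",
    "to_stress_strain",
    "truncate_at_failure",
    "mean_curve",
    "aspect_ratio",
    "cross_section_ratio",
]

DEFAULT_PRELOAD_N = 0.05


@dataclass(frozen=True)
class SpecimenGeometry:
    """Undeformed specimen geometry.

    ``gauge_length`` is the clamp edge-to-edge distance (mm) at the state
    the record's displacement origin refers to.  Exactly one of
    ``width + thickness`` (rectangular strip), ``diameter`` (native
    cylinder), or ``area`` (direct cross-section, e.g. from OCT) must
    determine the cross-section.
    """

    gauge_length: float
    width: Optional[float] = None
    thickness: Optional[float] = None
    diameter: Optional[float] = None
    area: Optional[float] = None

    def __post_init__(self):
        if self.gauge_length is None or self.gauge_length <= 0:
            raise GeometryError("gauge_length must be positive")
        rect = self.width is not None or self.thickness is not None
        ways = sum([rect, self.diameter is not None, self.area is not None])
        if ways != 1:
            raise GeometryError(
                "exactly one of width+thickness, diameter, or area must be given"
            )
        if rect and (self.width is None or self.thickness is None):
            raise GeometryError("rectangular specimens need both width and thickness")
        for name in ("width", "thickness", "diameter", "area"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise GeometryError(f"{name} must be positive")

    @property
    def shape(self) -> str:
        return "cylindrical" if self.diameter is not None else "rectangular"

    @property
    def cross_section(self) -> float:
        """Undeformed cross-sectional area A0 in mm^2."""
        if self.area is not None:
            return self.area
        if self.diameter is not None:
            return float(np.pi * (self.diameter / 2.0) ** 2)
        return self.width * self.thickness

    def with_gauge_length(self, gauge_length: float) -> "SpecimenGeometry":
        return replace(self, gauge_length=gauge_length)


@dataclass(eq=False)
class SpecimenRecord:
    """One specimen's raw tensile trace with geometry and metadata."""

    time: np.ndarray  # s, strictly increasing
    displacement: np.ndarray  # mm, relative to the trace origin
    force: np.ndarray  # N
    geometry: SpecimenGeometry
    region: str = ""
    orientation: str = ""
    donor_id: str = ""
    eye: str = ""
    group: str = ""
    age: float = float("nan")
    specimen_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = len(self.time)
        if len(self.displacement) != n or len(self.force) != n:
            raise DomainError("time, displacement, force must have equal length")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise DomainError("time must be strictly increasing")

    def sliced(self, start: int, stop: Optional[int] = None) -> "SpecimenRecord":
        return SpecimenRecord(
            time=self.time[start:stop],
            displacement=self.displacement[start:stop],
            force=self.force[start:stop],
            geometry=self.geometry,
            region=self.region,
            orientation=self.orientation,
            donor_id=self.donor_id,
            eye=self.eye,
            group=self.group,
            age=self.age,
            specimen_id=self.specimen_id,
        )


@dataclass(eq=False)
class StressStrainCurve:
    """Ordered engineering strain-stress samples of one loading ramp."""

    strain: np.ndarray  # dimensionless, strictly increasing
    stress: np.ndarray  # MPa
    failure_strain: Optional[float] = None
    failure_stress: Optional[float] = None

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if len(self.strain) != len(self.stress):
            raise DomainError("strain and stress must have equal length")
        if len(self.strain) >= 2 and not np.all(np.diff(self.strain) > 0):
            raise DomainError("strain must be strictly increasing")

    @property
    def max_strain(self) -> float:
        return float(self.strain[-1]) if len(self.strain) else float("nan")

    def interp(self, strain_grid) -> np.ndarray:
        """Linearly interpolated stresses at the requested strains."""
        return np.interp(strain_grid, self.strain, self.stress)


@dataclass(eq=False)
class MeanCurve:
    """Pointwise mean and SD of several curves on a common strain grid."""

    strain: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int

    @property
    def curve(self) -> StressStrainCurve:
        c = StressStrainCurve(strain=self.strain, stress=self.mean)
        c.failure_strain = float(self.strain[-1])
        c.failure_stress = float(self.mean[-1])
        return c


def _smooth(force: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(force) < window:
        return force
    kernel = np.ones(window) / window
    return np.convolve(force, kernel, mode="same")


def _noise_estimate(force: np.ndarray) -> float:
    """Robust force-noise SD from the head of the trace (the slack region):
    median absolute successive difference, detrended so a clean rising
    signal is not mistaken for noise."""
    head = force[: max(10, min(len(force) // 20, 200))]
    d = np.diff(head)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def zero_at_preload(
    record: SpecimenRecord,
    preload: float = DEFAULT_PRELOAD_N,
    smooth_window: Optional[int] = None,
) -> SpecimenRecord:
    """Re-reference a record to the preload state that removes slack.

    The first upward crossing of ``preload`` defines displacement zero and
    adds to the gauge length (the clamp separation at preload).  Samples
    are shifted, not discarded, so preconditioning structure survives;
    sub-zero strains are dropped later by :func:`to_stress_strain`.

    Detection is noise-robust: the force is smoothed with a window sized
    to the trace's own noise level (estimated from the slack region; no
    smoothing for clean traces), the first clearly-engaged sample (well
    above both preload and the noise band) is located, and the crossing is
    interpolated at the last sub-preload sample before it.  A record whose
    (smoothed) force never drops below the preload is returned unchanged;
    one that never reaches it is unusable.
    """
    f = record.force
    if len(f) < 2:
        raise UnusableSpecimenError("record too short")
    noise = _noise_estimate(f)
    if smooth_window is None:
        if noise < preload / 5:
            smooth_window = 1
        else:
            smooth_window = int(min(31, max(3, np.ceil((noise / (preload / 3)) ** 2))))
            smooth_window += 1 - smooth_window % 2  # odd
    fs = _smooth(f, smooth_window)
    if fs.max() < preload:
        raise UnusableSpecimenError(
            f"force never reaches the {preload} N preload (max {fs.max():.4g} N)"
        )
    # first clearly-engaged sample: above preload and above the noise band
    hi = max(2 * preload, preload + 5 * noise / np.sqrt(smooth_window))
    engaged = np.nonzero(fs >= hi)[0]
    k = int(engaged[0]) if len(engaged) else int(np.argmax(fs))
    if noise >= preload / 2:
        # noise comparable to the preload: the crossing itself is buried, so
        # extrapolate the first clean engaged band linearly back to the
        # preload level (slightly late on a stiffening toe, but consistent)
        band_hi = np.nonzero(fs[k:] >= 3 * hi)[0]
        k2 = k + int(band_hi[0]) if len(band_hi) else min(k + 30, len(fs) - 1)
        k2 = max(k2, k + 3)
        d_band = record.displacement[k : k2 + 1]
        f_band = f[k : k2 + 1]
        slope, intercept = np.polyfit(d_band, f_band, 1)
        if slope <= 0:
            raise UnusableSpecimenError("force does not rise at engagement")
        d0 = (preload - intercept) / slope
        d0 = float(np.clip(d0, record.displacement[0], record.displacement[k]))
    else:
        below = np.nonzero(fs[:k] < preload)[0]
        if len(below) == 0:
            return record  # already at/above preload from the start
        j = int(below[-1])  # last sub-preload sample before engagement
        f0, f1 = fs[j], fs[j + 1]
        w = (preload - f0) / (f1 - f0) if f1 > f0 else 1.0
        d0 = record.displacement[j] + w * (
            record.displacement[j + 1] - record.displacement[j]
        )
    out = record.sliced(0)
    out.displacement = record.displacement - d0
    out.geometry = record.geometry.with_gauge_length(record.geometry.gauge_length + d0)
    return out


def extract_test_ramp(
    record: SpecimenRecord,
    n_precycles: int = 5,
    precycle_strain: float = 0.05,
) -> SpecimenRecord:
    """Strip preconditioning cycles, returning the final loading ramp.

    Cycles are detected as local maxima of the (noise-free) clamp
    displacement; the ramp starts at the displacement minimum after the
    last cycle peak.  A mismatch between detected and expected cycle count
    raises a :class:`StructureError` carrying the detected count.
    """
    if n_precycles < 0:
        raise DomainError("n_precycles must be non-negative")
    if n_precycles == 0:
        return record
    peaks, _ = find_peaks(record.displacement)
    if len(peaks) != n_precycles:
        raise StructureError(
            f"expected {n_precycles} preconditioning cycles, detected {len(peaks)}",
            detected_cycles=len(peaks),
        )
    last_peak = peaks[-1]
    start = last_peak + int(np.argmin(record.displacement[last_peak:]))
    return record.sliced(start)


def to_stress_strain(record: SpecimenRecord) -> StressStrainCurve:
    """Engineering stress-strain curve of a zeroed, ramp-only record.

    ``stress = F / A0`` (MPa for N and mm^2), ``strain = d / L0`` clamp to
    clamp.  Samples at negative strain are dropped (with an interpolated
    sample inserted at exactly zero strain), and non-increasing strain
    samples are discarded so the curve is strictly ordered.
    """
    area = record.geometry.cross_section
    if area <= 0:
        raise GeometryError("cross-section must be positive")
    L0 = record.geometry.gauge_length
    strain = record.displacement / L0
    stress = record.force / area
    if strain[0] < 0:
        above = strain >= 0
        if not above.any():
            raise DomainError("record contains no non-negative strain samples")
        i = int(np.argmax(above))
        if i > 0 and strain[i] > 0:
            w = (0.0 - strain[i - 1]) / (strain[i] - strain[i - 1])
            s0 = stress[i - 1] + w * (stress[i] - stress[i - 1])
            strain = np.concatenate([[0.0], strain[i:]])
            stress = np.concatenate([[s0], stress[i:]])
        else:
            strain, stress = strain[i:], stress[i:]
    keep = np.concatenate([[True], np.diff(np.maximum.accumulate(strain)) > 0])
    return StressStrainCurve(strain=strain[keep], stress=stress[keep])


def truncate_at_failure(curve: StressStrainCurve) -> StressStrainCurve:
    """Cut a curve at its ultimate stress (global maximum) and record the
    failure point; a strictly rising curve is returned intact with the last
    sample as its failure point."""
    if len(curve.strain) == 0:
        raise DomainError("empty curve")
    i = int(np.argmax(curve.stress))
    out = StressStrainCurve(strain=curve.strain[: i + 1], stress=curve.stress[: i + 1])
    out.failure_strain = float(curve.strain[i])
    out.failure_stress = float(curve.stress[i])
    return out


def mean_curve(
    curves: Sequence[StressStrainCurve], grid_step: float = 0.001
) -> MeanCurve:
    """Pointwise mean and SD of curves interpolated onto a common strain
    grid from 0 to the least failure strain among them.

    SD uses the n-1 denominator and is zero for a single curve.
    """
    if len(curves) == 0:
        raise DomainError("mean_curve needs at least one curve")
    stop = min(
        c.failure_strain if c.failure_strain is not None else c.max_strain
        for c in curves
    )
    grid = np.arange(0.0, stop + grid_step / 2, grid_step)
    stacked = np.vstack([c.interp(grid) for c in curves])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean)
    return MeanCurve(strain=grid, mean=mean, sd=sd, n=len(curves))


def aspect_ratio(length: float, width: float) -> float:
    """Specimen length-to-width ratio, reported to two decimals."""
    if length <= 0 or width <= 0:
        raise DomainError("length and width must be positive")
    return round(length / width, 2)


def cross_section_ratio(diameter_a: float, diameter_b: float) -> int:
    """Cross-section of a relative to b as an integer percent,
    ``100 * (d_a / d_b)**2`` — e.g. atrophic vs healthy optic nerve."""
    if diameter_a <= 0 or diameter_b <= 0:
        raise DomainError("diameters must be positive")
    return int(round(100.0 * (diameter_a / diameter_b) ** 2))
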