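"""End-to-end pipeline: simulate/read -> preprocess -> fit -> moduli ->
compare -> correlate -> report, with stable tabular I/O.

All strains are dimensionless fractions internally; tables use one CSV
dialect (comma, UTF-8, ``.`` decimal, header row) with stable column order
and 6-significant-digit numeric formatting, so a rerun under the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from . import reference as ref
from .errors import (
    ConfigError,
    OculomechError,
    StructureError,
    UnusableSpecimenError,
    ValidationError,
    WindowCoverageError,
)
from .fitting import (
    FitResult,
    fit_reduced_polynomial,
    select_order,
    tangent_modulus_windowed,
)
from .preprocess import (
    SpecimenGeometry,
    SpecimenRecord,
    StressStrainCurve,
    extract_test_ramp,
    mean_curve,
    to_stress_strain,
    truncate_at_failure,
    zero_at_preload,
)
from .stats import (
    format_p,
    gee_curve_comparison,
    regional_correlation,
    two_sample_test,
)
from .synthetic import CohortConfig, CohortDataset, LoadingProtocol, generate_cohort

logger = logging.getLogger("oculomech")

__all__ = [
    "PipelineConfig",
    "write_cohort",
    "read_cohort",
    "preprocess_cohort",
    "fit_region_models",
    "eye_moduli",
    "compare_groups",
    "correlation_table",
    "gee_table",
    "run_pipeline",
]

RAW_COLUMNS = ["time_s", "displacement_mm", "force_N"]


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline parameters; defaults are the bench protocol values."""

    preload_n: float = 0.05
    n_precycles: int = 5
    precycle_strain: float = 0.05
    rate_mm_s: float = 0.1
    grid_step: float = 0.001
    tangent_centers: Tuple[float, float] = (0.03, 0.07)
    tangent_half_window: float = 0.007
    tangent_step: float = 0.002
    fit_order: int = 2
    poisson: float = 0.49
    test_variant: str = "welch"
    gee_formula: str = "stress ~ strain + I(strain ** 2) + C(group) + age"
    gee_strain_grid: Tuple[float, float, float] = (0.005, 0.10, 0.005)
    seed: int = 0

    def __post_init__(self):
        problems = []
        if not 0.0 < self.poisson < 0.5:
            problems.append(f"poisson must lie in (0, 0.5), got {self.poisson}")
        if self.preload_n <= 0:
            problems.append("preload_n must be positive")
        if self.grid_step <= 0:
            problems.append("grid_step must be positive")
        if self.fit_order < 1:
            problems.append("fit_order must be >= 1")
        if self.test_variant not in ("welch", "student"):
            problems.append(f"unknown test_variant {self.test_variant!r}")
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tangent_centers", "gee_strain_grid"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    """Round floats to 6 significant digits for stable output."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: float(f"{v:.6g}") if np.isfinite(v) else v
            )
    return out


def write_table(df: pd.DataFrame, path) -> None:
    _fmt(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort I/O


def write_cohort(dataset: CohortDataset, out_dir) -> None:
    """Write a cohort as per-specimen raw CSVs plus manifest and
    ground-truth CSVs."""
    out = Path(out_dir)
    raw = out / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    for rec in dataset.records:
        df = pd.DataFrame(
            {
                "time_s": rec.time,
                "displacement_mm": rec.displacement,
                "force_N": rec.force,
            }
        )
        _fmt(df).to_csv(raw / f"{rec.specimen_id}.csv", index=False)
    write_table(dataset.manifest, out / "manifest.csv")
    write_table(dataset.truth, out / "truth.csv")


def read_cohort(in_dir) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort`, validating the
    manifest before touching any trace."""
    root = Path(in_dir)
    manifest_path = root / "manifest.csv"
    if not manifest_path.exists():
        raise ValidationError(f"missing manifest: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {
        "specimen_id", "donor_id", "eye", "group", "age", "region",
        "orientation", "gauge_length_mm",
    }
    problems = [f"manifest missing column {c}" for c in sorted(required - set(manifest.columns))]
    records: List[SpecimenRecord] = []
    if not problems:
        for _, row in manifest.iterrows():
            path = root / "raw" / f"{row.specimen_id}.csv"
            if not path.exists():
                problems.append(f"missing trace for specimen {row.specimen_id}")
                continue
            df = pd.read_csv(path)
            missing = set(RAW_COLUMNS) - set(df.columns)
            if missing:
                problems.append(
                    f"{row.specimen_id}: missing columns {sorted(missing)}"
                )
                continue
            geom_kwargs = dict(gauge_length=row.gauge_length_mm)
            for src, dst in (
                ("width_mm", "width"),
                ("thickness_mm", "thickness"),
                ("diameter_mm", "diameter"),
                ("area_mm2", "area"),
            ):
                v = row.get(src)
                if v is not None and np.isfinite(v):
                    geom_kwargs[dst] = float(v)
            try:
                geometry = SpecimenGeometry(**geom_kwargs)
            except OculomechError as exc:
                problems.append(f"{row.specimen_id}: {exc}")
                continue
            records.append(
                SpecimenRecord(
                    time=df["time_s"].to_numpy(),
                    displacement=df["displacement_mm"].to_numpy(),
                    force=df["force_N"].to_numpy(),
                    geometry=geometry,
                    region=row.region,
                    orientation=row.orientation,
                    donor_id=str(row.donor_id),
                    eye=row.eye,
                    group=row.group,
                    age=float(row.age),
                    specimen_id=row.specimen_id,
                )
            )
    if problems:
        raise ValidationError(problems)
    truth_path = root / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    return CohortDataset(records=records, manifest=manifest, truth=truth)


# ---------------------------------------------------------------------------
# pipeline stages


def preprocess_cohort(
    dataset: CohortDataset, config: PipelineConfig = PipelineConfig()
) -> Tuple[Dict[str, StressStrainCurve], pd.DataFrame]:
    """Run every record through preload zeroing, ramp extraction, stress-
    strain conversion, and failure truncation.

    Returns the curves keyed by specimen id and a per-specimen summary
    (including failure point and a status column; specimens that cannot be
    processed are reported, not fatal — mirroring the occasional technical
    failures of bench testing).
    """
    curves: Dict[str, StressStrainCurve] = {}
    rows = []
    for rec in dataset.records:
        status = "ok"
        failure_strain = failure_stress = np.nan
        try:
            zeroed = zero_at_preload(rec, preload=config.preload_n)
            ramp = extract_test_ramp(
                zeroed,
                n_precycles=config.n_precycles,
                precycle_strain=config.precycle_strain,
            )
            curve = truncate_at_failure(to_stress_strain(ramp))
            curves[rec.specimen_id] = curve
            failure_strain, failure_stress = curve.failure_strain, curve.failure_stress
        except OculomechError as exc:
            status = f"{type(exc).__name__}: {exc}"
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "donor_id": rec.donor_id,
                "eye": rec.eye,
                "group": rec.group,
                "age": rec.age,
                "region": rec.region,
                "failure_strain": failure_strain,
                "failure_stress_MPa": failure_stress,
                "status": status,
            }
        )
    return curves, pd.DataFrame(rows)


def curves_long_table(
    curves: Dict[str, StressStrainCurve], manifest: pd.DataFrame
) -> pd.DataFrame:
    """Tidy (specimen_id, strain, stress_MPa) table of all curves."""
    meta = manifest.set_index("specimen_id")
    frames = []
    for sid, curve in curves.items():
        frames.append(
            pd.DataFrame(
                {"specimen_id": sid, "strain": curve.strain, "stress_MPa": curve.stress}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["specimen_id", "strain", "stress_MPa"])
    return pd.concat(frames, ignore_index=True)


def fit_region_models(
    curves: Dict[str, StressStrainCurve],
    manifest: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Fit the hyperelastic model to the mean curve of each region and
    group; returns a coefficient table (region, group, C10, C20, D1, D2,
    R2, n specimens)."""
    meta = manifest.set_index("specimen_id")
    rows = []
    for (region, group), ids in _group_specimens(curves, meta):
        mc = mean_curve([curves[i] for i in ids], grid_step=config.grid_step)
        fit = fit_reduced_polynomial(
            mc.curve, order=config.fit_order, poisson=config.poisson
        )
        rows.append(
            {
                "region": region,
                "group": group,
                "C10_MPa": fit.model.c10,
                "C20_MPa": fit.model.c20,
                "D1_per_MPa": fit.model.d1,
                "D2_per_MPa": 0.0,
                "R2": fit.r_squared,
                "stable": fit.stable,
                "n_specimens": len(ids),
            }
        )
    return pd.DataFrame(rows)


def _group_specimens(curves, meta):
    keys = {}
    for sid in curves:
        region, group = meta.loc[sid, "region"], meta.loc[sid, "group"]
        keys.setdefault((region, group), []).append(sid)
    ordered = sorted(
        keys.items(),
        key=lambda kv: (ref.REGIONS.index(kv[0][0]) if kv[0][0] in ref.REGIONS else 99, kv[0][1]),
    )
    return ordered


def eye_moduli(
    curves: Dict[str, StressStrainCurve],
    manifest: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Eye-level tangent moduli: specimen curves are averaged per eye and
    region, then the windowed OLS slope is taken at each centre strain.

    Eyes whose averaged curve cannot cover a window (failure before the
    window end) are omitted for that centre, mirroring per-region specimen
    attrition.
    """
    meta = manifest.set_index("specimen_id")
    by_eye: Dict[tuple, list] = {}
    for sid in curves:
        key = (
            meta.loc[sid, "donor_id"],
            meta.loc[sid, "eye"],
            meta.loc[sid, "group"],
            float(meta.loc[sid, "age"]),
            meta.loc[sid, "region"],
        )
        by_eye.setdefault(key, []).append(sid)
    rows = []
    for (donor, eye, group, age, region), ids in sorted(by_eye.items()):
        mc = mean_curve([curves[i] for i in ids], grid_step=config.grid_step)
        for center in config.tangent_centers:
            try:
                tm = tangent_modulus_windowed(
                    mc.curve,
                    center,
                    half_window=config.tangent_half_window,
                    step=config.tangent_step,
                )
            except WindowCoverageError:
                continue
            rows.append(
                {
                    "donor_id": donor,
                    "eye": eye,
                    "group": group,
                    "age": age,
                    "region": region,
                    "center_strain": center,
                    "value": tm.value,
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    moduli: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Group comparison table of eye-level tangent moduli per region and
    centre strain: n, mean, SD, CV per group plus the two-sample p-value."""
    rows = []
    for (region, center), sub in sorted(
        moduli.groupby(["region", "center_strain"]),
        key=lambda kv: (ref.REGIONS.index(kv[0][0]) if kv[0][0] in ref.REGIONS else 99, kv[0][1]),
    ):
        groups = sorted(sub["group"].unique())
        if len(groups) != 2:
            continue
        a = sub.loc[sub["group"] == groups[0], "value"].to_numpy()
        b = sub.loc[sub["group"] == groups[1], "value"].to_numpy()
        res = two_sample_test(a, b, variant=config.test_variant, region=region)
        rows.append(
            {
                "region": region,
                "center_strain": center,
                "group_a": groups[0],
                "n_a": len(a),
                "mean_a": a.mean(),
                "sd_a": a.std(ddof=1),
                "cv_a": a.std(ddof=1) / a.mean(),
                "group_b": groups[1],
                "n_b": len(b),
                "mean_b": b.mean(),
                "sd_b": b.std(ddof=1),
                "cv_b": b.std(ddof=1) / b.mean(),
                "t": res.t_statistic,
                "df": res.degrees_of_freedom,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def correlation_table(
    moduli: pd.DataFrame, center: float = 0.03
) -> pd.DataFrame:
    """Fig-3-style long table of pairwise regional Pearson correlations of
    eye-level moduli at one centre strain (r, r^2, n pairs, p, verbal
    strength)."""
    sub = moduli[moduli["center_strain"] == center]
    mat = regional_correlation(sub, regions=ref.REGIONS)
    rows = []
    for i, ra in enumerate(mat.regions):
        for rb in mat.regions[i + 1 :]:
            r = mat.r.loc[ra, rb]
            rows.append(
                {
                    "region_a": ra,
                    "region_b": rb,
                    "r": r,
                    "r_squared": r**2 if np.isfinite(r) else np.nan,
                    "n_pairs": int(mat.n_pairs.loc[ra, rb]),
                    "p_value": mat.p.loc[ra, rb],
                    "strength": mat.strength().loc[ra, rb],
                }
            )
    return pd.DataFrame(rows)


def gee_long_data(
    curves: Dict[str, StressStrainCurve],
    manifest: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    region: Optional[str] = None,
) -> pd.DataFrame:
    """Resample curves of one region onto the common GEE strain grid and
    return long-format rows (donor_id, eye, group, age, strain, stress)."""
    lo, hi, step = config.gee_strain_grid
    grid = np.arange(lo, hi + step / 2, step)
    meta = manifest.set_index("specimen_id")
    frames = []
    for sid, curve in curves.items():
        if region is not None and meta.loc[sid, "region"] != region:
            continue
        if curve.max_strain < hi:  # cannot cover the grid: excluded
            continue
        frames.append(
            pd.DataFrame(
                {
                    "donor_id": meta.loc[sid, "donor_id"],
                    "eye": meta.loc[sid, "eye"],
                    "group": meta.loc[sid, "group"],
                    "age": float(meta.loc[sid, "age"]),
                    "strain": grid,
                    "stress": curve.interp(grid),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["donor_id", "eye", "group", "age", "strain", "stress"]
        )
    return pd.concat(frames, ignore_index=True)


def gee_table(
    curves: Dict[str, StressStrainCurve],
    manifest: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Table-2-style GEE p-values (group effect, age effect) per region."""
    rows = []
    regions = [r for r in ref.REGIONS if r in set(manifest["region"])]
    for region in regions:
        data = gee_long_data(curves, manifest, config, region=region)
        if data.empty or data["group"].nunique() < 2:
            continue
        res = gee_curve_comparison(data, formula=config.gee_formula)
        rows.append(
            {
                "region": region,
                "p_group": res.p_group,
                "p_group_printed": res.p_group_formatted,
                "p_age": res.p_age,
                "p_age_printed": res.p_age_formatted,
                "n_donors": res.n_clusters,
                "n_obs": res.n_obs,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full pipeline


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    cohort_config: Optional[CohortConfig] = None,
    in_dir=None,
    out_dir="results",
) -> dict:
    """Execute the full pipeline and write the report bundle.

    Either simulate a cohort (``cohort_config``) or read one from
    ``in_dir``.  Writes: curve table, specimen summary, hyperelastic
    parameter table, eye-level moduli, group comparison, GEE table,
    correlation table, and a plain-text report.  Deterministic under fixed
    seed and config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort_config is not None:
        dataset = generate_cohort(cohort_config)
        write_cohort(dataset, out / "cohort")
    elif in_dir is not None:
        dataset = read_cohort(in_dir)
    else:
        raise ValidationError("either cohort_config or in_dir is required")

    curves, summary = preprocess_cohort(dataset, config)
    write_table(summary, out / "specimens.csv")
    write_table(curves_long_table(curves, dataset.manifest), out / "curves.csv")
    params = fit_region_models(curves, dataset.manifest, config)
    write_table(params, out / "hyperelastic_parameters.csv")
    moduli = eye_moduli(curves, dataset.manifest, config)
    write_table(moduli, out / "tangent_moduli.csv")
    comparison = compare_groups(moduli, config) if moduli["group"].nunique() > 1 else pd.DataFrame()
    if len(comparison):
        write_table(comparison, out / "group_comparison.csv")
    gee = (
        gee_table(curves, dataset.manifest, config)
        if dataset.manifest["group"].nunique() > 1
        else pd.DataFrame()
    )
    if len(gee):
        write_table(gee, out / "gee_pvalues.csv")
    corr = correlation_table(moduli, center=config.tangent_centers[0])
    write_table(corr, out / "regional_correlation.csv")

    report = _render_report(config, dataset, summary, params, comparison, gee, corr)
    (out / "report.txt").write_text(report)
    return {
        "curves": curves,
        "summary": summary,
        "parameters": params,
        "moduli": moduli,
        "comparison": comparison,
        "gee": gee,
        "correlation": corr,
        "report": report,
    }


def _render_report(config, dataset, summary, params, comparison, gee, corr) -> str:
    lines = [
        "oculomech tensile-analysis report",
        f"version: {__version__}",
        f"config hash: {config.config_hash()}",
        f"seed: {config.seed}",
        f"specimens: {len(dataset.records)} "
        f"({int((summary['status'] == 'ok').sum())} processed)",
        "",
        "Hyperelastic parameters (per region/group, fit to mean curve):",
        params.to_string(index=False, float_format=lambda v: f"{v:.6g}"),
    ]
    if len(comparison):
        lines += [
            "",
            "Tangent-modulus group comparison:",
            comparison.to_string(index=False, float_format=lambda v: f"{v:.6g}"),
        ]
    if len(gee):
        lines += [
            "",
            "GEE curve comparison (donor-clustered, age covariate):",
            gee.to_string(index=False, float_format=lambda v: f"{v:.6g}"),
        ]
    if len(corr):
        lines += [
            "",
            "Regional correlation of 3% tangent moduli:",
            corr.to_string(index=False, float_format=lambda v: f"{v:.6g}"),
        ]
    return "\n".join(lines) + "\n"
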