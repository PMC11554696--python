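"""Cohort-level statistics for tangent moduli and stress-strain curves.

Covers the study's statistical toolkit: coefficients of variation,
two-sample comparisons of tangent moduli (Welch by default, pooled-variance
Student as an option; both accept raw samples or printed ``(n, mean, SD)``
summaries), donor-clustered generalized estimating equations over complete
stress-strain curves with donor age as covariate, and the mutual Pearson
correlation matrix of regional 3%-strain moduli across eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, ValidationError

__all__ = [
    "GroupComparisonResult",
    "RegionalCorrelationMatrix",
    "GEEComparison",
    "coefficient_of_variation",
    "two_sample_test",
    "regional_correlation",
    "gee_curve_comparison",
    "format_p",
    "correlation_strength",
]

Summary = Tuple[int, float, float]  # (n, mean, sd)


def format_p(p: float) -> str:
    """Three-decimal p-value string; values below 0.001 print as ``0.000``
    (the convention of clustered-regression software output)."""
    return "0.000" if p < 0.001 else f"{p:.3f}"


def correlation_strength(r: float) -> str:
    """Verbal scale for a Pearson coefficient: strong >= 0.5, moderate
    0.3-0.5, weak < 0.3 (absolute value)."""
    a = abs(r)
    return "strong" if a >= 0.5 else "moderate" if a >= 0.3 else "weak"


def coefficient_of_variation(
    values: Optional[Sequence[float]] = None,
    *,
    mean: Optional[float] = None,
    sd: Optional[float] = None,
) -> float:
    """SD divided by mean, with the n-1 SD denominator for raw samples.

    Accepts either a sample of values (n >= 2 required) or a printed
    ``mean=``/``sd=`` summary.
    """
    if values is not None:
        x = np.asarray(values, dtype=float)
        if len(x) < 2:
            raise DomainError("CV needs at least two values")
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
    elif mean is None or sd is None:
        raise DomainError("provide values or both mean and sd")
    if mean == 0:
        raise DomainError("CV undefined for zero mean")
    return sd / mean


@dataclass(frozen=True)
class GroupComparisonResult:
    """Two-sample comparison of tangent moduli (or any scalar measure)."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str
    n: Tuple[int, int]
    mean_per_group: Tuple[float, float]
    sd_per_group: Tuple[float, float]
    region: str = ""
    center_strain: Optional[float] = None

    @property
    def cv_per_group(self) -> Tuple[float, float]:
        return tuple(s / m for s, m in zip(self.sd_per_group, self.mean_per_group))


def _summarize(x: Union[Sequence[float], Summary]) -> Summary:
    if isinstance(x, tuple) and len(x) == 3 and np.isscalar(x[0]):
        n, m, s = int(x[0]), float(x[1]), float(x[2])
    else:
        arr = np.asarray(x, dtype=float)
        n, m, s = len(arr), float(arr.mean()) if len(arr) else np.nan, (
            float(arr.std(ddof=1)) if len(arr) > 1 else np.nan
        )
    if n < 2:
        raise DomainError("each group needs n >= 2")
    return n, m, s


def two_sample_test(
    a: Union[Sequence[float], Summary],
    b: Union[Sequence[float], Summary],
    variant: str = "welch",
    region: str = "",
    center_strain: Optional[float] = None,
) -> GroupComparisonResult:
    """Two-tailed two-sample t-test from raw samples or ``(n, mean, sd)``
    summaries.

    ``variant='welch'`` (default) uses the unequal-variance statistic with
    Satterthwaite degrees of freedom; ``variant='student'`` pools the
    variances with ``n1 + n2 - 2`` degrees of freedom.
    """
    n1, m1, s1 = _summarize(a)
    n2, m2, s2 = _summarize(b)
    if variant == "welch":
        se2 = s1**2 / n1 + s2**2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1))
    elif variant == "student":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        raise DomainError(f"unknown test variant {variant!r}")
    p = float(2 * sps.t.sf(abs(t), df))
    return GroupComparisonResult(
        t_statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=p,
        variant=variant,
        n=(n1, n2),
        mean_per_group=(m1, m2),
        sd_per_group=(s1, s2),
        region=region,
        center_strain=center_strain,
    )


@dataclass(eq=False)
class RegionalCorrelationMatrix:
    """Pairwise-complete Pearson correlations of regional moduli across eyes."""

    regions: list
    r: pd.DataFrame  # Pearson coefficients, NaN where undefined (< 3 pairs)
    n_pairs: pd.DataFrame  # complete eye counts per cell
    p: pd.DataFrame  # two-tailed significance via t = r sqrt((n-2)/(1-r^2))

    def strength(self) -> pd.DataFrame:
        return self.r.map(
            lambda v: correlation_strength(v) if np.isfinite(v) else "undefined"
        )

    def r_squared(self) -> pd.DataFrame:
        """Shared-variance matrix r**2 (reported alongside r, since r itself
        is not a proportion of variance)."""
        return self.r**2


def regional_correlation(
    samples: pd.DataFrame,
    regions: Optional[Sequence[str]] = None,
    min_pairs: int = 3,
) -> RegionalCorrelationMatrix:
    """Mutual Pearson correlation matrix of per-eye tangent moduli.

    ``samples`` needs columns ``donor_id``, ``eye``, ``region``, ``value``
    (one modulus per eye per region, typically at 3% strain).  Each cell
    uses the pairwise-complete set of eyes; cells with fewer than
    ``min_pairs`` complete eyes are flagged undefined (NaN).
    """
    required = {"donor_id", "eye", "region", "value"}
    missing = required - set(samples.columns)
    if missing:
        raise ValidationError([f"missing column {c}" for c in sorted(missing)])
    wide = samples.pivot_table(
        index=["donor_id", "eye"], columns="region", values="value", aggfunc="mean"
    )
    if regions is None:
        regions = list(wide.columns)
    else:
        regions = [r for r in regions if r in wide.columns]
    wide = wide[regions]
    present = wide.notna().astype(int)
    n_pairs = pd.DataFrame(
        present.T.values @ present.values, index=regions, columns=regions
    )
    r = wide.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(r.values, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n = n_pairs.values.astype(float)
        rv = r.values
        t = rv * np.sqrt(np.maximum(n - 2, 0) / np.maximum(1 - rv**2, 1e-300))
        p = 2 * sps.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = pd.DataFrame(p, index=regions, columns=regions)
    p.values[np.isnan(rv)] = np.nan
    np.fill_diagonal(p.values, 0.0)
    return RegionalCorrelationMatrix(regions=list(regions), r=r, n_pairs=n_pairs, p=p)


@dataclass(frozen=True)
class GEEComparison:
    """Marginal-regression comparison of complete stress-strain curves."""

    p_group: float
    p_age: float
    params: dict
    n_clusters: int
    n_obs: int

    @property
    def p_group_formatted(self) -> str:
        return format_p(self.p_group)

    @property
    def p_age_formatted(self) -> str:
        return format_p(self.p_age)


def gee_curve_comparison(
    long_data: pd.DataFrame,
    formula: str = "stress ~ strain + I(strain ** 2) + C(group) + age",
    groups: str = "donor_id",
    cov_type: str = "bias_reduced",
    cov_struct=None,
) -> GEEComparison:
    """Donor-clustered GEE of stress on strain, group, and age.

    Fits a marginal Gaussian model with exchangeable working correlation
    clustered on donor (both eyes of one donor share a cluster) and robust
    sandwich standard errors; returns two-tailed Wald p-values for the
    group contrast and the age covariate.  The default mean model is
    quadratic in strain; pass another ``formula`` to change it.

    With cohorts of only a dozen donors the uncorrected sandwich is
    anticonservative, so the default covariance is the bias-reduced
    (Mancl-DeRouen) sandwich; pass ``cov_type='robust'`` for the plain
    estimator.
    """
    import statsmodels.formula.api as smf
    from statsmodels.genmod.cov_struct import Exchangeable
    from statsmodels.genmod.families import Gaussian

    problems = []
    for col in ("stress", "strain", "group", "age", groups):
        if col not in long_data.columns:
            problems.append(f"missing column {col}")
    if problems:
        raise ValidationError(problems)
    numeric = long_data[["stress", "strain", "age"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(numeric)):
        raise ValidationError("non-finite values in stress/strain/age")
    if long_data[groups].nunique() < 2:
        raise ValidationError("GEE needs at least two donor clusters")
    model = smf.gee(
        formula,
        groups=groups,
        data=long_data,
        cov_struct=Exchangeable() if cov_struct is None else cov_struct,
        family=Gaussian(),
    )
    res = model.fit(cov_type=cov_type)
    pvals = res.pvalues
    group_terms = [k for k in pvals.index if "group" in k.lower() and "Intercept" not in k]
    if not group_terms:
        raise ValidationError("formula contains no group term")
    return GEEComparison(
        p_group=float(pvals[group_terms[0]]),
        p_age=float(pvals["age"]) if "age" in pvals.index else float("nan"),
        params=dict(res.params),
        n_clusters=int(long_data[groups].nunique()),
        n_obs=int(len(long_data)),
    )
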