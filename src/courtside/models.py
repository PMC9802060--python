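"""Inferential models: post-on-pre regressions, minutes-controlled and
covariate-adjusted variants, restricted cubic splines, and one-way ANOVA on
return-to-sport days.

The prognostic regressions are separate ordinary-least-squares models per
post-injury year: the post-year season metric is regressed on the pre-injury
season metric, and the slope is the reported coefficient (a value near 0.5
reads as "the typical player retains half of a marginal pre-injury unit").
Confidence intervals use the t distribution with n - p degrees of freedom;
p-values are two-sided and uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearDesignError, ConfigError, DegenerateDesignError

_COND_LIMIT = 1e10


@dataclass
class RegressionResult:
    model_id: str
    metric: str
    year: int
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    covariates: list[str] = field(default_factory=list)
    intercept: float = float("nan")
    notes: list[str] = field(default_factory=list)


@dataclass
class AnovaResult:
    group_labels: list[str]
    group_means: list[float]
    group_sds: list[float]
    group_ns: list[int]
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


@dataclass
class SplineBasis:
    """Restricted cubic spline basis (Harrell parameterization).

    With k knots the design has k-1 columns: the linear term plus k-2
    truncated-cubic combinations, each constructed so the fitted function is
    linear beyond the boundary knots.  Nonlinear columns are normalized by
    (t_k - t_1)^2 so coefficients share the linear term's scale.
    """

    knots: np.ndarray

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        if knots.ndim != 1 or len(knots) < 3:
            raise ConfigError("a restricted cubic spline needs at least 3 knots")
        if np.any(np.diff(knots) <= 0):
            raise ConfigError(f"knots must be strictly increasing; got {knots.tolist()}")
        self.knots = knots

    @property
    def n_columns(self) -> int:
        return len(self.knots) - 1

    def transform(self, x) -> np.ndarray:
        """Design columns (without intercept) evaluated at x."""
        x = np.asarray(x, dtype=float)
        t = self.knots
        k = len(t)
        norm = (t[-1] - t[0]) ** 2

        def cube(u):
            return np.maximum(u, 0.0) ** 3

        cols = [x]
        for j in range(k - 2):
            term = (
                cube(x - t[j])
                - cube(x - t[k - 2]) * (t[-1] - t[j]) / (t[-1] - t[k - 2])
                + cube(x - t[-1]) * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
            )
            cols.append(term / norm)
        return np.column_stack(cols)


#: Harrell's conventional outer/inner knot quantiles by knot count.
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def rcs_design(x, n_knots: int = 3) -> tuple[SplineBasis, np.ndarray]:
    """Place knots at conventional quantiles of x and build the design."""
    x = np.asarray(x, dtype=float)
    if n_knots not in _KNOT_QUANTILES:
        raise ConfigError(f"n_knots must be one of {sorted(_KNOT_QUANTILES)}; got {n_knots}")
    if len(np.unique(x)) < n_knots:
        raise ConfigError("need at least n_knots distinct x values")
    knots = np.quantile(x, _KNOT_QUANTILES[n_knots])
    if np.any(np.diff(knots) <= 0):
        raise ConfigError("duplicate knots: x quantiles are not distinct")
    basis = SplineBasis(knots)
    return basis, basis.transform(x)


@dataclass
class RcsFit:
    basis: SplineBasis
    coefficients: np.ndarray  # intercept first, then basis columns

    def predict(self, x) -> np.ndarray:
        design = self.basis.transform(x)
        return self.coefficients[0] + design @ self.coefficients[1:]


def fit_rcs(x, y, n_knots: int = 3) -> RcsFit:
    """Least-squares restricted-cubic-spline fit of y on x."""
    basis, design = rcs_design(x, n_knots)
    X = np.column_stack([np.ones(len(design)), design])
    coef, *_ = np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)
    return RcsFit(basis, coef)


def fit_post_pre(
    pairs, metric: str = "", year: int = 1, model_id: str = "post_on_pre"
) -> RegressionResult:
    """OLS of the post-season metric on the pre-season metric (with intercept).

    Closed-form normal equations: slope = cov(pre, post) / var(pre); the CI
    is t-based with n - 2 degrees of freedom.  A pre-season metric with zero
    variance is a degenerate design.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ConfigError("pairs must be an (n, 2) array of (pre, post) values")
    arr = arr[~np.isnan(arr).any(axis=1)]
    n = len(arr)
    if n < 3:
        raise DegenerateDesignError(f"need at least 3 complete pairs; got {n}")
    x, y = arr[:, 0], arr[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateDesignError("pre-season metric has zero variance")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 / sxx))
    tcrit = float(stats.t.ppf(0.975, dof))
    if se > 0:
        p = float(2.0 * stats.t.sf(abs(slope / se), dof))
    else:
        p = 0.0 if slope != 0 else 1.0
    return RegressionResult(
        model_id=model_id,
        metric=metric,
        year=year,
        coefficient=slope,
        ci_low=slope - tcrit * se,
        ci_high=slope + tcrit * se,
        p_value=p,
        n=n,
        covariates=["pre"],
        intercept=intercept,
    )


def _ols_report_first(
    y: np.ndarray,
    columns: dict[str, np.ndarray],
    report: str,
    model_id: str,
    metric: str,
    year: int,
    min_n: int,
) -> RegressionResult:
    """OLS with named columns; reports the coefficient named ``report``.

    Constant (zero-variance) covariates other than the reported one are
    dropped with a note; a numerically collinear design is an error.
    """
    notes: list[str] = []
    kept: dict[str, np.ndarray] = {}
    for name, col in columns.items():
        if name != report and np.ptp(col) == 0.0:
            notes.append(f"dropped constant covariate {name!r}")
            continue
        kept[name] = col
    if np.ptp(kept[report]) == 0.0:
        raise DegenerateDesignError(f"covariate {report!r} has zero variance")
    n = len(y)
    if n < min_n:
        raise DegenerateDesignError(f"need at least {min_n} complete rows; got {n}")
    names = list(kept)
    X = np.column_stack([np.ones(n)] + [kept[k] for k in names])
    cond = float(np.linalg.cond(X))
    if cond > _COND_LIMIT or np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearDesignError(
            f"collinear regression design (condition number {cond:.3g})"
        )
    fit = sm.OLS(y, X).fit()
    idx = 1 + names.index(report)
    ci = fit.conf_int()
    return RegressionResult(
        model_id=model_id,
        metric=metric,
        year=year,
        coefficient=float(fit.params[idx]),
        ci_low=float(ci[idx, 0]),
        ci_high=float(ci[idx, 1]),
        p_value=float(fit.pvalues[idx]),
        n=n,
        covariates=names,
        intercept=float(fit.params[0]),
        notes=notes,
    )


def fit_per_minute(
    triples, metric: str = "", year: int = 1, model_id: str = "post_on_pre_minutes"
) -> RegressionResult:
    """OLS of post on pre with post-season minutes as an extra covariate.

    ``triples`` rows are (pre value, post value, post-season minutes); the
    reported coefficient is the pre-season term.
    """
    arr = np.asarray(triples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ConfigError("triples must be an (n, 3) array of (pre, post, post_minutes)")
    arr = arr[~np.isnan(arr).any(axis=1)]
    if len(arr) < 4:
        raise DegenerateDesignError(f"need at least 4 complete triples; got {len(arr)}")
    return _ols_report_first(
        arr[:, 1],
        {"pre": arr[:, 0], "post_minutes": arr[:, 2]},
        report="pre",
        model_id=model_id,
        metric=metric,
        year=year,
        min_n=4,
    )


_ADJUSTED_REQUIRED = [
    "pre_value",
    "post_value",
    "age_at_injury",
    "seasons_played_at_injury",
    "injury_year",
    "body_region",
    "position",
]

_REGION_REFERENCE = "knee"
_POSITION_REFERENCE = "guard"


def fit_adjusted(
    cohort_rows: pd.DataFrame, metric: str = "", year: int = 1, model_id: str = "adjusted"
) -> RegressionResult:
    """Covariate-adjusted post-on-pre OLS on complete cases.

    Covariates: age at primary severe injury, seasons played at injury,
    injury year, body region (reference: knee), position (reference:
    guard), and the age x seasons interaction.  Categorical levels absent
    from the complete-case data are simply not encoded; a stratum with a
    single level contributes no indicator (noted in the result).
    """
    missing = [c for c in _ADJUSTED_REQUIRED if c not in cohort_rows.columns]
    if missing:
        raise ConfigError(f"adjusted model input lacks column(s): {', '.join(missing)}")
    df = cohort_rows[_ADJUSTED_REQUIRED].dropna()
    if df.empty:
        raise DegenerateDesignError("no complete cases for the adjusted model")
    notes: list[str] = []
    columns: dict[str, np.ndarray] = {
        "pre": df["pre_value"].to_numpy(dtype=float),
        "age": df["age_at_injury"].to_numpy(dtype=float),
        "seasons": df["seasons_played_at_injury"].to_numpy(dtype=float),
        "injury_year": df["injury_year"].to_numpy(dtype=float),
    }
    for col, reference, prefix in (
        ("body_region", _REGION_REFERENCE, "region"),
        ("position", _POSITION_REFERENCE, "position"),
    ):
        levels = sorted(set(df[col].astype(str)))
        if len(levels) < 2:
            notes.append(f"single-level {col} ({levels[0]!r}); indicator dropped")
            continue
        for level in levels:
            if level == reference:
                continue
            columns[f"{prefix}[{level}]"] = (df[col].astype(str) == level).to_numpy(float)
    columns["age_x_seasons"] = columns["age"] * columns["seasons"]
    result = _ols_report_first(
        df["post_value"].to_numpy(dtype=float),
        columns,
        report="pre",
        model_id=model_id,
        metric=metric,
        year=year,
        min_n=len(columns) + 2,
    )
    result.notes = notes + result.notes
    return result


def anova_return_days(groups: dict[str, np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA from sums of squares.

    ``groups`` maps a label (e.g. body region) to its observations of days
    to return to sport.  Each group needs at least 2 observations.
    """
    if len(groups) < 2:
        raise ConfigError("ANOVA needs at least 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    for label, arr in zip(labels, arrays):
        if len(arr) < 2:
            raise ConfigError(f"group {label!r} has fewer than 2 observations")
    all_values = np.concatenate(arrays)
    grand_mean = all_values.mean()
    n_total = len(all_values)
    k = len(arrays)
    ss_between = sum(len(a) * (a.mean() - grand_mean) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0:
        f_stat = 0.0 if ss_between == 0.0 else float("inf")
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        group_labels=labels,
        group_means=[float(a.mean()) for a in arrays],
        group_sds=[float(a.std(ddof=1)) for a in arrays],
        group_ns=[len(a) for a in arrays],
        f_statistic=float(f_stat),
        p_value=p,
        df_between=df_between,
        df_within=df_within,
    )
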