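"""Cohort-level statistical procedures.

Implements the study-style analysis toolkit over a per-subject covariate
table: estimated cardiorespiratory fitness (eCRF) from a weighted linear
equation, single-pass |Z| > 2.5 outlier exclusion, split-half reliability,
partial correlation by residualization, a heteroscedasticity test based on
squared standardized residuals, and a simple (single-mediator) percentile
bootstrap mediation analysis.  One-tailed p-values are reported alongside
two-tailed ones; the caller's analysis plan declares which tail each
hypothesis uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

OUTLIER_Z_DEFAULT = 2.5

#: Default eCRF weights (METs), from the non-exercise estimation equation of
#: Jurca et al. (2005): constant + gender (M=1, F=0) + age + BMI + resting HR
#: + physical-activity category points.  Treated as data: override via config.
DEFAULT_ECRF_WEIGHTS = {
    "constant": 18.07,
    "gender_male": 2.77,
    "age_years": -0.10,
    "bmi": -0.17,
    "resting_hr_bpm": -0.03,
    "activity_points": [0.00, 0.32, 1.06, 1.76, 3.03],
}


@dataclass
class StatResult:
    """A single estimate with its inference and audit metadata."""

    estimate: float
    n: int
    df: int
    p_two_tailed: float
    p_one_tailed: float
    tail: str = "two-sided"
    stat_name: str = "r"
    covariates: tuple = ()
    excluded_ids: tuple = ()
    extra: dict = field(default_factory=dict)


def _pearson_with_df(x: np.ndarray, y: np.ndarray, df: int) -> tuple[float, float]:
    """Pearson r and its two-tailed p at the supplied residual df."""
    r = float(np.corrcoef(x, y)[0, 1])
    if df <= 0 or abs(r) >= 1.0:
        return r, 0.0 if abs(r) >= 1.0 else np.nan
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)


def one_tailed(p_two: float, estimate: float, tail: str) -> float:
    """Directional p-value: halve when the estimate lies in the hypothesized
    direction, otherwise fold to the complementary tail."""
    if tail == "two-sided" or not np.isfinite(p_two):
        return p_two
    in_direction = estimate > 0 if tail == "greater" else estimate < 0
    return p_two / 2.0 if in_direction else 1.0 - p_two / 2.0


def compute_ecrf(table: pd.DataFrame, weights: dict | None = None) -> pd.Series:
    """Estimated cardiorespiratory fitness (METs) per subject.

    A weighted linear combination of gender, age, BMI, resting heart rate and
    a physical-activity category (0-4), plus a constant.  Rows with any
    missing covariate yield NaN (logged via the returned series' name only;
    the caller decides how to handle missingness).
    """
    w = dict(DEFAULT_ECRF_WEIGHTS if weights is None else weights)
    required = ["gender", "age_years", "bmi", "resting_hr_bpm", "activity_level"]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing eCRF covariates: {missing_cols}")
    male = (table["gender"].astype(str).str.upper().isin(["M", "MALE", "1"])).astype(float)
    pts = np.asarray(w["activity_points"], dtype=float)
    act = table["activity_level"].to_numpy()
    act_pts = np.full(len(table), np.nan)
    valid_act = np.isfinite(act) & (act >= 0) & (act < len(pts))
    act_pts[valid_act] = pts[act[valid_act].astype(int)]
    ecrf = (
        w["constant"]
        + w["gender_male"] * male
        + w["age_years"] * table["age_years"]
        + w["bmi"] * table["bmi"]
        + w["resting_hr_bpm"] * table["resting_hr_bpm"]
        + act_pts
    )
    return ecrf.rename("ecrf_mets")


def exclude_outliers(values: pd.Series | np.ndarray, z_cut: float = OUTLIER_Z_DEFAULT):
    """Single-pass standardized outlier exclusion.

    Values are standardized against the sample mean and SD once (no
    re-standardization after removal); entries with |Z| > ``z_cut`` are
    excluded.  A zero-SD sample excludes nothing.

    Returns
    -------
    (keep, excluded_ids) : boolean mask aligned with the input, and the index
    labels (or positions) of the excluded entries.
    """
    s = pd.Series(values)
    if s.notna().sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    mu = s.mean()
    sd = s.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        keep = s.notna()
    else:
        keep = s.notna() & (np.abs((s - mu) / sd) <= z_cut)
    excluded = list(s.index[s.notna() & ~keep])
    return keep.to_numpy(), excluded


def split_half_reliability(block1, block2, tail: str = "greater") -> StatResult:
    """Pearson reliability of an index across two recording blocks."""
    x = np.asarray(block1, dtype=float)
    y = np.asarray(block2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("blocks must be paired (same subjects)")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    df = n - 2
    r, p2 = _pearson_with_df(x, y, df)
    return StatResult(
        estimate=r, n=n, df=df, p_two_tailed=p2,
        p_one_tailed=one_tailed(p2, r, tail), tail=tail, stat_name="r",
    )


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Least-squares residual of v on [1, Z]."""
    X = np.column_stack([np.ones(v.shape[0]), Z]) if Z.size else np.ones((v.shape[0], 1))
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlation(x, y, covariates=None, tail: str = "two-sided") -> StatResult:
    """Correlation of x and y after removing shared covariate variance.

    Both variables are projected on the covariates (plus intercept) and the
    residuals are correlated; df = n - 2 - #covariates.  With no covariates
    this reduces exactly to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = (
        np.column_stack([np.asarray(c, dtype=float) for c in covariates])
        if covariates is not None and len(covariates)
        else np.empty((x.size, 0))
    )
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[ok], y[ok], Z[ok]
    k = Z.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError("not enough observations for the covariate count")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    df = n - 2 - k
    # a variable that is an exact linear function of the covariates leaves a
    # numerically-zero residual; its correlation with anything is 0
    eps = np.finfo(float).eps
    if rx.std() <= 1e3 * eps * max(x.std(), 1.0) or ry.std() <= 1e3 * eps * max(
        y.std(), 1.0
    ):
        r, p2 = 0.0, 1.0
    else:
        r, p2 = _pearson_with_df(rx, ry, df)
    return StatResult(
        estimate=r, n=n, df=df, p_two_tailed=p2,
        p_one_tailed=one_tailed(p2, r, tail), tail=tail, stat_name="partial_r",
        covariates=tuple(range(k)),
    )


def residual_variance_vs_covariate(y, x, tail: str = "greater") -> StatResult:
    """Heteroscedasticity of y along x via squared standardized residuals.

    y is regressed on x; residuals are standardized by their SD, squared, and
    correlated with x.  A positive estimate means the spread of y grows with
    x.  If the fit is exact (all residuals ~0) the result is flagged
    degenerate with a NaN estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    resid = _residualize(y, x[:, None])
    sd = resid.std(ddof=2)
    if sd <= np.finfo(float).eps * max(1.0, np.abs(y).max()) * n:
        return StatResult(
            estimate=np.nan, n=n, df=n - 2, p_two_tailed=np.nan,
            p_one_tailed=np.nan, tail=tail, stat_name="resid_var_r",
            extra={"degenerate": True},
        )
    z2 = (resid / sd) ** 2
    df = n - 2
    r, p2 = _pearson_with_df(z2, x, df)
    return StatResult(
        estimate=r, n=n, df=df, p_two_tailed=p2,
        p_one_tailed=one_tailed(p2, r, tail), tail=tail, stat_name="resid_var_r",
    )


@dataclass
class MediationResult:
    """Simple-mediation estimates with a percentile bootstrap CI."""

    a: float
    b: float
    c_total: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    ci_level: float
    n: int
    n_boot: int
    significant: bool


def _ab_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """OLS a-path (m ~ x) and b-path (y ~ m + x) slopes, batched.

    Inputs may be 1-D (single dataset) or 2-D (bootstrap batch x n).
    """
    x = np.atleast_2d(x)
    m = np.atleast_2d(m)
    y = np.atleast_2d(y)
    xc = x - x.mean(axis=1, keepdims=True)
    mc = m - m.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (xc * xc).sum(axis=1)
    a = (xc * mc).sum(axis=1) / sxx
    # 2-predictor OLS for y ~ m + x on centered data
    smm = (mc * mc).sum(axis=1)
    smx = (mc * xc).sum(axis=1)
    smy = (mc * yc).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    det = smm * sxx - smx * smx
    b = (smy * sxx - smx * sxy) / det
    c_prime = (sxy * smm - smx * smy) / det
    c_total = sxy / sxx
    return a, b, c_total, c_prime


def mediation_simple(
    x, m, y,
    covariates=None,
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> MediationResult:
    """Single-mediator analysis with a percentile bootstrap CI.

    The a-path regresses the mediator on the predictor; the b-path regresses
    the outcome on the mediator controlling for the predictor; the indirect
    effect is a*b.  When covariates are supplied they are residualized out of
    predictor, mediator and outcome before the path models.  The CI resamples
    subjects with replacement ``n_boot`` times; mediation is called
    significant when the CI excludes zero.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = (
        np.column_stack([np.asarray(c, dtype=float) for c in covariates])
        if covariates is not None and len(covariates)
        else np.empty((x.size, 0))
    )
    ok = (
        np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
        & np.all(np.isfinite(Z), axis=1)
    )
    x, m, y, Z = x[ok], m[ok], y[ok], Z[ok]
    n = x.size
    if Z.shape[1]:
        x = _residualize(x, Z)
        m = _residualize(m, Z)
        y = _residualize(y, Z)

    a, b, c_total, c_prime = (v.item() for v in _ab_paths(x, m, y))
    indirect = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ab_boot = None
    a_b, b_b, *_ = _ab_paths(x[idx], m[idx], y[idx])
    ab_boot = a_b * b_b
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(ab_boot, [alpha, 1.0 - alpha])
    return MediationResult(
        a=a, b=b, c_total=c_total, c_prime=c_prime, indirect=indirect,
        ci_low=float(lo), ci_high=float(hi), ci_level=ci_level,
        n=n, n_boot=n_boot, significant=bool(lo > 0 or hi < 0),
    )


def run_study_analyses(
    cohort: pd.DataFrame, plan: dict, seed: int | None = None
) -> pd.DataFrame:
    """Execute a declared list of analyses over the cohort table.

    ``plan['analyses']`` is a list of dicts with keys: ``name``, ``kind``
    (``correlation`` | ``partial`` | ``residual_variance`` | ``reliability``
    | ``mediation``), the column names involved (``x``, ``y``, ``m``,
    ``covariates``), the ``tail`` and an optional ``outlier_z`` applied
    single-pass to the columns in ``exclude_outliers_on``.  Returns a tidy
    results table with every exclusion and covariate recorded.
    """
    analyses = plan.get("analyses", plan if isinstance(plan, list) else [])
    rows = []
    for entry in analyses:
        name = entry.get("name", entry.get("kind", "analysis"))
        kind = entry["kind"]
        tail = entry.get("tail", "two-sided")
        cols = [entry.get(k) for k in ("x", "y", "m")] + list(entry.get("covariates", []))
        cols = [c for c in cols if c]
        unknown = [c for c in cols if c not in cohort.columns]
        if unknown:
            raise ValueError(f"analysis {name!r} references unknown columns: {unknown}")

        df = cohort.copy()
        excluded: list = []
        z_cut = entry.get("outlier_z")
        for col in entry.get("exclude_outliers_on", []):
            keep, exc = exclude_outliers(df[col], z_cut or OUTLIER_Z_DEFAULT)
            excluded.extend(exc)
            df = df[keep]

        covs = [df[c].to_numpy(float) for c in entry.get("covariates", [])]
        if kind == "correlation":
            res = partial_correlation(df[entry["x"]], df[entry["y"]], None, tail)
        elif kind == "partial":
            res = partial_correlation(df[entry["x"]], df[entry["y"]], covs, tail)
        elif kind == "residual_variance":
            res = residual_variance_vs_covariate(df[entry["y"]], df[entry["x"]], tail)
        elif kind == "reliability":
            res = split_half_reliability(df[entry["x"]], df[entry["y"]], tail)
        elif kind == "mediation":
            med = mediation_simple(
                df[entry["x"]], df[entry["m"]], df[entry["y"]],
                covariates=covs or None,
                n_boot=entry.get("n_boot", 5000),
                seed=seed,
            )
            rows.append(
                {
                    "name": name, "kind": kind, "statistic": "indirect",
                    "estimate": med.indirect, "n": med.n, "df": np.nan,
                    "p_two_tailed": np.nan, "p_one_tailed": np.nan, "tail": tail,
                    "ci_low": med.ci_low, "ci_high": med.ci_high,
                    "significant": med.significant,
                    "covariates": ";".join(entry.get("covariates", [])),
                    "excluded_ids": ";".join(map(str, excluded)),
                }
            )
            continue
        else:
            raise ValueError(f"unknown analysis kind {kind!r}")
        rows.append(
            {
                "name": name, "kind": kind, "statistic": res.stat_name,
                "estimate": res.estimate, "n": res.n, "df": res.df,
                "p_two_tailed": res.p_two_tailed, "p_one_tailed": res.p_one_tailed,
                "tail": tail, "ci_low": np.nan, "ci_high": np.nan,
                "significant": np.nan,
                "covariates": ";".join(entry.get("covariates", [])),
                "excluded_ids": ";".join(map(str, excluded)),
            }
        )
    return pd.DataFrame(rows)
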