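"""Statistical procedures: eCRF arithmetic, outlier exclusion, reliability,
partial correlation vs independent oracles, heteroscedasticity test, and
bootstrap mediation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cerepulse.stats import (
    compute_ecrf,
    exclude_outliers,
    mediation_simple,
    partial_correlation,
    residual_variance_vs_covariate,
    run_study_analyses,
    split_half_reliability,
)
from cerepulse.synthcohort import SimConfig, simulate_covariates


# -------------------------------------------------------------------- eCRF


def cohort_row(gender="M", age=40.0, bmi=25.0, rhr=60.0, act=2):
    return pd.DataFrame(
        [{
            "gender": gender, "age_years": age, "bmi": bmi,
            "resting_hr_bpm": rhr, "activity_level": act,
        }]
    )


def test_ecrf_constant_only():
    w = {
        "constant": 10.0, "gender_male": 0.0, "age_years": 0.0,
        "bmi": 0.0, "resting_hr_bpm": 0.0, "activity_points": [0.0] * 5,
    }
    assert compute_ecrf(cohort_row(), w).iloc[0] == pytest.approx(10.0)

def test_ecrf_decreases_with_age():
    young = compute_ecrf(cohort_row(age=25.0)).iloc[0]
    old = compute_ecrf(cohort_row(age=70.0)).iloc[0]
    assert old < young

def test_ecrf_matches_hand_computed_dot_product():
    # 18.07 + 2.77*1 - 0.10*40 - 0.17*25 - 0.03*60 + 1.06
    expected = 18.07 + 2.77 - 4.0 - 4.25 - 1.8 + 1.06
    assert compute_ecrf(cohort_row()).iloc[0] == pytest.approx(expected, abs=1e-9)

def test_ecrf_missing_covariate_column_raises():
    with pytest.raises(ValueError, match="missing eCRF covariates"):
        compute_ecrf(cohort_row().drop(columns=["bmi"]))

def test_ecrf_missing_value_yields_nan():
    row = cohort_row()
    row.loc[0, "activity_level"] = np.nan
    assert np.isnan(compute_ecrf(row).iloc[0])


# ----------------------------------------------------------------- outliers


def test_outlier_single_extreme_excluded():
    v = pd.Series([0.0] * 46 + [10.0])
    keep, excluded = exclude_outliers(v)
    assert excluded == [46]
    assert keep.sum() == 46

def test_outlier_all_equal_none_excluded():
    keep, excluded = exclude_outliers(pd.Series([3.0] * 20))
    assert excluded == [] and keep.all()

def test_outlier_constructed_z26_excluded():
    # 40 standard-normal-ish values plus one placed exactly at z = 2.6
    rng = np.random.default_rng(8)
    base = rng.normal(0, 1, 40)
    base = (base - base.mean()) / base.std(ddof=1)
    # appending x changes mean/SD; solve by iteration for a point at z = 2.6
    x = 2.6
    for _ in range(100):
        v = np.append(base, x)
        mu, sd = v.mean(), v.std(ddof=1)
        x_new = mu + 2.6001 * sd
        if abs(x_new - x) < 1e-12:
            break
        x = x_new
    keep, excluded = exclude_outliers(pd.Series(np.append(base, x)))
    assert excluded == [40]

@given(scale=st.floats(0.01, 1e4), shift=st.floats(-1e4, 1e4))
def test_outlier_scale_and_shift_invariance(scale, shift):
    v = pd.Series([0.0, 1.0, 2.0, 1.5, 0.5, 30.0])
    keep1, _ = exclude_outliers(v)
    keep2, _ = exclude_outliers(v * scale + shift)
    assert np.array_equal(keep1, keep2)


# -------------------------------------------------------------- reliability


def test_reliability_perfect_and_inverted():
    x = np.arange(20.0)
    assert split_half_reliability(x, x).estimate == pytest.approx(1.0)
    assert split_half_reliability(x, -x).estimate == pytest.approx(-1.0)

def test_reliability_matches_covariance_formula_oracle():
    rng = np.random.default_rng(12)
    b1 = rng.normal(0, 1, 47)
    b2 = b1 + rng.normal(0, 0.5, 47)
    res = split_half_reliability(b1, b2)
    # independent oracle: covariance formula on the same draw
    oracle = np.cov(b1, b2)[0, 1] / (b1.std(ddof=1) * b2.std(ddof=1))
    assert res.estimate == pytest.approx(oracle, abs=1e-12)
    assert res.df == 45
    assert res.p_one_tailed == pytest.approx(res.p_two_tailed / 2)


# ------------------------------------------------------ partial correlation


def test_partial_reduces_to_pearson_without_covariates():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=(2, 60))
    res = partial_correlation(x, y)
    assert res.estimate == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
    assert res.df == 58

def test_partial_with_exact_covariate_dependence_is_zero():
    rng = np.random.default_rng(4)
    z = rng.normal(size=80)
    x = rng.normal(size=80)
    y = 3.0 * z - 1.0  # exact function of the covariate
    res = partial_correlation(x, y, [z])
    assert abs(res.estimate) < 1e-6

def test_partial_matches_recursion_formula_oracle():
    rng = np.random.default_rng(5)
    x, y, z = rng.normal(size=(3, 100))
    y = y + 0.5 * z
    x = x + 0.3 * z
    res = partial_correlation(x, y, [z])
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    oracle = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
    assert res.estimate == pytest.approx(oracle, abs=1e-10)

def test_partial_matches_statsmodels_two_stage_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(6)
    x, y = rng.normal(size=(2, 120))
    Z = rng.normal(size=(120, 2))
    y = y + Z @ [0.4, -0.2]
    res = partial_correlation(x, y, [Z[:, 0], Z[:, 1]])
    rx = sm.OLS(x, sm.add_constant(Z)).fit().resid
    ry = sm.OLS(y, sm.add_constant(Z)).fit().resid
    assert res.estimate == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)
    assert res.df == 120 - 2 - 2

def test_partial_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    df = pd.DataFrame(rng.normal(size=(80, 3)), columns=["x", "y", "z"])
    res = partial_correlation(df["x"], df["y"], [df["z"]])
    ref = pg.partial_corr(df, x="x", y="y", covar="z")
    pcol = "p_val" if "p_val" in ref.columns else "p-val"
    assert res.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
    assert res.p_two_tailed == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)


# -------------------------------------------------- residual variance vs x


def test_residual_variance_null_is_near_zero():
    rng = np.random.default_rng(9)
    x = rng.uniform(0, 1, 500)
    y = 2.0 * x + rng.normal(0, 1, 500)
    res = residual_variance_vs_covariate(y, x)
    assert abs(res.estimate) < 0.1

def test_residual_variance_detects_heteroscedasticity():
    rng = np.random.default_rng(10)
    hits = 0
    for _ in range(20):
        x = rng.uniform(0, 1, 500)
        y = 2.0 * x + rng.normal(0, 1 + x)
        res = residual_variance_vs_covariate(y, x, tail="greater")
        hits += res.p_one_tailed <= 0.05
    assert hits >= 18

def test_residual_variance_exact_fit_degenerate():
    x = np.linspace(0, 1, 50)
    res = residual_variance_vs_covariate(3 * x + 1, x)
    assert res.extra.get("degenerate") is True
    assert np.isnan(res.estimate)


# ---------------------------------------------------------------- mediation


def test_mediation_refuses_tiny_bootstrap():
    rng = np.random.default_rng(0)
    x, m, y = rng.normal(size=(3, 50))
    with pytest.raises(ValueError):
        mediation_simple(x, m, y, n_boot=50)

def test_mediation_null_ci_usually_contains_zero():
    rng = np.random.default_rng(11)
    contains = 0
    for i in range(20):
        x = rng.normal(size=200)
        m = rng.normal(size=200)  # a-path is null
        y = 0.5 * m + rng.normal(size=200)
        res = mediation_simple(x, m, y, n_boot=500, seed=i)
        contains += res.ci_low <= 0.0 <= res.ci_high
    assert contains >= 18

def test_mediation_detects_strong_effect():
    rng = np.random.default_rng(13)
    hits = 0
    for i in range(20):
        x = rng.normal(size=200)
        m = 0.5 * x + rng.normal(0, 0.5, 200)
        y = 0.5 * m + rng.normal(0, 0.5, 200)
        res = mediation_simple(x, m, y, n_boot=500, seed=i)
        hits += res.significant and res.indirect > 0
    assert hits >= 18

def test_mediation_permuted_outcome_centers_on_zero():
    rng = np.random.default_rng(14)
    x = rng.normal(size=300)
    m = 0.5 * x + rng.normal(0, 0.5, 300)
    y = 0.5 * m + rng.normal(0, 0.5, 300)
    estimates = [
        mediation_simple(x, m, rng.permutation(y), n_boot=100, seed=k).indirect
        for k in range(50)
    ]
    assert abs(np.mean(estimates)) < 0.02

def test_mediation_is_seed_deterministic():
    rng = np.random.default_rng(15)
    x, m, y = rng.normal(size=(3, 100))
    a = mediation_simple(x, m, y, n_boot=200, seed=4)
    b = mediation_simple(x, m, y, n_boot=200, seed=4)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

def test_mediation_covariate_residualization_removes_confound():
    rng = np.random.default_rng(16)
    z = rng.normal(size=400)
    x = z + rng.normal(0, 0.3, 400)
    m = z + rng.normal(0, 0.3, 400)  # x-m association is pure confound
    y = z + rng.normal(0, 0.3, 400)
    raw = mediation_simple(x, m, y, n_boot=300, seed=0)
    adj = mediation_simple(x, m, y, covariates=[z], n_boot=300, seed=0)
    assert abs(adj.indirect) < abs(raw.indirect) / 3


# ------------------------------------------------------------- study runner


def study_plan():
    return {
        "analyses": [
            {
                "name": "age_compliance", "kind": "partial",
                "x": "age_years", "y": "true_compliance_global",
                "covariates": ["gender_code"], "tail": "less",
                "exclude_outliers_on": ["true_compliance_global"],
            },
            {
                "name": "het", "kind": "residual_variance",
                "x": "age_years", "y": "true_pulse_pressure_pct", "tail": "greater",
            },
        ]
    }


def synthetic_table(n=60, seed=21):
    df = simulate_covariates(SimConfig(n_subjects=n, seed=seed))
    df["gender_code"] = (df["gender"] == "M").astype(float)
    return df


def test_study_runner_age_compliance_direction():
    res = run_study_analyses(synthetic_table(), study_plan())
    row = res[res["name"] == "age_compliance"].iloc[0]
    assert row["estimate"] < 0  # built-in effect: compliance falls with age

def test_study_runner_unknown_column_raises():
    plan = {"analyses": [{"name": "bad", "kind": "correlation", "x": "nope", "y": "age_years"}]}
    with pytest.raises(ValueError, match="nope"):
        run_study_analyses(synthetic_table(), plan)

def test_study_runner_deterministic():
    df = synthetic_table()
    a = run_study_analyses(df, study_plan(), seed=3).to_csv(index=False)
    b = run_study_analyses(df, study_plan(), seed=3).to_csv(index=False)
    assert a == b

def test_one_tailed_halves_two_tailed_in_direction():
    rng = np.random.default_rng(17)
    x = rng.normal(size=50)
    y = x + rng.normal(0, 1, 50)
    res = partial_correlation(x, y, tail="greater")
    assert res.estimate > 0
    assert res.p_one_tailed == pytest.approx(res.p_two_tailed / 2)
    res2 = partial_correlation(x, -y, tail="greater")
    assert res2.p_one_tailed == pytest.approx(1 - res2.p_two_tailed / 2)
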