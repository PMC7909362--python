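"""Longitudinal table construction and mixed-model machinery."""

import numpy as np
import pandas as pd
import pytest

from vcgmem.circular_stats import axial_transform
from vcgmem.longitudinal import (
    ModelDataError, build_long_table, fit_mixed, lrt_random_slope,
    ml_loglik, paired_t,
)
from vcgmem.simulate import simulate_long_table


def _cov_table(n):
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "age": rng.normal(70, 10, n), "female": rng.integers(0, 2, n),
        "history_MI": rng.integers(0, 2, n), "history_NSVT": rng.integers(0, 2, n),
        "history_sustained_VT": rng.integers(0, 2, n),
        "LVEF": rng.normal(32, 7, n), "diabetes": rng.integers(0, 2, n),
        "hypertension": rng.integers(0, 2, n), "ACEi_ARB": rng.integers(0, 2, n),
        "classIII_AA": rng.integers(0, 2, n),
    })


def _metrics_table(n):
    rng = np.random.default_rng(1)
    rows = []
    for i in range(n):
        for mode in ("AAI", "DDD"):
            for day in (1, 7):
                rows.append({
                    "patient_id": f"P{i}", "mode": mode, "day": day,
                    "t_area_azimuth": rng.uniform(-180, 180),
                    "qrs_area_azimuth": rng.uniform(-180, 180),
                    "t_area_mag": rng.uniform(10, 60),
                    "qrs_area_mag": rng.uniform(40, 140),
                })
    return pd.DataFrame(rows)


def test_long_table_two_rows_per_patient():
    m, c = _metrics_table(20), _cov_table(20)
    long = build_long_table(m, c, "t_area_azimuth", "AAI")
    assert len(long) == 40
    assert set(long["day"]) == {0.0, 1.0}
    # angles stored on the axial scale
    src = m[(m["mode"] == "AAI") & (m["day"] == 1)].set_index("patient_id")
    got = long[long["day"] == 0].set_index("patient_id")["y"]
    for pid in src.index:
        assert got[pid] == pytest.approx(axial_transform(src.loc[pid, "t_area_azimuth"]))


def test_long_table_drops_incomplete_patients():
    m, c = _metrics_table(10), _cov_table(10)
    m = m[~((m["patient_id"] == "P3") & (m["day"] == 7))]
    long = build_long_table(m, c, "t_area_mag", "AAI")
    assert "P3" not in set(long["patient_id"])
    assert len(long) == 18


def test_magnitude_outcome_not_transformed():
    m, c = _metrics_table(8), _cov_table(8)
    long = build_long_table(m, c, "t_area_mag", "DDD")
    src = m[(m["mode"] == "DDD") & (m["day"] == 1)].set_index("patient_id")
    got = long[long["day"] == 0].set_index("patient_id")["y"]
    for pid in src.index:
        assert got[pid] == pytest.approx(src.loc[pid, "t_area_mag"])


def test_day_effect_recovered_single_fit():
    df, truth = simulate_long_table(200, 30.0, -80.0, seed=11)
    fit = fit_mixed(df, model="M1", angle_outcome=False)
    tab = fit.table.set_index("term")
    assert tab.loc["day", "ci_lo"] < truth["day"] < tab.loc["day", "ci_hi"]
    assert tab.loc["day:female", "ci_lo"] < truth["day:female"] < tab.loc["day:female", "ci_hi"]
    assert tab.loc["day:female", "p"] < 0.05


def test_angle_back_transform_halves_all_but_qrs_slope():
    df, _ = simulate_long_table(60, 30.0, seed=3)
    raw = fit_mixed(df, model="M1", angle_outcome=False).table.set_index("term")
    deg = fit_mixed(df, model="M1", angle_outcome=True).table.set_index("term")
    for term in raw.index:
        factor = 1.0 if term == "qrs" else 2.0
        assert deg.loc[term, "estimate"] == pytest.approx(
            raw.loc[term, "estimate"] / factor)


def test_permuted_covariates_collapse_to_null():
    """Negative control: shuffling covariates across patients destroys the
    female-by-day interaction."""
    df, _ = simulate_long_table(150, 30.0, -80.0, seed=21)
    rng = np.random.default_rng(0)
    perm = df.drop_duplicates("patient_id")[["patient_id", "female"]].copy()
    perm["female"] = rng.permutation(perm["female"].to_numpy())
    df = df.drop(columns="female").merge(perm, on="patient_id")
    fit = fit_mixed(df, model="M1", angle_outcome=False)
    tab = fit.table.set_index("term")
    assert tab.loc["day:female", "ci_lo"] < 0 < tab.loc["day:female", "ci_hi"]


def test_constant_outcome_degenerate():
    df, _ = simulate_long_table(20, 0.0, seed=5)
    df["y"] = 0.0
    fit = fit_mixed(df, angle_outcome=False)
    tab = fit.table.set_index("term")
    assert tab.loc["day", "estimate"] == 0.0
    assert fit.random_structure == "degenerate"


def test_model_spec_covariate_sets():
    df, _ = simulate_long_table(30, 10.0, seed=9)
    m1 = fit_mixed(df, model="M1", angle_outcome=False).table
    m2 = fit_mixed(df, model="M2", angle_outcome=False).table
    assert "day:LVEF" not in set(m1["term"])
    assert {"day:LVEF", "day:classIII_AA", "day:ACEi_ARB"} <= set(m2["term"])
    with pytest.raises(ModelDataError):
        fit_mixed(df, model="M3")


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def test_profiled_ml_matches_statsmodels():
    """The fast balanced-design ML path and statsmodels MixedLM agree on
    the maximized log-likelihood of both covariance structures."""
    import warnings
    from statsmodels.regression.mixed_linear_model import MixedLM
    rng = np.random.default_rng(4)
    n, m = 30, 3
    pid = np.repeat([f"S{i}" for i in range(n)], m)
    day = np.tile(np.arange(m, dtype=float), n)
    y = (1.5 * day + rng.normal(0, 1, n * m)
         + np.repeat(rng.normal(0, 1.2, n), m)
         + day * np.repeat(rng.normal(0, 0.7, n), m))
    df = pd.DataFrame(dict(patient_id=pid, day=day, y=y))
    X = np.column_stack([np.ones(n * m), day])
    for slope in (True, False):
        ours = ml_loglik(df, slope=slope)
        re = X if slope else X[:, :1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = MixedLM(y, X, pid, exog_re=re).fit(reml=False).llf
        assert ours == pytest.approx(ref, abs=1e-3)


def test_lrt_detects_slope_variance():
    rng = np.random.default_rng(6)
    n, m = 60, 4
    pid = np.repeat([f"S{i}" for i in range(n)], m)
    day = np.tile(np.arange(m, dtype=float), n)
    y = (0.5 * day + rng.normal(0, 1, n * m)
         + np.repeat(rng.normal(0, 1, n), m)
         + day * np.repeat(rng.normal(0, 1.5, n), m))
    lr, p = lrt_random_slope(pd.DataFrame(dict(patient_id=pid, day=day, y=y)))
    assert lr > 0 and p < 0.01


def test_lrt_nonnegative_and_null_behaved():
    rng = np.random.default_rng(7)
    n, m = 40, 4
    pid = np.repeat([f"S{i}" for i in range(n)], m)
    day = np.tile(np.arange(m, dtype=float), n)
    y = rng.normal(0, 1, n * m) + np.repeat(rng.normal(0, 1, n), m)
    lr, p = lrt_random_slope(pd.DataFrame(dict(patient_id=pid, day=day, y=y)))
    assert lr >= 0.0
    assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# Paired t
# ---------------------------------------------------------------------------

def test_paired_t_identical_and_shift():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    assert paired_t(a, a) == (0.0, 1.0)
    t, p = paired_t(a + 0.5 + np.array([0.01, -0.01, 0.02, -0.02]), a)
    assert p < 0.01 and t > 0


def test_paired_t_power_matches_closed_form():
    """Shift d = 0.5 sigma at n = 20: Monte-Carlo power tracks the
    noncentral-t closed form."""
    from scipy import stats
    n, d = 20, 0.5
    nc = d * np.sqrt(n)
    crit = stats.t.ppf(0.975, n - 1)
    power_theory = stats.nct.sf(crit, n - 1, nc) + stats.nct.cdf(-crit, n - 1, nc)
    rng = np.random.default_rng(13)
    hits = sum(paired_t(rng.normal(d, 1, n), np.zeros(n))[1] < 0.05
               for _ in range(400))
    assert hits / 400 == pytest.approx(power_theory, abs=0.08)
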