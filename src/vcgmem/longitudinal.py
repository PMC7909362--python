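"""Longitudinal mixed models for day-1 -> day-7 vector changes.

Each outcome (T/SVG direction or magnitude in a given pacing mode) is
modeled over the two study days with a random intercept and random day
slope per patient.  Angles enter on the axial 2θ+360° scale and are
halved for reporting.  Model 1 adjusts for age, sex (female indicator),
history of MI and history of NSVT; Model 2 additionally for LVEF,
diabetes, hypertension, ACEi/ARB use and class III antiarrhythmics.
Both models adjust for the longitudinal change in the corresponding QRS
variable (azimuth outcome paired with QRS azimuth, elevation with
elevation, area with area).  Clinical covariates enter both as main
effects and as day interactions; the day interaction carries the
"modification of the day-1 -> day-7 change" interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .circular_stats import axial_transform

MODEL1_COVARIATES = ("age", "female", "history_MI", "history_NSVT")
MODEL2_COVARIATES = MODEL1_COVARIATES + (
    "LVEF", "diabetes", "hypertension", "ACEi_ARB", "classIII_AA",
)

#: Outcome -> (corresponding QRS-side covariate, is the outcome an angle).
#: For QRS outcomes the pairing flips to the corresponding T variable.
_ANGLE_SUFFIXES = ("azimuth", "elevation")


class ModelDataError(ValueError):
    pass


def _pair_column(outcome: str) -> str:
    """The 'corresponding QRS variable' (or T variable for QRS outcomes)."""
    prefix = "t" if outcome.startswith("qrs_") else "qrs"
    suffix = outcome.split("_", 1)[1]  # e.g. "area_azimuth", "area_mag"
    if outcome.startswith("svg_"):
        suffix = outcome.split("_", 1)[1]
    return f"{prefix}_{suffix}"


def is_angle_outcome(outcome: str) -> bool:
    return outcome.endswith(_ANGLE_SUFFIXES)


def build_long_table(
    geh_df: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: str,
    mode: str,
) -> pd.DataFrame:
    """Assemble the two-rows-per-patient table for one outcome and mode.

    Angles (azimuth/elevation columns) are stored on the 2θ+360° axial
    scale, as is the corresponding QRS (or T) angle covariate.  Patients
    missing either day are dropped.
    """
    if mode not in ("AAI", "DDD"):
        raise ModelDataError(f"mode must be AAI or DDD, got {mode!r}")
    pair = _pair_column(outcome)
    for col in (outcome, pair):
        if col not in geh_df.columns:
            raise ModelDataError(f"metric column {col!r} not in the metrics table")
    sub = geh_df[geh_df["mode"] == mode].copy()
    angle = is_angle_outcome(outcome)
    y = axial_transform(sub[outcome]) if angle else sub[outcome].to_numpy(float)
    q = axial_transform(sub[pair]) if angle else sub[pair].to_numpy(float)
    rows = pd.DataFrame({
        "patient_id": sub["patient_id"].astype(str).to_numpy(),
        "day": (sub["day"].to_numpy(int) == 7).astype(float),  # day 1 -> 0, day 7 -> 1
        "y": y,
        "qrs": q,
    })
    counts = rows.groupby("patient_id")["day"].nunique()
    keep = counts[counts == 2].index
    rows = rows[rows["patient_id"].isin(keep)]
    if rows.empty:
        raise ModelDataError("no patient has both study days for this outcome")
    cov = covariates.reset_index(drop=True).copy()
    cov["patient_id"] = cov["patient_id"].astype(str)
    out = rows.merge(cov, on="patient_id", how="left", validate="many_to_one")
    missing = [c for c in MODEL2_COVARIATES if out[c].isna().any()]
    if missing:
        raise ModelDataError(f"missing covariate values for columns {missing}")
    return out.sort_values(["patient_id", "day"]).reset_index(drop=True)


@dataclass
class ModelFit:
    """Tidy fixed-effect table of one mixed-model fit.

    ``table`` columns: term, estimate, se, ci_lo, ci_hi, p — on the
    reporting scale (angle coefficients halved back from 2θ).
    """

    table: pd.DataFrame
    loglik: float
    converged: bool
    singular: bool
    random_structure: str  # "intercept+slope" or "intercept"
    angle_outcome: bool


def _design(df: pd.DataFrame, model: str, interactions: bool):
    covs = MODEL1_COVARIATES if model == "M1" else MODEL2_COVARIATES
    cols = {"Intercept": np.ones(len(df)), "day": df["day"].to_numpy(float),
            "qrs": df["qrs"].to_numpy(float)}
    # a covariate without variation (e.g. a universal history in a small
    # cohort) is collinear with the intercept (and its day interaction
    # with the day term); drop both
    varying = [c for c in covs if np.ptp(df[c].to_numpy(float)) > 0]
    for c in varying:
        cols[c] = df[c].to_numpy(float)
    if interactions:
        for c in varying:
            cols[f"day:{c}"] = cols["day"] * cols[c]
    return pd.DataFrame(cols, index=df.index)


def fit_mixed(
    df: pd.DataFrame,
    model: str = "M1",
    angle_outcome: bool = True,
    covariate_day_interactions: bool = True,
    reml: bool = True,
) -> ModelFit:
    """REML fit of the random-intercept + random-day-slope model.

    Singular or non-convergent random-effect covariances fall back to a
    random intercept only (flagged).  Wald 95% CIs and p-values.  When
    ``angle_outcome``, every coefficient except the corresponding-QRS
    slope (which is scale-free, angle on angle) is halved back to
    degrees for reporting.
    """
    if model not in ("M1", "M2"):
        raise ModelDataError(f"model must be 'M1' or 'M2', got {model!r}")
    if df["patient_id"].nunique() < 3:
        raise ModelDataError("need at least 3 patients")
    X = _design(df, model, covariate_day_interactions)
    y = df["y"].to_numpy(float)
    groups = df["patient_id"].to_numpy()
    if np.allclose(y, y[0]):
        tab = pd.DataFrame({
            "term": X.columns, "estimate": 0.0, "se": 0.0,
            "ci_lo": 0.0, "ci_hi": 0.0, "p": 1.0,
        })
        tab.loc[tab["term"] == "Intercept", ["estimate", "ci_lo", "ci_hi"]] = y[0]
        if angle_outcome:
            mask = ~tab["term"].isin(["qrs"])
            tab.loc[mask, ["estimate", "ci_lo", "ci_hi"]] /= 2.0
        return ModelFit(tab, float("nan"), True, True, "degenerate", angle_outcome)

    if len(df) <= X.shape[1] + 2:
        raise ModelDataError(
            f"{len(df)} rows cannot support {X.shape[1]} fixed effects")
    exog_re = np.column_stack([np.ones(len(df)), df["day"].to_numpy(float)])
    res, singular, structure = None, False, "intercept+slope"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = MixedLM(y, X.to_numpy(), groups, exog_re=exog_re).fit(reml=reml)
            ev = np.linalg.eigvalsh(np.asarray(res.cov_re))
            if not res.converged or ev.min() < 1e-8 * max(ev.max(), 1.0):
                singular = True
        except (np.linalg.LinAlgError, ValueError):
            singular = True
        if singular or res is None:
            structure = "intercept"
            try:
                res = MixedLM(y, X.to_numpy(), groups,
                              exog_re=exog_re[:, :1]).fit(reml=reml)
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise ModelDataError(f"mixed model unfittable: {exc}") from exc
    k = X.shape[1]
    est = np.asarray(res.fe_params)[:k]
    se = np.asarray(res.bse)[:k]
    z = stats.norm.ppf(0.975)
    tab = pd.DataFrame({
        "term": X.columns,
        "estimate": est,
        "se": se,
        "ci_lo": est - z * se,
        "ci_hi": est + z * se,
        "p": 2 * stats.norm.sf(np.abs(est) / np.where(se > 0, se, np.inf)),
    })
    if angle_outcome:
        mask = ~tab["term"].isin(["qrs"])
        tab.loc[mask, ["estimate", "se", "ci_lo", "ci_hi"]] /= 2.0
    return ModelFit(
        table=tab.reset_index(drop=True),
        loglik=float(res.llf),
        converged=bool(res.converged),
        singular=singular,
        random_structure=structure,
        angle_outcome=angle_outcome,
    )


# ---------------------------------------------------------------------------
# Profiled ML for the random-slope likelihood-ratio test
# ---------------------------------------------------------------------------

def _profiled_ml(y2: np.ndarray, X3: np.ndarray, Z: np.ndarray, slope: bool) -> float:
    """Maximized ML log-likelihood for a balanced mixed model.

    ``y2``: (n_subjects, m) responses; ``X3``: (n_subjects, m, p) fixed
    design; ``Z``: (m, q) random-effect design shared by all subjects
    (q = 2 with slope, 1 without).  Fixed effects are profiled out by GLS
    at each covariance evaluation; the search runs over the log-Cholesky
    parameterization of the random-effect covariance plus log residual SD.
    """
    n, m = y2.shape
    p = X3.shape[2]

    def neg_ll(params: np.ndarray) -> float:
        sig2 = np.exp(2 * params[0])
        if slope:
            L = np.array([[np.exp(params[1]), 0.0], [params[2], np.exp(params[3])]])
        else:
            L = np.array([[np.exp(params[1])]])
        G = L @ L.T
        V = sig2 * np.eye(m) + Z @ G @ Z.T
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2 * np.sum(np.log(np.diag(c)))
        ci = np.linalg.solve(c, np.eye(m))
        Vinv = ci.T @ ci  # stable V^{-1} via the Cholesky factor
        XtVX = np.einsum("nmp,mk,nkq->pq", X3, Vinv, X3)
        XtVy = np.einsum("nmp,mk,nk->p", X3, Vinv, y2)
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return 1e12
        r = y2 - np.einsum("nmp,p->nm", X3, beta)
        quad = np.einsum("nm,mk,nk->", r, Vinv, r)
        return 0.5 * (n * logdet + quad + n * m * np.log(2 * np.pi))

    v0 = max(np.var(y2), 1e-6)
    if slope:
        x0 = np.array([0.5 * np.log(v0 / 2), 0.5 * np.log(v0 / 2), 0.0,
                       0.5 * np.log(v0 / 4)])
    else:
        x0 = np.array([0.5 * np.log(v0 / 2), 0.5 * np.log(v0 / 2)])
    best = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                             options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
    # a second start guards against a bad local optimum
    alt = optimize.minimize(neg_ll, x0 + 0.7, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
    return float(-min(best.fun, alt.fun))


def _balanced_arrays(df: pd.DataFrame, fixed_cols) -> tuple | None:
    """Stack per-subject arrays when every subject shares the same time grid."""
    g = df.sort_values(["patient_id", "day"]).groupby("patient_id", sort=True)
    sizes = g.size()
    if sizes.nunique() != 1:
        return None
    m = int(sizes.iloc[0])
    days = np.stack([sub["day"].to_numpy(float) for _, sub in g])
    if not np.allclose(days, days[0]):
        return None
    cols = ["Intercept"] + list(fixed_cols)
    dfx = df.sort_values(["patient_id", "day"]).copy()
    dfx["Intercept"] = 1.0
    X = dfx[cols].to_numpy(float).reshape(-1, m, len(cols))
    y2 = dfx["y"].to_numpy(float).reshape(-1, m)
    t = days[0]
    return y2, X, t


def ml_loglik(df: pd.DataFrame, fixed_cols=("day",), slope: bool = True) -> float:
    """Maximized ML log-likelihood of the mixed model (intercept [+ slope]).

    A fast profiled path handles the balanced common-time-grid case;
    unbalanced data fall back to statsmodels MixedLM with ML.
    """
    arrs = _balanced_arrays(df, fixed_cols)
    if arrs is not None:
        y2, X3, t = arrs
        Z = np.column_stack([np.ones_like(t), t]) if slope else np.ones((t.size, 1))
        return _profiled_ml(y2, X3, Z, slope)
    dfx = df.copy()
    dfx["Intercept"] = 1.0
    X = dfx[["Intercept"] + list(fixed_cols)].to_numpy(float)
    exog_re = np.column_stack([np.ones(len(dfx)), dfx["day"].to_numpy(float)])
    if not slope:
        exog_re = exog_re[:, :1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM(dfx["y"].to_numpy(float), X, dfx["patient_id"].to_numpy(),
                      exog_re=exog_re).fit(reml=False)
    return float(res.llf)


def lrt_random_slope(df: pd.DataFrame, fixed_cols=("day",)) -> tuple[float, float]:
    """Likelihood-ratio test for the random day slope; (LR, p).

    Both models are fit by ML (not REML, since fixed effects coincide the
    comparison is of covariance structures at matched likelihoods is
    valid either way; ML keeps the reference distribution standard).
    The null distribution is the boundary 50:50 mixture of χ²(1) and
    χ²(2) (slope variance on the boundary plus a free covariance).
    """
    ll1 = ml_loglik(df, fixed_cols, slope=True)
    ll0 = ml_loglik(df, fixed_cols, slope=False)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    if lr == 0.0:
        return 0.0, 1.0
    p = 0.5 * stats.chi2.sf(lr, 1) + 0.5 * stats.chi2.sf(lr, 2)
    return float(lr), float(p)


def paired_t(values_a, values_b) -> tuple[float, float]:
    """Paired t-test for linear (non-angle) metrics; (t, p).

    Identical columns are degenerate and reported as (0, 1).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ModelDataError("paired samples must have equal length")
    d = a - b
    if np.allclose(d, d[0]) and np.allclose(d[0], 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
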