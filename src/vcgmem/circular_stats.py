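"""Circular statistics for spatial-angle and direction variables.

Descriptives (mean direction, resultant length, von Mises concentration,
circular variance/SD, circular median, 95% CI of the mean direction),
uniformity tests (Rayleigh, Kuiper), two-sample tests (Kuiper, Watson
U²), a paired test on circular variables (Hotelling), circular–circular
correlation (Fisher–Lee), circular–linear correlation
(Fisher–Mardia–Jupp), and the axial 2θ+360° transform used to carry
axial angles into linear mixed models.

All public functions take and return degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats


class CircularError(ValueError):
    pass


def _rad(deg):  # noqa: D103
    return np.deg2rad(np.asarray(deg, dtype=float))


def _wrap_deg(deg):
    """Wrap to (−180, 180]."""
    d = (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(d == -180.0, 180.0, d)


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

@dataclass
class CircularSummary:
    n: int
    mean_direction: float      # degrees, NaN when undefined (R̄ = 0)
    resultant_length: float    # R̄ in [0, 1]
    ci95: tuple[float, float]  # degrees (lo, hi around the mean)
    median_direction: float    # degrees
    kappa: float               # ML von Mises concentration
    circ_variance: float       # 1 − R̄
    circ_sd: float             # sqrt(−2 ln R̄), degrees
    mean_defined: bool = True


def mean_resultant(angles_deg) -> tuple[float, float]:
    """(mean direction in degrees, resultant length R̄)."""
    th = _rad(angles_deg)
    if th.size == 0:
        raise CircularError("empty angle sample")
    C, S = np.mean(np.cos(th)), np.mean(np.sin(th))
    R = float(np.hypot(C, S))
    mu = float(np.degrees(np.arctan2(S, C)))
    return mu, R


def kappa_ml(rbar: float, tol: float = 1e-12, max_iter: int = 50) -> float:
    """Maximum-likelihood von Mises concentration from R̄.

    Inverts A1(κ) = I1(κ)/I0(κ) = R̄ with the usual piecewise starting
    approximation and Newton refinement.  No small-n bias correction.
    """
    r = float(rbar)
    if r <= 0:
        return 0.0
    if r >= 1:
        return float("inf")
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        k = 1 / (r**3 - 4 * r**2 + 3 * r)
    for _ in range(max_iter):
        a = special.i1e(k) / special.i0e(k)
        # d/dκ A1 = 1 − A1/κ − A1²
        da = 1 - a / k - a * a
        if da == 0:
            break
        step = (a - r) / da
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2
        if abs(k_new - k) < tol * max(1.0, k):
            k = k_new
            break
        k = k_new
    return float(k)


def circ_median(angles_deg) -> float:
    """Direction minimizing the mean circular distance to the sample.

    Candidates are the data points (and their antipodes); ties break to
    the smallest wrapped angle among minimizers.
    """
    a = np.atleast_1d(_wrap_deg(angles_deg))
    cands = np.unique(np.concatenate([a, _wrap_deg(a + 180.0)]))
    th = np.deg2rad(a)
    phi = np.deg2rad(cands)
    d = np.pi - np.abs(np.pi - np.abs(th[None, :] - phi[:, None]) % (2 * np.pi))
    scores = d.mean(axis=1)
    best = np.flatnonzero(np.isclose(scores, scores.min(), atol=1e-12))
    return float(cands[best].min())


def circ_summary(
    angles_deg,
    ci_method: str = "auto",
    n_boot: int = 2000,
    seed: int | None = None,
) -> CircularSummary:
    """Descriptive summary of a circular sample.

    The 95% CI of the mean direction uses the large-sample circular
    dispersion; for n < 15 (``ci_method="auto"``) a seeded bootstrap is
    used instead, since asymptotics are shaky at the study's sample size.
    """
    a = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    n = a.size
    if n == 0:
        raise CircularError("empty angle sample")
    mu, R = mean_resultant(a)
    var = 1.0 - R
    sd = float(np.degrees(np.sqrt(-2 * np.log(R)))) if R > 0 else float("inf")
    defined = R > 1e-12
    if not defined:
        mu = float("nan")
    kap = kappa_ml(R)
    med = circ_median(a)
    ci: tuple[float, float] = (float("nan"), float("nan"))
    if defined and n >= 2:
        if ci_method == "bootstrap" or (ci_method == "auto" and n < 15):
            ci = _ci_bootstrap(a, mu, n_boot, seed)
        else:
            ci = _ci_dispersion(a, mu, R)
    return CircularSummary(
        n=n, mean_direction=mu, resultant_length=R, ci95=ci,
        median_direction=med, kappa=kap, circ_variance=var, circ_sd=sd,
        mean_defined=bool(defined),
    )


def _ci_dispersion(a, mu, R) -> tuple[float, float]:
    th = _rad(a)
    n = th.size
    rho2 = float(np.mean(np.cos(2 * (th - np.deg2rad(mu)))))
    disp = (1 - rho2) / (2 * R * R)
    se = np.sqrt(disp / n)
    if 1.96 * se >= 1:
        return (float("nan"), float("nan"))
    half = float(np.degrees(np.arcsin(1.96 * se)))
    return (float(_wrap_deg(mu - half)), float(_wrap_deg(mu + half)))


def _ci_bootstrap(a, mu, n_boot, seed) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = a.size
    devs = np.empty(n_boot)
    for b in range(n_boot):
        m, _ = mean_resultant(rng.choice(a, size=n, replace=True))
        devs[b] = _wrap_deg(m - mu)
    lo, hi = np.percentile(devs, [2.5, 97.5])
    return (float(_wrap_deg(mu + lo)), float(_wrap_deg(mu + hi)))


# ---------------------------------------------------------------------------
# Uniformity tests
# ---------------------------------------------------------------------------

def rayleigh_test(angles_deg) -> tuple[float, float]:
    """Rayleigh test of uniformity; returns (Z, p)."""
    a = np.atleast_1d(np.asarray(angles_deg, float))
    n = a.size
    _, R = mean_resultant(a)
    Z = n * R * R
    p = np.exp(-Z) * (
        1 + (2 * Z - Z * Z) / (4 * n)
        - (24 * Z - 132 * Z**2 + 76 * Z**3 - 9 * Z**4) / (288 * n * n)
    )
    return float(Z), float(min(max(p, 0.0), 1.0))


def _kuiper_p(V: float, ne: float) -> float:
    lam = (np.sqrt(ne) + 0.155 + 0.24 / np.sqrt(ne)) * V
    if lam < 0.4:
        return 1.0
    k = np.arange(1, 101)
    terms = (4 * k**2 * lam**2 - 1) * np.exp(-2 * k**2 * lam**2)
    return float(min(max(2 * terms.sum(), 0.0), 1.0))


def kuiper_test(angles_deg) -> tuple[float, float]:
    """One-sample Kuiper test against circular uniformity; (Vn, p).

    Rotation-invariant (unlike Kolmogorov–Smirnov).
    """
    a = np.sort((np.asarray(angles_deg, float) % 360.0) / 360.0)
    n = a.size
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - a)
    d_minus = np.max(a - (i - 1) / n)
    V = float(d_plus + d_minus)
    return V, _kuiper_p(V, n)


def kuiper_two_sample(a_deg, b_deg) -> tuple[float, float]:
    """Two-sample Kuiper test; rotation-invariant; (V, p asymptotic)."""
    a = np.sort(np.asarray(a_deg, float) % 360.0)
    b = np.sort(np.asarray(b_deg, float) % 360.0)
    n1, n2 = a.size, b.size
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / n1
    fb = np.searchsorted(b, grid, side="right") / n2
    V = float(np.max(fa - fb) + np.max(fb - fa))
    ne = n1 * n2 / (n1 + n2)
    return V, _kuiper_p(V, ne)


def watson_u2_two_sample(a_deg, b_deg) -> tuple[float, float]:
    """Two-sample Watson U² test; rotation-invariant; (U², p asymptotic)."""
    a = np.sort(np.asarray(a_deg, float) % 360.0)
    b = np.sort(np.asarray(b_deg, float) % 360.0)
    n1, n2 = a.size, b.size
    N = n1 + n2
    grid = np.sort(np.concatenate([a, b]))
    fa = np.searchsorted(a, grid, side="right") / n1
    fb = np.searchsorted(b, grid, side="right") / n2
    d = fa - fb
    u2 = float(n1 * n2 / N**2 * np.sum((d - d.mean()) ** 2))
    if u2 < 1e-8:  # the asymptotic series does not converge at U² ≈ 0
        return u2, 1.0
    k = np.arange(1, 101)
    p = 2 * np.sum((-1.0) ** (k - 1) * np.exp(-2 * k**2 * np.pi**2 * u2))
    return u2, float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Paired and correlation statistics
# ---------------------------------------------------------------------------

def hotelling_paired(a_deg, b_deg) -> tuple[float, float]:
    """Hotelling's paired test for circular variables; (T², p).

    Per pair the rectangular difference vector (cos a − cos b,
    sin a − sin b) is formed and tested against (0, 0) with a one-sample
    Hotelling T²; p from F(2, n−2).  All-zero differences are degenerate
    and reported as (0, 1).
    """
    a = _rad(a_deg)
    b = _rad(b_deg)
    if a.shape != b.shape:
        raise CircularError("paired samples must have equal length")
    n = a.size
    if n < 3:
        raise CircularError("need at least 3 pairs")
    d = np.column_stack([np.cos(a) - np.cos(b), np.sin(a) - np.sin(b)])
    if np.allclose(d, 0):
        return 0.0, 1.0
    dbar = d.mean(axis=0)
    S = np.cov(d, rowvar=False)
    try:
        t2 = float(n * dbar @ np.linalg.solve(S, dbar))
    except np.linalg.LinAlgError:
        return float("inf"), 0.0
    f = (n - 2) / (2 * (n - 1)) * t2
    p = float(stats.f.sf(f, 2, n - 2))
    return t2, p


def _fisher_lee_r(a: np.ndarray, b: np.ndarray) -> float:
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    num = np.sum(np.triu(sa * sb, k=1))
    den = np.sqrt(np.sum(np.triu(sa * sa, k=1)) * np.sum(np.triu(sb * sb, k=1)))
    if den == 0:
        return float("nan")
    return float(num / den)


def circ_circ_corr(
    a_deg, b_deg, method: str = "jackknife", n_perm: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Fisher–Lee circular–circular correlation; (r, p).

    r = Σ_{i<j} sin(aᵢ−aⱼ) sin(bᵢ−bⱼ) /
        sqrt(Σ_{i<j} sin²(aᵢ−aⱼ) · Σ_{i<j} sin²(bᵢ−bⱼ)).

    p by jackknife normal approximation (default) or by a seeded
    permutation test.
    """
    a, b = _rad(a_deg), _rad(b_deg)
    if a.shape != b.shape:
        raise CircularError("samples must have equal length")
    n = a.size
    if n < 4:
        raise CircularError("need at least 4 pairs")
    r = _fisher_lee_r(a, b)
    if not np.isfinite(r):
        return r, float("nan")
    if method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            if abs(_fisher_lee_r(a, rng.permutation(b))) >= abs(r) - 1e-15:
                hits += 1
        return r, (hits + 1) / (n_perm + 1)
    # leave-one-out jackknife
    idx = np.arange(n)
    r_loo = np.array([_fisher_lee_r(a[idx != i], b[idx != i]) for i in idx])
    var = (n - 1) / n * np.sum((r_loo - r_loo.mean()) ** 2)
    if var <= 0:
        return r, 0.0 if abs(r) > 0 else 1.0
    z = abs(r) / np.sqrt(var)
    return r, float(2 * stats.norm.sf(z))


def circ_linear_corr(theta_deg, x) -> tuple[float, float]:
    """Fisher–Mardia–Jupp circular–linear correlation; (R, p).

    R² = (r_xc² + r_xs² − 2 r_xc r_xs r_cs) / (1 − r_cs²) with
    r_xc = corr(x, cos θ), r_xs = corr(x, sin θ), r_cs = corr(cos θ, sin θ);
    p from n·R² ~ χ²(2).
    """
    th = _rad(theta_deg)
    x = np.asarray(x, dtype=float)
    if th.shape != x.shape:
        raise CircularError("samples must have equal length")
    n = th.size
    c, s = np.cos(th), np.sin(th)
    rxc = np.corrcoef(x, c)[0, 1]
    rxs = np.corrcoef(x, s)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    r2 = (rxc**2 + rxs**2 - 2 * rxc * rxs * rcs) / (1 - rcs**2)
    r2 = float(np.clip(r2, 0.0, 1.0))
    p = float(stats.chi2.sf(n * r2, 2))
    return float(np.sqrt(r2)), p


# ---------------------------------------------------------------------------
# Axial transform (for mixed models on axial data)
# ---------------------------------------------------------------------------

def axial_transform(theta_deg):
    """2θ + 360°, the recoding that lets linear mixed models respect the
    circular topology of axial angles."""
    return 2.0 * np.asarray(theta_deg, dtype=float) + 360.0


def inverse_axial(t):
    """Exact inverse of :func:`axial_transform` (used for reporting)."""
    return (np.asarray(t, dtype=float) - 360.0) / 2.0
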