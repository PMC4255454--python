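"""Stage 2: modified liquid association (MLA) estimation.

Liquid association in Li's original sense is LA(X1, X2 | X3) = E(X1 X2 X3)
on standardized data.  MLA refines this by letting the conditional means and
variances of (X1, X2) depend on the controller X3, so the statistic isolates
change in *correlation*.  Two estimators are provided:

* a trivariate conditional normal model (CNM): given X3 = z,

      (X1, X2) ~ BVN( mu_i(z) = m_i0 + m_i1 z,
                      sigma_i^2(z) = exp(v_i0 + v_i1 z),
                      rho(z) = tanh(c0 + c1 z) )

  fitted by maximum likelihood.  The "full" model frees all ten parameters;
  the "simple" model fixes the mean/variance dependence (m11 = m21 = v11 =
  v21 = 0) and keeps only the correlation dependence.  The null of no
  liquid association is c1 = 0, tested by the Wald statistic
  (c1 / SE(c1))^2 with p = 2 Phi(-sqrt(W)).

* a robust direct estimate: bin samples into equal-count bins of X3
  (3 by default), re-standardize X1 and X2 within each bin, and average
  x1* x2* x3 over all samples; a bootstrap over samples gives its standard
  error.  Used when the CNM fits poorly.

The estimation cascade runs full CNM -> simple CNM -> robust, moving on
whenever a lack-of-fit check fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm, shapiro
from statsmodels.tools.numdiff import approx_hess1

logger = logging.getLogger("fastla")

_LOG_2PI = np.log(2.0 * np.pi)


class EstimationError(ValueError):
    """Raised for degenerate inputs during estimation."""


@dataclass
class CNMFit:
    """A fitted conditional normal model.

    ``mean_coefs`` = (m10, m11, m20, m21), ``logvar_coefs`` = (v10, v11,
    v20, v21), ``corr_coefs`` = (c0, c1).  ``cov`` is the inverse observed
    information over the free parameters.  ``wald`` = (c1 / SE(c1))^2 and
    ``pvalue`` = 2 Phi(-sqrt(wald)); ``mla_estimate`` is the model-based MLA
    averaged over the observed controller values.
    """

    model_tag: str
    mean_coefs: tuple[float, float, float, float]
    logvar_coefs: tuple[float, float, float, float]
    corr_coefs: tuple[float, float]
    loglik: float
    converged: bool
    cov: np.ndarray
    wald: float
    pvalue: float
    mla_estimate: float


@dataclass
class RobustEstimate:
    """Direct MLA estimate with a bootstrap standard error."""

    mla_estimate: float
    se_boot: float
    pvalue: float
    n_boot: int
    seed: int
    n_redrawn: int = 0


# ---------------------------------------------------------------------------
# direct estimator


def equal_count_bins(values: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Equal-count bin index sets over sorted ``values`` (no missing).

    Remainder samples go to the outermost bins first (lowest, then highest,
    working inward); ties broken by a stable sort on original index.
    """
    n = values.size
    if n < 3 * n_bins:
        raise EstimationError(f"need >= {3 * n_bins} values for {n_bins} bins")
    sizes = np.full(n_bins, n // n_bins)
    extras = n % n_bins
    outer = []
    lo, hi = 0, n_bins - 1
    while lo <= hi:
        outer.append(lo)
        if hi != lo:
            outer.append(hi)
        lo, hi = lo + 1, hi - 1
    for k in range(extras):
        sizes[outer[k]] += 1
    order = np.argsort(values, kind="stable")
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [order[edges[b]:edges[b + 1]] for b in range(n_bins)]


def _conditional_standardize(x: np.ndarray, bins: list[np.ndarray]) -> np.ndarray:
    """Re-center/scale x to mean 0, sd 1 (population sd) within each bin."""
    out = np.empty_like(x)
    for idx in bins:
        sub = x[idx]
        sd = sub.std()
        if sd == 0.0:
            raise EstimationError("zero within-bin variance")
        out[idx] = (sub - sub.mean()) / sd
    return out


def _complete_cases(*vectors: np.ndarray) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise EstimationError("triplet vectors must have equal length")
    obs = ~np.any([np.isnan(a) for a in arrs], axis=0)
    return tuple(a[obs] for a in arrs)


def binned_controller(x3: np.ndarray, bins: list[np.ndarray]) -> np.ndarray:
    """Replace each controller value by its bin mean (discretized X3)."""
    out = np.empty_like(x3)
    for idx in bins:
        out[idx] = x3[idx].mean()
    return out


def mla_direct(x1: np.ndarray, x2: np.ndarray, x3: np.ndarray,
               n_bins: int = 3) -> float:
    """Direct MLA estimate: bin on x3, conditionally standardize, average.

    Samples are split into ``n_bins`` equal-count bins of x3; within each
    bin x1 and x2 are re-centered and re-scaled (the "modified" adjustment
    removing conditional mean/variance effects, making the within-bin mean
    of x1* x2* exactly the within-bin Pearson correlation) and x3 is
    discretized to its bin mean; the estimate is the mean of
    x1* x2* x3bar over all samples, i.e. sum_b (n_b/n) rho_b x3bar_b.
    On marginally normal x3 its magnitude is bounded by the mean absolute
    bin mean — sqrt(2/pi) for a median split, about 0.73 for tertiles.
    """
    x1, x2, x3 = _complete_cases(x1, x2, x3)
    bins = equal_count_bins(x3, n_bins)
    z1 = _conditional_standardize(x1, bins)
    z2 = _conditional_standardize(x2, bins)
    return float(np.mean(z1 * z2 * binned_controller(x3, bins)))


def robust_estimate(x1: np.ndarray, x2: np.ndarray, x3: np.ndarray,
                    n_bins: int = 3, n_boot: int = 1000,
                    seed: int = 0) -> RobustEstimate:
    """Direct MLA estimate with a bootstrap-over-samples standard error.

    Resamples with replacement ``n_boot`` times; a resample whose bins are
    degenerate (zero within-bin variance) is redrawn.  The two-sided p-value
    uses the normal approximation 2 Phi(-|est| / SE).
    """
    if n_boot < 100:
        raise EstimationError("n_boot must be >= 100")
    x1, x2, x3 = _complete_cases(x1, x2, x3)
    est = mla_direct(x1, x2, x3, n_bins)
    rng = np.random.default_rng(seed)
    n = x1.size
    boot = np.empty(n_boot)
    n_redrawn = 0
    b = 0
    max_draws = 20 * n_boot
    draws = 0
    while b < n_boot:
        draws += 1
        if draws > max_draws:
            raise EstimationError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, n, n)
        try:
            boot[b] = mla_direct(x1[idx], x2[idx], x3[idx], n_bins)
        except EstimationError:
            n_redrawn += 1
            continue
        b += 1
    if n_redrawn:
        logger.info("robust_estimate: redrew %d degenerate resamples", n_redrawn)
    se = float(boot.std(ddof=1))
    p = float(2.0 * norm.cdf(-abs(est) / se)) if se > 0 else 1.0
    return RobustEstimate(est, se, max(p, np.finfo(float).tiny), n_boot,
                          seed, n_redrawn)


# ---------------------------------------------------------------------------
# conditional normal model

_FULL_NAMES = ("m10", "m11", "m20", "m21", "v10", "v11", "v20", "v21", "c0", "c1")


def _unpack(theta: np.ndarray, simple: bool) -> np.ndarray:
    """Expand a simple-model parameter vector to the full 10-vector."""
    if not simple:
        return theta
    m10, m20, v10, v20, c0, c1 = theta
    return np.array([m10, 0.0, m20, 0.0, v10, 0.0, v20, 0.0, c0, c1])


def _nll_terms(theta10, x1, x2, z):
    m10, m11, m20, m21, v10, v11, v20, v21, c0, c1 = theta10
    v1 = v10 + v11 * z
    v2 = v20 + v21 * z
    s1 = np.exp(0.5 * v1)
    s2 = np.exp(0.5 * v2)
    e1 = (x1 - m10 - m11 * z) / s1
    e2 = (x2 - m20 - m21 * z) / s2
    r = np.tanh(c0 + c1 * z)
    d = 1.0 - r * r
    q = e1 * e1 - 2.0 * r * e1 * e2 + e2 * e2
    nll = np.sum(_LOG_2PI + 0.5 * (v1 + v2) + 0.5 * np.log(d) + q / (2.0 * d))
    return nll, (s1, s2, e1, e2, r, d, q)


def _nll_grad(theta: np.ndarray, x1, x2, z, simple: bool):
    """Negative log-likelihood and analytic gradient (free parameters)."""
    theta10 = _unpack(theta, simple)
    nll, (s1, s2, e1, e2, r, d, q) = _nll_terms(theta10, x1, x2, z)
    # d nll / d mu_i, v_i (per sample), then chain through the linear forms
    g_mu1 = (-e1 + r * e2) / (s1 * d)
    g_mu2 = (-e2 + r * e1) / (s2 * d)
    g_v1 = 0.5 + (-e1 * e1 + r * e1 * e2) / (2.0 * d)
    g_v2 = 0.5 + (-e2 * e2 + r * e1 * e2) / (2.0 * d)
    g_a = -r - e1 * e2 + q * r / d  # a = c0 + c1 z
    full = np.array([
        g_mu1.sum(), (g_mu1 * z).sum(),
        g_mu2.sum(), (g_mu2 * z).sum(),
        g_v1.sum(), (g_v1 * z).sum(),
        g_v2.sum(), (g_v2 * z).sum(),
        g_a.sum(), (g_a * z).sum(),
    ])
    if simple:
        full = full[[0, 2, 4, 6, 8, 9]]
    return nll, full


def _corr_slope_init(x1, x2, z) -> tuple[float, float]:
    """Initialize (c0, c1) from tertile correlations on the Fisher-z scale."""
    try:
        bins = equal_count_bins(z, 3)
    except EstimationError:
        return 0.0, 0.0
    zs, fs = [], []
    for idx in bins:
        a, b = x1[idx], x2[idx]
        if a.std() == 0 or b.std() == 0:
            continue
        rho = np.clip(np.corrcoef(a, b)[0, 1], -0.99, 0.99)
        zs.append(z[idx].mean())
        fs.append(np.arctanh(rho))
    if len(fs) < 2:
        return 0.0, 0.0
    slope, intercept = np.polyfit(zs, fs, 1)
    return float(intercept), float(slope)


def fit_cnm(x1: np.ndarray, x2: np.ndarray, x3: np.ndarray,
            model_tag: str = "full", max_iter: int = 500) -> CNMFit:
    """Fit the conditional normal model by maximum likelihood.

    The full model is initialized from per-variable linear regressions on z
    and tertile correlations on the Fisher-z scale; the simple model from
    global moments.  Optimization is quasi-Newton (BFGS) on the analytic
    gradient.  A failed optimization returns ``converged=False`` rather than
    raising.  The parameter covariance is the inverse observed information
    (numerical Hessian at the optimum).
    """
    if model_tag not in ("full", "simple"):
        raise EstimationError(f"unknown model tag {model_tag!r}")
    x1, x2, x3 = _complete_cases(x1, x2, x3)
    n = x1.size
    if n < 20:
        raise EstimationError(f"need >= 20 jointly observed samples, got {n}")
    if x1.std() == 0 or x2.std() == 0 or x3.std() == 0:
        raise EstimationError("degenerate (constant) input vector")
    z = x3
    simple = model_tag == "simple"
    c0, c1 = _corr_slope_init(x1, x2, z)
    if simple:
        theta0 = np.array([x1.mean(), x2.mean(),
                           np.log(x1.var()), np.log(x2.var()), c0, c1])
    else:
        b1 = np.polyfit(z, x1, 1)
        b2 = np.polyfit(z, x2, 1)
        r1 = x1 - np.polyval(b1, z)
        r2 = x2 - np.polyval(b2, z)
        theta0 = np.array([b1[1], b1[0], b2[1], b2[0],
                           np.log(r1.var()), 0.0, np.log(r2.var()), 0.0,
                           c0, c1])

    res = optimize.minimize(
        _nll_grad, theta0, args=(x1, x2, z, simple), jac=True,
        method="BFGS", options={"maxiter": max_iter, "gtol": 1e-8 * n},
    )
    theta = res.x
    converged = bool(res.success) or (np.max(np.abs(res.jac)) < 1e-5 * n)

    def nll_only(t):
        return _nll_grad(t, x1, x2, z, simple)[0]

    k = theta.size
    try:
        hess = approx_hess1(theta, nll_only)
        cov = np.linalg.inv(hess)
        if not np.all(np.isfinite(cov)) or cov[k - 1, k - 1] <= 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False

    theta10 = _unpack(theta, simple)
    se_c1 = float(np.sqrt(cov[k - 1, k - 1])) if np.isfinite(cov[k - 1, k - 1]) else np.nan
    c1_hat = theta10[9]
    wald = float((c1_hat / se_c1) ** 2) if np.isfinite(se_c1) and se_c1 > 0 else np.nan
    pval = wald_pvalue(wald) if np.isfinite(wald) else np.nan
    mla = float(c1_hat * np.mean(1.0 - np.tanh(theta10[8] + c1_hat * z) ** 2))
    return CNMFit(
        model_tag=model_tag,
        mean_coefs=tuple(theta10[:4]),
        logvar_coefs=tuple(theta10[4:8]),
        corr_coefs=(float(theta10[8]), float(c1_hat)),
        loglik=float(-res.fun),
        converged=converged,
        cov=cov,
        wald=wald,
        pvalue=pval,
        mla_estimate=mla,
    )


def wald_pvalue(wald: float) -> float:
    """Two-sided p-value of the z-statistic whose square is the Wald stat."""
    if wald < 0:
        raise EstimationError("Wald statistic must be non-negative")
    return float(min(max(2.0 * norm.cdf(-np.sqrt(wald)), np.finfo(float).tiny), 1.0))


def mla_from_cnm(fit: CNMFit, x3: np.ndarray) -> float:
    """Model-based MLA: mean derivative of rho(z) over the controller values.

    d/dz tanh(c0 + c1 z) = c1 (1 - tanh^2(c0 + c1 z)), averaged over the
    observed z.  Exactly 0 when c1 = 0.
    """
    if not fit.converged:
        raise EstimationError("cannot compute MLA from a non-converged fit")
    c0, c1 = fit.corr_coefs
    z = np.asarray(x3, dtype=float)
    z = z[~np.isnan(z)]
    return float(c1 * np.mean(1.0 - np.tanh(c0 + c1 * z) ** 2))


def lack_of_fit(fit: CNMFit, x1: np.ndarray, x2: np.ndarray, x3: np.ndarray,
                corr_tol: float = 0.35, alpha: float = 0.01) -> bool:
    """Decide whether the CNM inadequately describes the triplet.

    True when any of: the fit did not converge; a within-tertile empirical
    correlation deviates from the model-implied tanh(c0 + c1 zbar) by more
    than ``corr_tol`` (catches non-linear correlation profiles such as
    U-shapes); or a Shapiro-Wilk test rejects normality of the model's
    standardized, decorrelated residuals at level ``alpha`` (split over the
    two residual series).  Tolerances are configurable.
    """
    if not fit.converged:
        return True
    x1, x2, x3 = _complete_cases(x1, x2, x3)
    theta10 = np.array([*fit.mean_coefs, *fit.logvar_coefs, *fit.corr_coefs])
    _, (s1, s2, e1, e2, r, d, _) = _nll_terms(theta10, x1, x2, x3)
    c0, c1 = fit.corr_coefs
    for idx in equal_count_bins(x3, 3):
        a, b = x1[idx], x2[idx]
        if a.std() == 0 or b.std() == 0:
            return True
        emp = np.corrcoef(a, b)[0, 1]
        implied = np.tanh(c0 + c1 * x3[idx].mean())
        if abs(emp - implied) > corr_tol:
            return True
    # under the model e1 and (e2 - r e1)/sqrt(1-r^2) are iid standard normal
    u2 = (e2 - r * e1) / np.sqrt(d)
    for resid in (e1, u2):
        sample = resid if resid.size <= 5000 else resid[:5000]
        if shapiro(sample).pvalue < alpha / 2.0:
            return True
    return False


# ---------------------------------------------------------------------------
# cascade


@dataclass
class TripletEstimate:
    """Outcome of the full -> simple -> robust estimation cascade."""

    mla: float
    wald: float
    pvalue: float
    model: str  # F, S or R


def estimate_triplet(x1: np.ndarray, x2: np.ndarray, x3: np.ndarray,
                     n_bins: int = 3, n_boot: int = 1000, seed: int = 0,
                     lof_corr_tol: float = 0.35, lof_alpha: float = 0.01,
                     max_iter: int = 500) -> TripletEstimate:
    """Run the estimation cascade for one screened triplet.

    Fits the full CNM; on lack of fit refits the simple CNM; on lack of fit
    again falls back to the robust direct estimate with bootstrap standard
    error.  The model code records which estimate is reported (F/S/R).
    """
    x1, x2, x3 = _complete_cases(x1, x2, x3)
    for tag, code in (("full", "F"), ("simple", "S")):
        try:
            fit = fit_cnm(x1, x2, x3, tag, max_iter=max_iter)
        except EstimationError:
            break
        if not lack_of_fit(fit, x1, x2, x3, lof_corr_tol, lof_alpha):
            return TripletEstimate(fit.mla_estimate, fit.wald, fit.pvalue, code)
    rob = robust_estimate(x1, x2, x3, n_bins, n_boot, seed)
    wald = (rob.mla_estimate / rob.se_boot) ** 2 if rob.se_boot > 0 else np.nan
    return TripletEstimate(rob.mla_estimate, float(wald), rob.pvalue, "R")
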