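"""Causal-effect estimators for summary-level two-sample MR.

The main analysis is the inverse variance-weighted (IVW) estimator

    theta_ivw = sum_j w_j beta_jy beta_jx / sum_j w_j beta_jx^2,
    w_j = 1 / var(beta_jy),

i.e. a weighted regression of outcome effects on exposure effects through the
origin with first-order weights.  Each sensitivity estimator relaxes a
different instrument-validity assumption: MR-Egger allows a common directional
pleiotropy intercept (valid under InSIDE); the weighted median tolerates up to
half invalid instruments by weight; the mode-based estimate (MBE) requires
only the largest group of instruments to be valid; MR-Robust downweights
outlying instruments with a Huber loss; MR-RAPS maximizes a robust adjusted
profile score that also accounts for exposure-side sampling error and an
overdispersion parameter.

Confidence intervals are normal-theory (theta +- 1.96 se) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .harmonize import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)
HUBER_C = 1.345


class EstimationError(ValueError):
    pass


class UnitError(ValueError):
    pass


@dataclass
class MREstimate:
    """One method's causal-effect estimate on the per-exposure-SD scale."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_iv: int
    scale: str = "linear"  # linear | log_odds
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.n_iv < 1:
            raise ValueError("n_iv must be >= 1")
        if not (self.ci_low <= self.theta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class OddsRatioEstimate:
    method: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    pval: float
    n_iv: int


@dataclass
class RatioEstimates:
    """Per-instrument Wald ratios and first-order inverse-variance weights."""

    ratios: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ratios) != len(self.weights):
            raise ValueError("ratios and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")


def _wald_p(theta: float, se: float) -> float:
    if se == 0:
        return 0.0 if theta != 0 else 1.0
    return float(2 * stats.norm.sf(abs(theta) / se))


def _estimate(method, theta, se, n_iv, scale, extras) -> MREstimate:
    return MREstimate(
        method=method, theta=float(theta), se=float(se),
        ci_low=float(theta - Z95 * se), ci_high=float(theta + Z95 * se),
        pval=_wald_p(theta, se), n_iv=int(n_iv), scale=scale, extras=extras,
    )


def _scale_of(hset: HarmonizedSet) -> str:
    return "log_odds" if hset.outcome_type == "binary" else "linear"


def ratio_estimates(hset: HarmonizedSet) -> RatioEstimates:
    bx, _sx, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise EstimationError("ratio estimates undefined for beta_x = 0")
    return RatioEstimates(ratios=by / bx, weights=bx**2 / sy**2)


# ---------------------------------------------------------------------------
# IVW and Cochran's Q


def cochran_q(hset: HarmonizedSet, theta: float) -> tuple[float, int]:
    """Heterogeneity statistic Q = sum w_j (beta_jy - theta beta_jx)^2, df = k-1."""
    if hset.n_iv < 2:
        raise EstimationError("Cochran Q needs at least 2 instruments")
    bx, _sx, by, sy = hset.arrays()
    q = float(np.sum((by - theta * bx) ** 2 / sy**2))
    return q, hset.n_iv - 1


def ivw_estimate(hset: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse variance-weighted estimate.

    ``model="fixed"`` uses the analytic fixed-effect standard error
    (sum w_j beta_jx^2)^(-1/2); ``model="multiplicative_random"`` (default,
    the field-standard "random IVW") inflates it by max(1, sqrt(Q/(k-1))) so
    heterogeneity can widen but never narrow the interval.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown model {model!r}")
    k = hset.n_iv
    if k < 1 or (model == "multiplicative_random" and k < 2):
        raise EstimationError(f"too few instruments (k={k}) for IVW model {model}")
    bx, _sx, by, sy = hset.arrays()
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise EstimationError("all exposure effects are zero; IVW undefined")
    theta = float(np.sum(w * by * bx)) / denom
    se = denom ** -0.5
    extras: dict = {"model": model}
    if k >= 2:
        q, df = cochran_q(hset, theta)
        extras["Q"] = q
        extras["Q_df"] = df
        inflation = max(1.0, np.sqrt(q / df))
        extras["inflation"] = inflation
        if model == "multiplicative_random":
            se *= inflation
    return _estimate("ivw", theta, se, k, _scale_of(hset), extras)


# ---------------------------------------------------------------------------
# MR-Egger


def egger_estimate(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: WLS of beta_y on beta_x with an intercept.

    Instruments are first oriented so every beta_x >= 0 (both betas negated
    where needed), the convention that makes the intercept interpretable as
    average directional pleiotropy.  Standard errors are inflated by
    max(1, residual scale).  The intercept, its se and p-value are in
    ``extras`` ("egger_intercept", "intercept_se", "intercept_pval").
    """
    if hset.n_iv < 3:
        raise EstimationError("MR-Egger needs at least 3 instruments")
    bx, _sx, by, sy = hset.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.allclose(bx, bx[0]):
        raise EstimationError("exposure effects collinear after orientation")
    import statsmodels.api as sm

    X = sm.add_constant(bx)
    res = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    k = hset.n_iv
    # statsmodels scales by the residual variance; clamp the inflation at 1
    # (use the unscaled covariance so a perfect fit keeps finite se's)
    sigma = float(np.sqrt(res.scale))
    base_se = np.sqrt(np.diag(res.normalized_cov_params))
    se_int, se_slope = base_se * max(1.0, sigma)
    intercept, slope = float(res.params[0]), float(res.params[1])
    extras = {
        "egger_intercept": intercept,
        "intercept_se": float(se_int),
        "intercept_pval": _wald_p(intercept, float(se_int)),
        "residual_scale": float(sigma),
    }
    return _estimate("egger", slope, se_slope, k, _scale_of(hset), extras)


# ---------------------------------------------------------------------------
# Weighted median


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(s, 0.5))
    # interpolate linearly between the bracketing ratios
    return float(r[j - 1] + (r[j] - r[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1]))


def weighted_median_estimate(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the Wald ratios; consistent when valid instruments
    carry at least half the weight.  Standard error by parametric bootstrap.
    """
    if hset.n_iv < 3:
        raise EstimationError("weighted median needs at least 3 instruments")
    bx, sx, by, sy = hset.arrays()
    re = ratio_estimates(hset)
    theta = _weighted_median(re.ratios, re.weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(hset.n_iv)
        byb = by + sy * rng.standard_normal(hset.n_iv)
        bxb = np.where(bxb == 0, 1e-300, bxb)
        boots[b] = _weighted_median(byb / bxb, bxb**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    extras = {"n_boot": n_boot, "seed": seed}
    return _estimate("wmedian", theta, se, hset.n_iv, _scale_of(hset), extras)


# ---------------------------------------------------------------------------
# Mode-based estimate (MBE)


def _mbe_point(ratios: np.ndarray, kweights: np.ndarray, phi: float) -> tuple[float, float]:
    """Maximizer of the weighted normal-kernel density of the ratios."""
    k = len(ratios)
    s = float(np.std(ratios, ddof=1)) if k > 1 else 0.0
    iqr = float(stats.iqr(ratios))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    h = phi * 0.9 * spread * k ** (-1 / 5)
    if h <= 0:
        return float(ratios[0]), 0.0
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = (kweights[None, :] * stats.norm.pdf((grid[:, None] - ratios[None, :]) / h)).sum(axis=1)
    i = int(np.argmax(dens))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, 511)]

    def negdens(x: float) -> float:
        return -float((kweights * stats.norm.pdf((x - ratios) / h)).sum())

    res = optimize.minimize_scalar(negdens, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-12})
    return float(res.x), h


def mode_based_estimate(
    hset: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted mode of the Wald ratios (normal-kernel density maximizer).

    Bandwidth is ``phi`` times a modified Silverman rule on the ratios;
    kernel weights are the first-order inverse ratio variances.  If every
    ratio coincides the common value is returned directly.  Standard error by
    parametric bootstrap.
    """
    if hset.n_iv < 3:
        raise EstimationError("mode-based estimate needs at least 3 instruments")
    bx, sx, by, sy = hset.arrays()
    re = ratio_estimates(hset)
    theta, h = _mbe_point(re.ratios, re.weights, phi)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(hset.n_iv)
        byb = by + sy * rng.standard_normal(hset.n_iv)
        bxb = np.where(bxb == 0, 1e-300, bxb)
        boots[b], _ = _mbe_point(byb / bxb, bxb**2 / sy**2, phi)
    se = float(np.std(boots, ddof=1))
    extras = {"bandwidth": h, "phi": phi, "n_boot": n_boot, "seed": seed}
    return _estimate("mbe", theta, se, hset.n_iv, _scale_of(hset), extras)


# ---------------------------------------------------------------------------
# MR-Robust (Huber IRLS through the origin)


def robust_ivw_estimate(hset: HarmonizedSet) -> MREstimate:
    """IVW with Huber robust regression (MR-Robust).

    Weighted regression through the origin of beta_y on beta_x fitted by
    iteratively reweighted least squares with Huber loss (tuning 1.345, MAD
    scale), equivalent to robust regression of by/sy on bx/sy.  Falls back to
    the exact weighted fit when the residual scale degenerates to zero
    (perfect proportionality).
    """
    if hset.n_iv < 3:
        raise EstimationError("MR-Robust needs at least 3 instruments")
    bx, _sx, by, sy = hset.arrays()
    xs = bx / sy
    ys = by / sy
    denom = float(xs @ xs)
    if denom == 0:
        raise EstimationError("all exposure effects are zero")
    theta0 = float(xs @ ys) / denom
    resid0 = ys - theta0 * xs
    mad = stats.median_abs_deviation(resid0, scale="normal")
    extras: dict = {"loss": "huber", "tuning": HUBER_C}
    if mad < 1e-12 and np.max(np.abs(resid0)) < 1e-10 * max(1.0, np.max(np.abs(ys))):
        # perfect fit: robust weighting is immaterial, return the exact WLS fit
        return _estimate("robust", theta0, denom ** -0.5, hset.n_iv, _scale_of(hset), extras)
    import statsmodels.api as sm

    model = sm.RLM(ys, xs[:, None], M=sm.robust.norms.HuberT(t=HUBER_C))
    res = model.fit(maxiter=200, tol=1e-10)
    if not np.isfinite(res.params[0]):
        raise EstimationError("MR-Robust IRLS failed to converge within 200 iterations")
    extras["scale"] = float(res.scale)
    return _estimate("robust", float(res.params[0]), float(res.bse[0]),
                     hset.n_iv, _scale_of(hset), extras)


# ---------------------------------------------------------------------------
# MR-RAPS (robust adjusted profile score)


def _huber_psi(t: np.ndarray) -> np.ndarray:
    return np.clip(t, -HUBER_C, HUBER_C)


# E[psi(Z) Z] for Z ~ N(0,1): the centering constant of the overdispersion
# moment equation (= 1 for the identity psi).
_HUBER_DELTA = float(2 * stats.norm.cdf(HUBER_C) - 1)


def _raps_t(theta, tau2, bx, sx, by, sy):
    v = sy**2 + theta**2 * sx**2 + tau2
    return (by - theta * bx) / np.sqrt(v), v


def _raps_score(theta, tau2, bx, sx, by, sy, psi):
    t, v = _raps_t(theta, tau2, bx, sx, by, sy)
    dt = (-bx * v - (by - theta * bx) * theta * sx**2) / v**1.5
    return float(np.sum(psi(t) * dt))


def _solve_root(f, x0: float, step: float, max_expand: int = 60) -> float:
    lo, hi = x0 - step, x0 + step
    flo, fhi = f(lo), f(hi)
    n = 0
    while flo * fhi > 0:
        lo -= step
        hi += step
        step *= 1.5
        flo, fhi = f(lo), f(hi)
        n += 1
        if n >= max_expand:
            raise EstimationError("no sign change in bracket after expansion")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def raps_estimate(
    hset: HarmonizedSet, loss: str = "huber", overdispersion: bool = True
) -> MREstimate:
    """MR-RAPS: profile-score estimation using both sampling variances.

    Solves sum_j psi(t_j) dt_j/dtheta = 0 with standardized residuals
    t_j = (beta_jy - theta beta_jx) / sqrt(se_jy^2 + theta^2 se_jx^2 + tau^2);
    psi is the identity (``loss="squared"``) or Huber-clipped at 1.345
    (``loss="huber"``).  With ``overdispersion`` the systematic-pleiotropy
    variance tau^2 >= 0 is profiled out from the second moment equation
    sum_j [psi(t_j) t_j - delta] = 0.  Sandwich standard error.
    """
    if hset.n_iv < 3:
        raise EstimationError("MR-RAPS needs at least 3 instruments")
    if loss not in ("squared", "huber"):
        raise ValueError(f"unknown loss {loss!r}")
    psi = _huber_psi if loss == "huber" else (lambda t: t)
    delta = _HUBER_DELTA if loss == "huber" else 1.0
    bx, sx, by, sy = hset.arrays()

    ivw_theta = float(np.sum(by * bx / sy**2) / np.sum(bx**2 / sy**2))
    ivw_se = float(np.sum(bx**2 / sy**2)) ** -0.5
    theta, tau2 = ivw_theta, 0.0
    for _ in range(200):
        theta_new = _solve_root(
            lambda th: _raps_score(th, tau2, bx, sx, by, sy, psi),
            theta, max(4 * ivw_se, 0.25),
        )
        tau2_new = 0.0
        if overdispersion:
            def moment(t2):
                t, _ = _raps_t(theta_new, t2, bx, sx, by, sy)
                return float(np.sum(psi(t) * t) - len(t) * delta)

            if moment(0.0) > 0:
                hi = float(np.mean(sy**2))
                while moment(hi) > 0:
                    hi *= 4
                    if hi > 1e8:
                        raise EstimationError("overdispersion solve diverged")
                tau2_new = float(optimize.brentq(moment, 0.0, hi, xtol=1e-14))
        if abs(theta_new - theta) < 1e-10 and abs(tau2_new - tau2) < 1e-12:
            theta, tau2 = theta_new, tau2_new
            break
        theta, tau2 = theta_new, tau2_new

    # sandwich variance: Var(S)/ (dS/dtheta)^2 at the solution
    t, _v = _raps_t(theta, tau2, bx, sx, by, sy)
    dt = (-bx * _v - (by - theta * bx) * theta * sx**2) / _v**1.5
    var_s = float(np.sum(psi(t) ** 2 * dt**2))
    eps = 1e-6 * max(abs(theta), 1.0)
    ds = (
        _raps_score(theta + eps, tau2, bx, sx, by, sy, psi)
        - _raps_score(theta - eps, tau2, bx, sx, by, sy, psi)
    ) / (2 * eps)
    se = np.sqrt(var_s) / abs(ds) if ds != 0 else float("inf")
    extras = {"tau2": float(tau2), "loss": loss, "overdispersion": overdispersion}
    return _estimate("raps", theta, float(se), hset.n_iv, _scale_of(hset), extras)


# ---------------------------------------------------------------------------
# Reporting scale


def to_odds_ratio(est: MREstimate) -> OddsRatioEstimate:
    """Exponentiate a log-odds estimate into an odds ratio with its CI."""
    if est.scale != "log_odds":
        raise UnitError(
            f"estimate for a {est.scale}-scale outcome cannot be exponentiated to an OR"
        )
    return OddsRatioEstimate(
        method=est.method,
        odds_ratio=float(np.exp(est.theta)),
        ci_low=float(np.exp(est.ci_low)),
        ci_high=float(np.exp(est.ci_high)),
        pval=est.pval,
        n_iv=est.n_iv,
    )


#: registry used by the pipeline/CLI `--methods` flag
METHODS = ("ivw", "egger", "wmedian", "mbe", "robust", "raps")
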