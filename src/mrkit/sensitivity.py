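"""Outlier and pleiotropy diagnostics: leave-one-out, MR-PRESSO, plot data.

MR-PRESSO tests for horizontal pleiotropy through the residual sum of squares
of the IVW fit: the *global* test compares the observed leave-one-out weighted
RSS with its parametric-simulation null distribution; the *outlier* test
compares each instrument's residual contribution with its simulated
counterpart (two-sided, Bonferroni-adjusted); the *distortion* test asks
whether removing the flagged instruments changes the causal estimate more
than removing a random subset of the same size would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import EstimationError, MREstimate, ivw_estimate, ratio_estimates
from .harmonize import HarmonizedSet
from .sumstats import VariantKey


@dataclass
class LooResult:
    """Leave-one-out IVW estimates plus the full-set estimate."""

    estimates: list[MREstimate]
    full: MREstimate
    left_out: list[VariantKey] = field(default_factory=list)


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_pvals: list[float]
    outliers: list[VariantKey]
    corrected: MREstimate | None
    distortion_p: float | None
    n_sim: int
    seed: int


@dataclass
class FunnelData:
    """Per-IV ratio estimates vs precision, for funnel-plot symmetry checks.

    ``asymmetry_score`` (precision-weighted mean signed deviation from the
    full-set estimate) is a numeric companion to the visual check.
    """

    ratios: np.ndarray
    precisions: np.ndarray
    reference: float
    asymmetry_score: float


@dataclass
class ScatterData:
    table: "pd.DataFrame"  # noqa: F821 - imported lazily
    fits: list[tuple[str, float, float]]  # (method, slope, intercept)


def leave_one_out(hset: HarmonizedSet, model: str = "multiplicative_random") -> LooResult:
    """IVW estimate recomputed with each instrument left out in turn."""
    if hset.n_iv < 3:
        raise EstimationError("leave-one-out needs at least 3 instruments")
    full = ivw_estimate(hset, model=model)
    estimates = []
    left_out = []
    for j in range(hset.n_iv):
        sub = hset.subset([i for i in range(hset.n_iv) if i != j])
        est = ivw_estimate(sub, model=model)
        key = hset.instruments[j].key
        est.extras["left_out"] = key.rsid or f"{key.chrom}:{key.pos}"
        estimates.append(est)
        left_out.append(key)
    return LooResult(estimates=estimates, full=full, left_out=left_out)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized (supports batched 2-D input)."""
    num = np.sum(w * by * bx, axis=-1, keepdims=True)
    den = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (num - w * by * bx) / (den - w * bx**2)


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    sig: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    Observed statistic: RSS = sum_j w_j (beta_jy - theta_{-j} beta_jx)^2 with
    theta_{-j} the leave-one-out IVW slope and w_j = 1/se_jy^2.  The null
    distribution comes from ``n_sim`` parametric draws of (beta_jx*, beta_jy*)
    centered on the expected values under theta_{-j}.  Outliers are flagged at
    Bonferroni-adjusted two-sided p < ``sig``; the corrected estimate is IVW
    after their removal.
    """
    k = hset.n_iv
    if k < 4:
        raise EstimationError(f"MR-PRESSO needs at least 4 instruments, got {k}")
    bx, sx, by, sy = hset.arrays()
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx[None, :], by[None, :], w[None, :])[0]
    resid_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    bx_sim = bx + sx * rng.standard_normal((n_sim, k))
    by_sim = theta_loo * bx + sy * rng.standard_normal((n_sim, k))
    theta_loo_sim = _loo_slopes(bx_sim, by_sim, np.broadcast_to(w, (n_sim, k)))
    resid_sim = w * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)
    global_p = float(np.mean(rss_sim >= rss_obs))

    # per-IV two-sided simulation p-values, Bonferroni over k
    p_upper = np.mean(resid_sim >= resid_obs[None, :], axis=0)
    p_two = 2 * np.minimum(p_upper, 1 - p_upper)
    p_adj = np.minimum(p_two * k, 1.0)
    flagged = np.flatnonzero(p_adj < sig)
    outlier_keys = [hset.instruments[int(j)].key for j in flagged]

    corrected = None
    distortion_p = None
    if len(flagged) > 0:
        keep = [i for i in range(k) if i not in set(flagged.tolist())]
        if len(keep) >= 2:
            corrected = ivw_estimate(hset.subset(keep))
            full_theta = float(np.sum(w * by * bx) / np.sum(w * bx**2))
            corr_theta = corrected.theta
            if corr_theta != 0:
                d_obs = 100.0 * (full_theta - corr_theta) / abs(corr_theta)
                n_out = len(flagged)
                d_null = np.empty(n_sim)
                keep_arr = np.array(keep)
                for b in range(n_sim):
                    drop = rng.choice(keep_arr, size=n_out, replace=True)
                    mask = np.ones(k, dtype=bool)
                    mask[drop] = False
                    th = float(np.sum(w[mask] * by[mask] * bx[mask])
                               / np.sum(w[mask] * bx[mask] ** 2))
                    d_null[b] = 100.0 * (full_theta - th) / abs(th) if th != 0 else np.inf
                distortion_p = float(np.mean(np.abs(d_null) >= abs(d_obs)))

    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_pvals=[float(p) for p in p_adj],
        outliers=outlier_keys,
        corrected=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


def funnel_data(hset: HarmonizedSet, full: MREstimate) -> FunnelData:
    """Per-IV ratio estimates and precisions for a funnel plot."""
    if hset.n_iv < 1:
        raise EstimationError("funnel data needs at least 1 instrument")
    re = ratio_estimates(hset)
    bx, _sx, _by, sy = hset.arrays()
    prec = np.abs(bx) / sy  # 1 / first-order ratio se
    score = float(np.sum(prec * (re.ratios - full.theta)) / np.sum(prec))
    return FunnelData(
        ratios=re.ratios, precisions=prec, reference=full.theta, asymmetry_score=score,
    )


def scatter_data(hset: HarmonizedSet, fits: list[MREstimate]) -> ScatterData:
    """Exposure-vs-outcome effect scatter with 95% error bars and fit lines."""
    import pandas as pd

    bx, sx, by, sy = hset.arrays()
    z = 1.959963984540054
    table = pd.DataFrame({
        "snp": [i.key.rsid or f"{i.key.chrom}:{i.key.pos}" for i in hset.instruments],
        "beta_x": bx, "se_x": sx, "beta_y": by, "se_y": sy,
        "xerr": z * sx, "yerr": z * sy,
    })
    lines = []
    for est in fits:
        intercept = float(est.extras.get("egger_intercept", 0.0)) if est.method == "egger" else 0.0
        lines.append((est.method, float(est.theta), intercept))
    return ScatterData(table=table, fits=lines)
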