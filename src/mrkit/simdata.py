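"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the statistical structure a summary-level MR analysis
assumes: two non-overlapping GWAS samples of the same population, per-SNP
marginal effects with standard errors scaling as 1/sqrt(2 n p (1-p)), a true
causal effect ``theta`` of the exposure on a continuous or liability-threshold
binary outcome, and configurable balanced or directional pleiotropy.

Genotypes are drawn from a blockwise AR(1) Gaussian copula thresholded to
haplotypes: within an LD block the latent correlation of adjacent variants is
calibrated (tetrachoric inverse) so that the realized *dosage* correlation
equals ``ld_rho``.  Exposure model::

    x = sum_j gamma_j g_j + e,            Var(x) = 1, sum 2 p q gamma^2 = h2_x
    y = theta * x + sum_j alpha_j g_j + u,  u ~ N(0, 1)

For a binary outcome, y is treated as a liability and cases are the top K
fraction; per-SNP log-odds are computed by the logistic score approximation
(or exact per-SNP logistic fits when ``exact_logistic`` is set).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import optimize, stats
from scipy.special import owens_t

from .sumstats import (
    COMPLEMENT,
    AssociationRecord,
    ReferencePanel,
    SumstatsTable,
    VariantKey,
)

logger = logging.getLogger(__name__)

_NUC = np.array(list("ACGT"))
# fixed substream tags so that panel and GWAS simulation agree on variants
_TAG_VARIANTS, _TAG_PANEL, _TAG_TRUTH, _TAG_EXPOSURE, _TAG_OUTCOME = 1, 2, 3, 4, 5

_MIN_P = 1e-300


class SimConfigError(ValueError):
    pass


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), int(tag))))


@dataclass
class SimConfig:
    """Generating parameters of a synthetic two-sample MR dataset.

    Defaults describe the reference study condition used throughout the
    package's recovery experiments: 50 independent causal variants jointly
    explaining 3% of exposure variance in GWAS samples of 100,000, no
    pleiotropy, continuous outcome with true effect ``theta`` = 0.5.
    """

    m_snps: int = 50
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    n_ref: int = 2_000
    maf_range: tuple[float, float] = (0.10, 0.40)
    ld_rho: float = 0.0
    block_size: int = 10
    n_causal: int = 50
    h2_x: float = 0.03
    theta: float = 0.5
    pleiotropy_mode: str = "none"   # none | balanced | directional
    pleio_fraction: float = 0.0
    pleio_sd: float = 0.0
    outcome_type: str = "continuous"  # continuous | binary
    prevalence: float = 0.0825
    seed: int = 0
    exact_logistic: bool = False
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_causal > self.m_snps:
            raise SimConfigError("n_causal exceeds m_snps")
        if not (0.0 <= self.h2_x < 1.0):
            raise SimConfigError(f"h2_x must be in [0, 1), got {self.h2_x}")
        if not (0.0 <= self.pleio_fraction <= 1.0):
            raise SimConfigError("pleio_fraction must be in [0, 1]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise SimConfigError("ld_rho must be in [0, 1)")
        if self.block_size > self.m_snps:
            raise SimConfigError("block_size exceeds m_snps")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise SimConfigError(f"maf_range must lie within [0.01, 0.5], got {self.maf_range}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise SimConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.outcome_type not in ("continuous", "binary"):
            raise SimConfigError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "binary" and not (0 < self.prevalence < 1):
            raise SimConfigError("binary outcome requires prevalence in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for recovery tests."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    seed: int

    @property
    def causal_idx(self) -> np.ndarray:
        return np.flatnonzero(self.gamma)

    @property
    def pleiotropic_idx(self) -> np.ndarray:
        return np.flatnonzero(self.alpha)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "theta": self.theta,
            "gamma": [float(g) for g in self.gamma],
            "alpha": [float(a) for a in self.alpha],
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


# ---------------------------------------------------------------------------
# Gaussian-copula LD machinery


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Owen's T evaluation; accurate enough (~1e-14) for the tetrachoric solves.
    """
    if abs(rho) < 1e-14:
        return float(stats.norm.cdf(h) * stats.norm.cdf(k))
    rho = float(np.clip(rho, -0.999999, 0.999999))
    # perturb exact zeros off the removable singularity of the T terms
    if h == 0.0:
        h = 1e-13
    if k == 0.0:
        k = 1e-13
    denom = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    beta = 0.0 if h * k > 0 else 0.5
    val = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - owens_t(h, a_h) - owens_t(k, a_k) - beta
    )
    return float(min(max(val, 0.0), 1.0))


def _allele_corr(t1: float, t2: float, p1: float, p2: float, r: float) -> float:
    p11 = bvn_cdf(t1, t2, r)
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def _latent_corr_for(p1: float, p2: float, target: float) -> float:
    """Latent Gaussian correlation giving Bernoulli-allele correlation ``target``."""
    if target <= 0:
        return 0.0
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    hi = 0.999999
    if _allele_corr(t1, t2, p1, p2, hi) < target:
        logger.warning(
            "dosage correlation %.3f unattainable for MAFs (%.3f, %.3f); capping",
            target, p1, p2,
        )
        return hi
    return float(optimize.brentq(
        lambda r: _allele_corr(t1, t2, p1, p2, r) - target, 0.0, hi, xtol=1e-12,
    ))


def _block_starts(m: int, block_size: int) -> np.ndarray:
    return np.arange(0, m, block_size)


def _adjacent_latent(mafs: np.ndarray, block_size: int, ld_rho: float) -> np.ndarray:
    """Per-SNP latent correlation with the previous SNP (0 at block starts)."""
    m = len(mafs)
    a = np.zeros(m)
    if ld_rho <= 0:
        return a
    starts = set(_block_starts(m, block_size).tolist())
    for j in range(1, m):
        if j in starts:
            continue
        a[j] = _latent_corr_for(mafs[j - 1], mafs[j], ld_rho)
    return a


def _draw_dosages(
    rng: np.random.Generator, mafs: np.ndarray, latent_a: np.ndarray, n: int
) -> np.ndarray:
    """Draw an n x m dosage matrix (float32, values 0/1/2)."""
    m = len(mafs)
    if not np.any(latent_a > 0):
        # one uniform per genotype via the Binomial(2, p) inverse CDF
        u = rng.random((n, m), dtype=np.float32)
        p = mafs.astype(np.float32)
        hom = p * p
        return (u < hom).astype(np.float32) + (u < hom + 2 * p * (1 - p))
    thresh = stats.norm.ppf(mafs)
    g = np.zeros((n, m), dtype=np.float32)
    for _hap in range(2):
        z = rng.standard_normal((n, m))
        for j in range(1, m):
            if latent_a[j] > 0:
                z[:, j] = latent_a[j] * z[:, j - 1] + np.sqrt(1 - latent_a[j] ** 2) * z[:, j]
        g += (z < thresh).astype(np.float32)
    return g


# ---------------------------------------------------------------------------
# Variant frame shared by panel and GWAS samples


def _make_variants(config: SimConfig) -> tuple[list[VariantKey], np.ndarray]:
    rng = _rng(config.seed, _TAG_VARIANTS)
    m = config.m_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    # allele pairs uniform over ordered non-identical nucleotide pairs
    ea_idx = rng.integers(0, 4, size=m)
    shift = rng.integers(1, 4, size=m)
    oa_idx = (ea_idx + shift) % 4
    variants = []
    per_chrom_count: dict[int, int] = {}
    for j in range(m):
        block = j // config.block_size
        chrom = (block % 22) + 1
        idx_on_chrom = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = idx_on_chrom + 1
        variants.append(VariantKey(
            chrom=str(chrom),
            pos=1_000_000 + idx_on_chrom * 50_000,
            ea=str(_NUC[ea_idx[j]]),
            oa=str(_NUC[oa_idx[j]]),
            rsid=f"rs{100000 + j}",
        ))
    return variants, mafs


def simulate_reference_panel(config: SimConfig) -> ReferencePanel:
    """Simulate the LD reference panel (deterministic given ``config.seed``)."""
    variants, mafs = _make_variants(config)
    latent_a = _adjacent_latent(mafs, config.block_size, config.ld_rho)
    rng = _rng(config.seed, _TAG_PANEL)
    dosages = _draw_dosages(rng, mafs, latent_a, config.n_ref)
    return ReferencePanel(variants=variants, dosages=np.asarray(dosages, dtype=np.float64))


# ---------------------------------------------------------------------------
# Marginal GWAS on simulated individuals


def _marginal_continuous(g: np.ndarray, y: np.ndarray):
    n = len(y)
    sg = g.sum(0, dtype=np.float64)
    gbar = sg / n
    sgg_c = (g * g).sum(0, dtype=np.float64) - n * gbar**2
    yc = (y - y.mean()).astype(np.float32)
    sgy_c = (g.T @ yc).astype(np.float64)
    syy = float(yc.astype(np.float64) @ yc.astype(np.float64))
    sgg_c = np.maximum(sgg_c, 1e-12)
    beta = sgy_c / sgg_c
    resvar = np.maximum(syy - beta * sgy_c, 0.0) / (n - 2)
    se = np.sqrt(np.maximum(resvar, 1e-30) / sgg_c)
    pval = np.clip(stats.chi2.sf((beta / se) ** 2, df=1), _MIN_P, 1.0)
    eaf = np.clip(gbar / 2, 1 / (4 * n), 1 - 1 / (4 * n))
    return beta, se, pval, eaf


def _marginal_binary_score(g: np.ndarray, y: np.ndarray):
    """Logistic score approximation: linear coefficients rescaled to log-odds."""
    n = len(y)
    ybar = y.mean()
    vbar = ybar * (1 - ybar)
    sg = g.sum(0, dtype=np.float64)
    gbar = sg / n
    sgg_c = np.maximum((g * g).sum(0, dtype=np.float64) - n * gbar**2, 1e-12)
    yc = (y - ybar).astype(np.float32)
    sgy_c = (g.T @ yc).astype(np.float64)
    beta = sgy_c / (vbar * sgg_c)
    se = 1.0 / np.sqrt(vbar * sgg_c)
    pval = np.clip(stats.chi2.sf((beta / se) ** 2, df=1), _MIN_P, 1.0)
    eaf = np.clip(gbar / 2, 1 / (4 * n), 1 - 1 / (4 * n))
    return beta, se, pval, eaf


def _marginal_binary_exact(g: np.ndarray, y: np.ndarray):
    import statsmodels.api as sm

    n, m = g.shape
    beta = np.empty(m)
    se = np.empty(m)
    for j in range(m):
        x = sm.add_constant(np.asarray(g[:, j], dtype=np.float64))
        res = sm.Logit(y, x).fit(disp=0)
        beta[j] = res.params[1]
        se[j] = res.bse[1]
    pval = np.clip(stats.chi2.sf((beta / se) ** 2, df=1), _MIN_P, 1.0)
    eaf = np.clip(g.mean(0, dtype=np.float64) / 2, 1 / (4 * n), 1 - 1 / (4 * n))
    return beta, se, pval, eaf


def _records(variants, beta, se, pval, eaf, n, n_cases=None):
    recs = []
    for j, v in enumerate(variants):
        recs.append(AssociationRecord(
            key=v, beta=float(beta[j]), se=float(se[j]), pval=float(pval[j]),
            n=int(n), eaf=float(eaf[j]), n_cases=n_cases,
        ))
    return recs


def simulate_two_sample_stats(
    config: SimConfig, panel: ReferencePanel | None = None
) -> tuple[SumstatsTable, SumstatsTable, SimTruth]:
    """Simulate exposure and outcome GWAS summary statistics.

    Exposure- and outcome-sample genotypes are drawn independently (no
    sample overlap unless ``overlap_fraction`` > 0) from the same
    variant/MAF/LD frame as :func:`simulate_reference_panel` under the same
    seed; per-SNP statistics are marginal regressions.  Returns the two
    tables and the generating :class:`SimTruth`.
    """
    variants, mafs = _make_variants(config)
    if panel is not None and len(panel.variants) != len(variants):
        raise SimConfigError("panel does not match config variant count")
    latent_a = _adjacent_latent(mafs, config.block_size, config.ld_rho)
    m = config.m_snps

    # --- ground truth ------------------------------------------------------
    rng_t = _rng(config.seed, _TAG_TRUTH)
    gamma = np.zeros(m)
    if config.h2_x > 0 and config.n_causal == 0:
        raise SimConfigError("h2_x > 0 requires n_causal >= 1")
    if config.n_causal > 0 and config.h2_x > 0:
        causal = np.sort(rng_t.choice(m, size=config.n_causal, replace=False))
        two_pq = 2 * mafs[causal] * (1 - mafs[causal])
        # equal variance explained per causal SNP, random sign
        per_snp = config.h2_x / config.n_causal
        signs = rng_t.choice([-1.0, 1.0], size=config.n_causal)
        gamma[causal] = signs * np.sqrt(per_snp / two_pq)
    else:
        causal = np.array([], dtype=int)
    alpha = np.zeros(m)
    if config.pleiotropy_mode != "none" and config.pleio_fraction > 0 and len(causal):
        n_pleio = int(round(config.pleio_fraction * len(causal)))
        pleio = rng_t.choice(causal, size=n_pleio, replace=False)
        draws = rng_t.normal(0.0, config.pleio_sd, size=n_pleio)
        if config.pleiotropy_mode == "directional":
            # direct effects point the same way as the exposure-increasing
            # allele, so the Wald ratios are shifted coherently upward
            draws = np.abs(draws) * np.sign(gamma[pleio])
        alpha[pleio] = draws
    truth = SimTruth(theta=config.theta, gamma=gamma, alpha=alpha, seed=config.seed)

    env_sd = np.sqrt(1.0 - config.h2_x)

    # --- exposure sample ---------------------------------------------------
    rng_e = _rng(config.seed, _TAG_EXPOSURE)
    g_e = _draw_dosages(rng_e, mafs, latent_a, config.n_exposure)
    x_e = g_e @ gamma.astype(np.float32) + rng_e.normal(0, env_sd, config.n_exposure).astype(np.float32)
    beta, se, pval, eaf = _marginal_continuous(g_e, np.asarray(x_e, dtype=np.float64))
    exposure = SumstatsTable(
        _records(variants, beta, se, pval, eaf, config.n_exposure),
        trait_name="exposure", trait_type="continuous",
    )

    # --- outcome sample ----------------------------------------------------
    rng_o = _rng(config.seed, _TAG_OUTCOME)
    g_o = _draw_dosages(rng_o, mafs, latent_a, config.n_outcome)
    n_ov = int(config.overlap_fraction * min(config.n_exposure, config.n_outcome))
    if n_ov > 0:
        g_o[:n_ov] = g_e[:n_ov]
    x_o = g_o @ gamma.astype(np.float32) + rng_o.normal(0, env_sd, config.n_outcome).astype(np.float32)
    if n_ov > 0:
        x_o[:n_ov] = x_e[:n_ov]
    liability = (
        config.theta * np.asarray(x_o, dtype=np.float64)
        + np.asarray(g_o @ alpha.astype(np.float32), dtype=np.float64)
        + rng_o.normal(0, 1.0, config.n_outcome)
    )
    if config.outcome_type == "continuous":
        beta, se, pval, eaf = _marginal_continuous(g_o, liability)
        outcome = SumstatsTable(
            _records(variants, beta, se, pval, eaf, config.n_outcome),
            trait_name="outcome", trait_type="continuous",
        )
    else:
        cut = np.quantile(liability, 1.0 - config.prevalence)
        y = (liability > cut).astype(np.float64)
        n_cases = int(y.sum())
        fit = _marginal_binary_exact if config.exact_logistic else _marginal_binary_score
        beta, se, pval, eaf = fit(g_o, y)
        outcome = SumstatsTable(
            _records(variants, beta, se, pval, eaf, config.n_outcome, n_cases=n_cases),
            trait_name="outcome", trait_type="binary",
        )
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# Harmonization noise


def inject_harmonization_noise(
    table: SumstatsTable, swap_fraction: float, flip_fraction: float, seed: int
) -> SumstatsTable:
    """Return a copy with allele bookkeeping perturbed, statistics intact.

    A *swap* exchanges effect/other alleles and reflects the statistics
    (beta -> -beta, eaf -> 1-eaf); a *flip* strand-complements both alleles
    and leaves the statistics unchanged.  Selection of affected records is
    deterministic given ``seed``; a record may receive both perturbations.
    """
    for frac, name in ((swap_fraction, "swap_fraction"), (flip_fraction, "flip_fraction")):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 6)))
    m = len(table.records)
    swap = rng.random(m) < swap_fraction
    flip = rng.random(m) < flip_fraction
    new_records = []
    for j, rec in enumerate(table.records):
        key, beta, eaf = rec.key, rec.beta, rec.eaf
        if swap[j]:
            key = replace(key, ea=key.oa, oa=key.ea)
            beta = -beta
            eaf = None if eaf is None else 1.0 - eaf
        if flip[j]:
            key = replace(key, ea=COMPLEMENT[key.ea], oa=COMPLEMENT[key.oa])
        new_records.append(replace(rec, key=key, beta=beta, eaf=eaf))
    out = SumstatsTable(new_records, trait_name=table.trait_name, trait_type=table.trait_type)
    return out
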