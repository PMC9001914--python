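"""Analytic power for two-sample MR (the mRnd non-centrality method).

For a binary outcome with case proportion K and an assumed odds ratio OR per
exposure SD, the attenuated regression coefficient of outcome on exposure is

    b = K (OR / (1 + K (OR - 1)) - 1),

its sampling variance given instruments explaining R^2_xz of the exposure is

    v = (K (1 - K) - b^2) / (N R^2_xz),

and power is the upper tail of a 1-df noncentral chi-square with ncp = b^2/v
beyond the central 1-alpha quantile.  For a continuous (unit-variance) outcome
ncp = N R^2_xz beta_yx^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats


class PowerSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the mRnd power formula.

    ``odds_ratio`` is per 1 SD of the exposure, matching the package's (and
    the field's) OR reporting scale.
    """

    n: int
    r2xz: float
    alpha: float = 0.05
    outcome: str = "binary"
    k_prev: float | None = None
    odds_ratio: float | None = None
    beta_yx: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise PowerSpecError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0 < self.r2xz < 1):
            raise PowerSpecError(f"r2xz must be in (0, 1), got {self.r2xz}")
        if self.n < 1:
            raise PowerSpecError("n must be positive")
        if self.outcome == "binary":
            if self.k_prev is None or not (0 < self.k_prev < 1):
                raise PowerSpecError("binary outcome requires k_prev in (0, 1)")
            if self.odds_ratio is None or self.odds_ratio <= 0:
                raise PowerSpecError("binary outcome requires odds_ratio > 0")
        elif self.outcome == "continuous":
            if self.beta_yx is None:
                raise PowerSpecError("continuous outcome requires beta_yx")
        else:
            raise PowerSpecError(f"unknown outcome {self.outcome!r}")


def _chi2_power(ncp: float, alpha: float) -> float:
    crit = stats.chi2.ppf(1 - alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else float(alpha)


def mr_power_binary(spec: PowerSpec) -> float:
    """Power to detect the assumed OR with a binary outcome."""
    if spec.outcome != "binary":
        raise PowerSpecError("spec is not a binary-outcome spec")
    k, orr = spec.k_prev, spec.odds_ratio
    b = k * (orr / (1 + k * (orr - 1)) - 1)
    varb = k * (1 - k) - b * b
    if varb <= 0:
        raise PowerSpecError("degenerate variance: K(1-K) <= b^2")
    v = varb / (spec.n * spec.r2xz)
    return _chi2_power(b * b / v, spec.alpha)


def mr_power_continuous(spec: PowerSpec) -> float:
    """Power to detect beta_yx (per exposure SD, unit-variance outcome)."""
    if spec.outcome != "continuous":
        raise PowerSpecError("spec is not a continuous-outcome spec")
    ncp = spec.n * spec.r2xz * spec.beta_yx**2
    return _chi2_power(ncp, spec.alpha)


def power_curve(
    spec: PowerSpec, n_grid: list[int], or_grid: list[float]
) -> pd.DataFrame:
    """Binary-outcome power over the cross-product of sample sizes and ORs."""
    if not n_grid or not or_grid:
        raise PowerSpecError("grids must be non-empty")
    rows = []
    for n, orr in product(n_grid, or_grid):
        p = mr_power_binary(PowerSpec(
            n=int(n), r2xz=spec.r2xz, alpha=spec.alpha, outcome="binary",
            k_prev=spec.k_prev, odds_ratio=float(orr),
        ))
        rows.append({"n": int(n), "odds_ratio": float(orr), "power": p,
                     "power_pct": round(100 * p)})
    return pd.DataFrame(rows)


def case_proportion(n_cases: int, n_total: int) -> float:
    """Case fraction K of a case/control GWAS (e.g. 74124/898130 = 0.0825)."""
    if not (0 < n_cases <= n_total):
        raise PowerSpecError("need 0 < n_cases <= n_total")
    return n_cases / n_total
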