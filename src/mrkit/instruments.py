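"""Instrument selection and strength diagnostics.

Selection follows the standard two-stage recipe: keep genome-wide significant
variants (p < 5e-8, strict), then greedily prune by linkage disequilibrium
(r^2 < 0.01 within a 10,000 kb window) against a reference panel so that the
retained index SNPs are approximately independent.  Strength is summarized by
per-SNP F = (beta/se)^2, the variance explained (PVE), and the overall
Cragg-Donald F statistic R^2 (n-k-1) / (k (1-R^2)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sumstats import AssociationRecord, ReferencePanel, SumstatsTable

logger = logging.getLogger(__name__)


class ClumpError(ValueError):
    pass


class StrengthError(ValueError):
    pass


@dataclass(frozen=True)
class ClumpParams:
    """LD-clumping thresholds; defaults are the conventional GWAS values."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.window_kb <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")


@dataclass
class StrengthReport:
    per_snp_f: list[float]
    overall_f: float
    pve: float
    k: int
    n: int
    r2_method: str = "eaf"  # eaf | tstat
    weak: list[str] = field(default_factory=list)  # rsids with F < 10

    def __post_init__(self) -> None:
        if len(self.per_snp_f) != self.k:
            raise ValueError("per_snp_f length must equal k")


def filter_genomewide(table: SumstatsTable, p_threshold: float = 5e-8) -> SumstatsTable:
    """Keep records with p strictly below the genome-wide threshold."""
    return table.subset(r for r in table.records if r.pval < p_threshold)


def ld_clump(
    table: SumstatsTable, panel: ReferencePanel, params: ClumpParams = ClumpParams()
) -> SumstatsTable:
    """Greedy LD clumping against the reference panel.

    Repeatedly takes the remaining record with the smallest p-value (ties
    broken by genomic order) as an index SNP and removes remaining records on
    the same chromosome within ``window_kb`` whose panel r^2 with the index
    is at or above ``r2_threshold``.  Variants absent from the panel are
    dropped with a logged warning rather than assumed independent.
    """
    if panel.dosages.size == 0 or len(panel.variants) == 0:
        raise ClumpError("empty reference panel")

    candidates = []
    for rec in table.records:
        col = panel.column(rec.key.chrom, rec.key.pos)
        if col is None:
            logger.warning(
                "variant %s (%s:%d) absent from panel; dropped from clumping",
                rec.key.rsid, rec.key.chrom, rec.key.pos,
            )
            continue
        candidates.append((rec, col))

    # centered, unit-norm dosage columns for fast pairwise r^2
    cols = {col for _, col in candidates}
    normed: dict[int, np.ndarray] = {}
    for col in cols:
        v = panel.dosages[:, col] - panel.dosages[:, col].mean()
        norm = np.linalg.norm(v)
        normed[col] = v / norm if norm > 0 else v

    window_bp = params.window_kb * 1000.0
    remaining = sorted(
        candidates, key=lambda rc: (rc[0].pval, rc[0].key.sort_key())
    )
    index_snps: list[AssociationRecord] = []
    while remaining:
        index_rec, index_col = remaining.pop(0)
        index_snps.append(index_rec)
        survivors = []
        for rec, col in remaining:
            if rec.key.chrom == index_rec.key.chrom and abs(rec.key.pos - index_rec.key.pos) <= window_bp:
                r = float(normed[index_col] @ normed[col])
                if r * r >= params.r2_threshold:
                    continue
            survivors.append((rec, col))
        remaining = survivors
    return table.subset(index_snps)


def per_snp_f(record: AssociationRecord) -> float:
    """Single-instrument F statistic, (beta/se)^2."""
    return (record.beta / record.se) ** 2


def strength_report(instruments: SumstatsTable, n: int) -> StrengthReport:
    """Instrument-strength diagnostics for a set of independent instruments.

    Per-SNP variance explained uses 2 p (1-p) beta^2 when every record has an
    effect-allele frequency (assuming per-SD effect sizes, i.e. unit trait
    variance), else the t-statistic form t^2 / (t^2 + n - 2).  The overall F
    is the Cragg-Donald statistic.
    """
    k = len(instruments)
    if k < 1:
        raise StrengthError("need at least one instrument")
    if n <= k + 1:
        raise StrengthError(f"exposure sample size {n} too small for k={k}")
    fs = [per_snp_f(r) for r in instruments.records]
    if all(r.eaf is not None for r in instruments.records):
        r2 = [2 * r.eaf * (1 - r.eaf) * r.beta**2 for r in instruments.records]
        method = "eaf"
    else:
        r2 = [f / (f + n - 2) for f in fs]
        method = "tstat"
    pve = float(min(sum(r2), 1.0 - 1e-12))
    overall = pve * (n - k - 1) / (k * (1 - pve))
    weak = [r.key.rsid or f"{r.key.chrom}:{r.key.pos}"
            for r, f in zip(instruments.records, fs) if f < 10]
    return StrengthReport(
        per_snp_f=fs, overall_f=float(overall), pve=pve, k=k, n=int(n),
        r2_method=method, weak=weak,
    )
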