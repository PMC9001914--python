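"""End-to-end orchestration: select -> harmonize -> estimate -> diagnose.

``run_mr`` reproduces the standard two-sample MR workflow on summary files:
genome-wide filtering, LD clumping against a reference panel, harmonization,
instrument-strength diagnostics, the requested estimators, leave-one-out and
MR-PRESSO, and plot-ready tables.  ``direction="reverse"`` swaps the roles of
the two traits and re-selects instruments from the outcome GWAS;
``direction="both"`` runs forward then reverse.  All randomness derives from
``config.seed``; identical configs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .estimators import (
    METHODS,
    MREstimate,
    OddsRatioEstimate,
    egger_estimate,
    ivw_estimate,
    mode_based_estimate,
    raps_estimate,
    robust_ivw_estimate,
    to_odds_ratio,
    weighted_median_estimate,
)
from .harmonize import HarmonizedSet, harmonize_tables
from .instruments import ClumpParams, StrengthReport, filter_genomewide, ld_clump, strength_report
from .sensitivity import (
    FunnelData,
    LooResult,
    PressoResult,
    ScatterData,
    funnel_data,
    leave_one_out,
    mr_presso,
    scatter_data,
)
from .sumstats import ReferencePanel, SumstatsTable, read_sumstats

logger = logging.getLogger(__name__)


class EmptyInstrumentError(RuntimeError):
    def __init__(self, stage: str):
        super().__init__(f"no instruments remain after stage {stage!r}")
        self.stage = stage


@dataclass
class RunConfig:
    exposure_path: str
    outcome_path: str
    panel_prefix: str
    clump: ClumpParams = field(default_factory=ClumpParams)
    palindrome_maf_limit: float = 0.42
    methods: tuple[str, ...] = METHODS
    presso_n_sim: int = 1000
    presso_sig: float = 0.05
    n_boot: int = 1000
    ivw_model: str = "multiplicative_random"
    seed: int = 0
    direction: str = "forward"  # forward | reverse | both
    report_dir: str | None = None
    exposure_trait_type: str = "continuous"
    outcome_trait_type: str = "continuous"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unsupported methods: {sorted(unknown)}")
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        clump = ClumpParams(**raw.pop("clump", {}))
        methods = tuple(raw.pop("methods", METHODS))
        return cls(clump=clump, methods=methods, **raw)

    def canonical_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d.pop("report_dir", None)  # output location is not analysis config
        return d


@dataclass
class DirectionResult:
    direction: str
    stage_counts: dict
    strength: StrengthReport
    estimates: list[MREstimate]
    odds_ratios: list[OddsRatioEstimate]
    loo: LooResult | None
    presso: PressoResult | None
    funnel: FunnelData
    scatter: ScatterData
    drop_log: list[tuple]
    hset: HarmonizedSet


@dataclass
class RunReport:
    config: dict
    provenance: dict
    directions: dict[str, DirectionResult]


def _derived_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence(entropy=(int(seed), int(tag))).generate_state(1)[0] % 2**31)


def _dispatch(method: str, hset: HarmonizedSet, config: RunConfig) -> MREstimate:
    if method == "ivw":
        return ivw_estimate(hset, model=config.ivw_model)
    if method == "egger":
        return egger_estimate(hset)
    if method == "wmedian":
        return weighted_median_estimate(hset, n_boot=config.n_boot,
                                        seed=_derived_seed(config.seed, 11))
    if method == "mbe":
        return mode_based_estimate(hset, n_boot=config.n_boot,
                                   seed=_derived_seed(config.seed, 12))
    if method == "robust":
        return robust_ivw_estimate(hset)
    if method == "raps":
        return raps_estimate(hset)
    raise ValueError(f"unknown method {method!r}")


def run_direction(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    panel: ReferencePanel,
    config: RunConfig,
    direction: str = "forward",
) -> DirectionResult:
    """Run the full analysis with ``exposure`` as the instrumented trait."""
    counts = {"candidates": len(exposure)}
    filtered = filter_genomewide(exposure, config.clump.p_threshold)
    counts["post_filter"] = len(filtered)
    if len(filtered) == 0:
        raise EmptyInstrumentError("filter_genomewide")
    clumped = ld_clump(filtered, panel, config.clump)
    counts["post_clump"] = len(clumped)
    if len(clumped) == 0:
        raise EmptyInstrumentError("ld_clump")
    hset = harmonize_tables(clumped, outcome, config.palindrome_maf_limit)
    counts["harmonized"] = hset.n_iv
    counts["dropped"] = len(hset.dropped)
    if hset.n_iv == 0:
        raise EmptyInstrumentError("harmonize")

    retained = {i.key.position_id() for i in hset.instruments}
    retained_table = clumped.subset(
        r for r in clumped.records if r.key.position_id() in retained
    )
    strength = strength_report(retained_table, n=hset.n_exposure or 2)

    estimates = [_dispatch(m, hset, config) for m in config.methods]
    odds_ratios = (
        [to_odds_ratio(e) for e in estimates] if hset.outcome_type == "binary" else []
    )
    loo = leave_one_out(hset, model=config.ivw_model) if hset.n_iv >= 3 else None
    presso = None
    if hset.n_iv >= 4:
        presso = mr_presso(hset, n_sim=config.presso_n_sim,
                           seed=_derived_seed(config.seed, 13), sig=config.presso_sig)
    else:
        logger.warning("%s: MR-PRESSO skipped, only %d instruments", direction, hset.n_iv)
    full_ivw = next((e for e in estimates if e.method == "ivw"), None)
    full_ivw = full_ivw or ivw_estimate(hset, model=config.ivw_model)
    funnel = funnel_data(hset, full_ivw)
    scatter = scatter_data(hset, estimates)
    return DirectionResult(
        direction=direction, stage_counts=counts, strength=strength,
        estimates=estimates, odds_ratios=odds_ratios, loo=loo, presso=presso,
        funnel=funnel, scatter=scatter, drop_log=list(hset.dropped), hset=hset,
    )


def run_mr(config: RunConfig) -> RunReport:
    """Execute the configured analysis and return the structured report."""
    exposure = read_sumstats(config.exposure_path, trait_type=config.exposure_trait_type)
    outcome = read_sumstats(config.outcome_path, trait_type=config.outcome_trait_type)
    panel = ReferencePanel.load(config.panel_prefix)

    directions: dict[str, DirectionResult] = {}
    if config.direction in ("forward", "both"):
        directions["forward"] = run_direction(exposure, outcome, panel, config, "forward")
    if config.direction in ("reverse", "both"):
        directions["reverse"] = run_direction(outcome, exposure, panel, config, "reverse")

    cfg = config.canonical_dict()
    cfg["clump"] = asdict(config.clump)
    blob = json.dumps(cfg, sort_keys=True).encode()
    provenance = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "mrkit_version": __version__,
    }
    report = RunReport(config=cfg, provenance=provenance, directions=directions)
    if config.report_dir:
        render_report(report, config.report_dir)
    return report


# ---------------------------------------------------------------------------
# Serialization


def _est_dict(e: MREstimate) -> dict:
    return {
        "method": e.method, "theta": e.theta, "se": e.se, "ci_low": e.ci_low,
        "ci_high": e.ci_high, "pval": e.pval, "n_iv": e.n_iv, "scale": e.scale,
        "extras": {k: v for k, v in e.extras.items()},
    }


def _key_str(key) -> str:
    return key.rsid or f"{key.chrom}:{key.pos}"


def report_to_dict(report: RunReport) -> dict:
    out = {"config": report.config, "provenance": report.provenance, "directions": {}}
    for name, d in report.directions.items():
        presso = None
        if d.presso is not None:
            presso = {
                "global_rss": d.presso.global_rss,
                "global_p": d.presso.global_p,
                "outlier_pvals": d.presso.outlier_pvals,
                "outliers": [_key_str(k) for k in d.presso.outliers],
                "corrected": _est_dict(d.presso.corrected) if d.presso.corrected else None,
                "distortion_p": d.presso.distortion_p,
                "n_sim": d.presso.n_sim,
                "seed": d.presso.seed,
            }
        out["directions"][name] = {
            "stage_counts": d.stage_counts,
            "strength": {
                "per_snp_f": d.strength.per_snp_f,
                "overall_f": d.strength.overall_f,
                "pve": d.strength.pve,
                "k": d.strength.k,
                "n": d.strength.n,
                "r2_method": d.strength.r2_method,
                "weak": d.strength.weak,
            },
            "estimates": [_est_dict(e) for e in d.estimates],
            "odds_ratios": [
                {"method": o.method, "odds_ratio": o.odds_ratio, "ci_low": o.ci_low,
                 "ci_high": o.ci_high, "pval": o.pval, "n_iv": o.n_iv}
                for o in d.odds_ratios
            ],
            "loo": None if d.loo is None else {
                "full": _est_dict(d.loo.full),
                "estimates": [_est_dict(e) for e in d.loo.estimates],
            },
            "presso": presso,
            "funnel_asymmetry_score": d.funnel.asymmetry_score,
            "drop_log": [[_key_str(k), reason] for k, reason in d.drop_log],
        }
    return out


def _tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                repr(v) if isinstance(v, float) else ("NA" if v is None else str(v))
                for v in row
            ) + "\n")


def render_report(report: RunReport, report_dir: str | Path, plots: bool = False) -> list[Path]:
    """Write report.json plus per-direction forest/scatter/funnel/LOO TSVs.

    File contents are a pure function of the report; regeneration is
    byte-identical.  With ``plots=True`` PNG scatter/funnel/forest figures are
    also written (requires matplotlib).
    """
    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    jpath = report_dir / "report.json"
    jpath.write_text(json.dumps(report_to_dict(report), sort_keys=True, indent=2) + "\n")
    written.append(jpath)

    for name, d in report.directions.items():
        ors = {o.method: o for o in d.odds_ratios}
        rows = []
        for e in d.estimates:
            o = ors.get(e.method)
            rows.append([
                e.method, e.theta, e.se, e.ci_low, e.ci_high, e.pval, e.n_iv,
                o.odds_ratio if o else None, o.ci_low if o else None,
                o.ci_high if o else None,
            ])
        p = report_dir / f"{name}_forest.tsv"
        _tsv(p, ["method", "theta", "se", "ci_low", "ci_high", "pval", "n_iv",
                 "or", "or_ci_low", "or_ci_high"], rows)
        written.append(p)

        p = report_dir / f"{name}_scatter.tsv"
        sc = d.scatter
        rows = sc.table.values.tolist()
        _tsv(p, list(sc.table.columns), rows)
        written.append(p)
        p = report_dir / f"{name}_fits.tsv"
        _tsv(p, ["method", "slope", "intercept"], [list(f) for f in sc.fits])
        written.append(p)

        p = report_dir / f"{name}_funnel.tsv"
        _tsv(p, ["ratio", "precision"],
             [[float(r), float(q)] for r, q in zip(d.funnel.ratios, d.funnel.precisions)])
        written.append(p)

        if d.loo is not None:
            p = report_dir / f"{name}_loo.tsv"
            _tsv(p, ["left_out", "theta", "se", "ci_low", "ci_high", "pval"],
                 [[e.extras.get("left_out"), e.theta, e.se, e.ci_low, e.ci_high, e.pval]
                  for e in d.loo.estimates])
            written.append(p)

        p = report_dir / f"{name}_drops.tsv"
        _tsv(p, ["snp", "reason"], [[_key_str(k), r] for k, r in d.drop_log])
        written.append(p)

        if plots:
            written.extend(_render_plots(d, report_dir, name))
    return written


def _render_plots(d: DirectionResult, report_dir: Path, name: str) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    sc = d.scatter
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(sc.table["beta_x"], sc.table["beta_y"], xerr=sc.table["xerr"],
                yerr=sc.table["yerr"], fmt="o", ms=3, lw=0.8, alpha=0.7)
    xs = np.linspace(0, sc.table["beta_x"].max() * 1.05, 50)
    for method, slope, intercept in sc.fits:
        ax.plot(xs, intercept + slope * xs, label=method, lw=1)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=7)
    p = report_dir / f"{name}_scatter.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(d.funnel.ratios, d.funnel.precisions, s=12)
    ax.axvline(d.funnel.reference, color="k", lw=1)
    ax.set_xlabel("Wald ratio estimate")
    ax.set_ylabel("precision (1/se)")
    p = report_dir / f"{name}_funnel.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written
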