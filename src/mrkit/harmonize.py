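"""Align exposure and outcome summary statistics on a shared effect allele.

Exposure and outcome GWAS report each variant relative to an arbitrary effect
allele and strand.  Harmonization matches variants by chromosome and position
and transforms the *outcome* statistics onto the exposure's effect-allele
frame: label swaps negate the outcome beta and reflect its frequency, strand
complements relabel alleles without touching statistics, and palindromic
variants (A/T, C/G) — where strand is unknowable from alleles alone — are
aligned by allele-frequency agreement when both frequencies are available and
informative, otherwise dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import COMPLEMENT, MISSING, SumstatsTable, VariantKey


@dataclass
class HarmonizedInstrument:
    """Per-instrument quadruple used by every MR estimator.

    ``beta_x``/``se_x`` are the exposure association, ``beta_y``/``se_y`` the
    outcome association, both for one copy of the exposure effect allele.
    """

    key: VariantKey
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float | None = None
    eaf_y: float | None = None
    status: str = "direct"  # direct | swapped | strand_flipped | palindromic_inferred

    def __post_init__(self) -> None:
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError("standard errors must be positive")


@dataclass
class HarmonizedSet:
    instruments: list[HarmonizedInstrument]
    dropped: list[tuple[VariantKey, str]] = field(default_factory=list)
    exposure_trait: str = "exposure"
    outcome_trait: str = "outcome"
    outcome_type: str = "continuous"
    n_exposure: int | None = None
    n_outcome: int | None = None

    @property
    def n_iv(self) -> int:
        return len(self.instruments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_x, se_x, beta_y, se_y) as float arrays."""
        bx = np.array([i.beta_x for i in self.instruments])
        sx = np.array([i.se_x for i in self.instruments])
        by = np.array([i.beta_y for i in self.instruments])
        sy = np.array([i.se_y for i in self.instruments])
        return bx, sx, by, sy

    def subset(self, keep_idx) -> "HarmonizedSet":
        keep_idx = list(keep_idx)
        return HarmonizedSet(
            instruments=[self.instruments[i] for i in keep_idx],
            dropped=list(self.dropped),
            exposure_trait=self.exposure_trait,
            outcome_trait=self.outcome_trait,
            outcome_type=self.outcome_type,
            n_exposure=self.n_exposure,
            n_outcome=self.n_outcome,
        )


def _median_n(table: SumstatsTable) -> int | None:
    if not table.records:
        return None
    return int(np.median([r.n for r in table.records]))


def harmonize_tables(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    palindrome_maf_limit: float = 0.42,
    palindrome_policy: str = "infer",
) -> HarmonizedSet:
    """Harmonize selected exposure instruments with the outcome GWAS.

    Parameters
    ----------
    exposure
        The selected instrument set (post filtering/clumping).
    outcome
        Full outcome summary statistics; matched by (chromosome, position).
    palindrome_maf_limit
        A palindromic variant is only frequency-aligned when both minor
        allele frequencies fall strictly below this limit; near 0.5 the
        orientation is statistically unidentifiable.
    palindrome_policy
        ``infer`` (default) aligns by frequency agreement, ``drop`` discards
        every palindromic variant, ``keep`` trusts allele labels as-is
        (mimics a naive merge; for sensitivity checks only).

    Every candidate lands either in ``instruments`` or in ``dropped`` with a
    reason (``absent_in_outcome``, ``allele_mismatch``,
    ``palindromic_ambiguous``, ``palindromic``).
    """
    if palindrome_policy not in ("infer", "drop", "keep"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    out_by_pos = outcome.by_position()
    instruments: list[HarmonizedInstrument] = []
    dropped: list[tuple[VariantKey, str]] = []

    for rec in exposure.records:
        xkey = rec.key
        orec = out_by_pos.get(xkey.position_id())
        if orec is None:
            dropped.append((xkey, "absent_in_outcome"))
            continue
        e1, o1 = xkey.ea, xkey.oa
        e2, o2 = orec.key.ea, orec.key.oa
        beta_y, eaf_y = orec.beta, orec.eaf

        if xkey.is_palindromic:
            if {e2, o2} != {e1, o1}:
                dropped.append((xkey, "allele_mismatch"))
                continue
            # label alignment first (swap indistinguishable from strand flip)
            if e2 == e1:
                by0, fy0 = beta_y, eaf_y
            else:
                by0 = -beta_y
                fy0 = None if eaf_y is None else 1.0 - eaf_y
            if palindrome_policy == "drop":
                dropped.append((xkey, "palindromic"))
                continue
            if palindrome_policy == "keep":
                instruments.append(HarmonizedInstrument(
                    key=xkey, beta_x=rec.beta, se_x=rec.se, beta_y=by0,
                    se_y=orec.se, eaf_x=rec.eaf, eaf_y=fy0, status="palindromic_inferred",
                ))
                continue
            if rec.eaf is None or fy0 is None:
                dropped.append((xkey, "palindromic_ambiguous"))
                continue
            maf_x = min(rec.eaf, 1 - rec.eaf)
            maf_y = min(fy0, 1 - fy0)
            if maf_x >= palindrome_maf_limit or maf_y >= palindrome_maf_limit:
                dropped.append((xkey, "palindromic_ambiguous"))
                continue
            if (rec.eaf - 0.5) * (fy0 - 0.5) < 0:
                # frequencies disagree: outcome is on the opposite strand frame
                by0 = -by0
                fy0 = 1.0 - fy0
            instruments.append(HarmonizedInstrument(
                key=xkey, beta_x=rec.beta, se_x=rec.se, beta_y=by0,
                se_y=orec.se, eaf_x=rec.eaf, eaf_y=fy0, status="palindromic_inferred",
            ))
            continue

        ce2, co2 = COMPLEMENT[e2], COMPLEMENT[o2]
        if (e2, o2) == (e1, o1):
            status, sign, flip_f = "direct", 1.0, False
        elif (e2, o2) == (o1, e1):
            status, sign, flip_f = "swapped", -1.0, True
        elif (ce2, co2) == (e1, o1):
            status, sign, flip_f = "strand_flipped", 1.0, False
        elif (ce2, co2) == (o1, e1):
            status, sign, flip_f = "strand_flipped", -1.0, True
        else:
            dropped.append((xkey, "allele_mismatch"))
            continue
        eaf_out = None
        if eaf_y is not None:
            eaf_out = 1.0 - eaf_y if flip_f else eaf_y
        instruments.append(HarmonizedInstrument(
            key=xkey, beta_x=rec.beta, se_x=rec.se, beta_y=sign * beta_y,
            se_y=orec.se, eaf_x=rec.eaf, eaf_y=eaf_out, status=status,
        ))

    return HarmonizedSet(
        instruments=instruments,
        dropped=dropped,
        exposure_trait=exposure.trait_name,
        outcome_trait=outcome.trait_name,
        outcome_type=outcome.trait_type,
        n_exposure=_median_n(exposure),
        n_outcome=_median_n(outcome),
    )


# ---------------------------------------------------------------------------
# TSV round-trip used by the CLI stages

_HARM_COLUMNS = (
    "snp", "chr", "pos", "ea", "oa", "beta_x", "se_x", "beta_y", "se_y",
    "eaf_x", "eaf_y", "status",
)


def _cell(v) -> str:
    if v is None:
        return MISSING
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_harmonized(hset: HarmonizedSet, path) -> Path:
    """Write instruments as TSV plus a sibling ``<stem>.drops.tsv`` audit log."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_HARM_COLUMNS) + "\n")
        fh.write(f"# exposure={hset.exposure_trait}\toutcome={hset.outcome_trait}"
                 f"\toutcome_type={hset.outcome_type}"
                 f"\tn_exposure={hset.n_exposure}\tn_outcome={hset.n_outcome}\n")
        for i in hset.instruments:
            fh.write("\t".join([
                _cell(i.key.rsid), str(i.key.chrom), str(i.key.pos), i.key.ea,
                i.key.oa, repr(i.beta_x), repr(i.se_x), repr(i.beta_y),
                repr(i.se_y), _cell(i.eaf_x), _cell(i.eaf_y), i.status,
            ]) + "\n")
    drop_path = path.with_suffix(".drops.tsv")
    with open(drop_path, "w") as fh:
        fh.write("snp\tchr\tpos\tea\toa\treason\n")
        for key, reason in hset.dropped:
            fh.write(f"{_cell(key.rsid)}\t{key.chrom}\t{key.pos}\t{key.ea}\t{key.oa}\t{reason}\n")
    return path


def read_harmonized(path) -> HarmonizedSet:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        meta_line = fh.readline().rstrip("\n")
        body = fh.read()
    meta = {}
    for part in meta_line.lstrip("# ").split("\t"):
        k, _, v = part.partition("=")
        meta[k] = v
    from io import StringIO

    df = pd.read_csv(StringIO("\t".join(header) + "\n" + body), sep="\t",
                     dtype=str, keep_default_na=False)
    instruments = []
    for row in df.to_dict(orient="records"):
        instruments.append(HarmonizedInstrument(
            key=VariantKey(chrom=row["chr"], pos=int(row["pos"]), ea=row["ea"],
                           oa=row["oa"],
                           rsid=None if row["snp"] == MISSING else row["snp"]),
            beta_x=float(row["beta_x"]), se_x=float(row["se_x"]),
            beta_y=float(row["beta_y"]), se_y=float(row["se_y"]),
            eaf_x=None if row["eaf_x"] == MISSING else float(row["eaf_x"]),
            eaf_y=None if row["eaf_y"] == MISSING else float(row["eaf_y"]),
            status=row["status"],
        ))

    def _int_or_none(v):
        return None if v in ("None", "", MISSING) else int(v)

    return HarmonizedSet(
        instruments=instruments,
        exposure_trait=meta.get("exposure", "exposure"),
        outcome_trait=meta.get("outcome", "outcome"),
        outcome_type=meta.get("outcome_type", "continuous"),
        n_exposure=_int_or_none(meta.get("n_exposure", "None")),
        n_outcome=_int_or_none(meta.get("n_outcome", "None")),
    )
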