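"""Data model and file I/O for GWAS summary statistics and reference panels.

The on-disk dialect is plain tab-delimited text with canonical columns
``snp chr pos ea oa eaf beta se pval n n_cases`` and ``NA`` as the missing
token.  Effect sizes are per standard deviation of the trait for continuous
traits and log-odds for binary traits; odds ratios are produced only at
reporting time.  Positions are 1-based and variants are matched by exact
chromosome and position (no liftover, no rsid merging).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
MISSING = "NA"

#: canonical column order of the tab-delimited dialect
CANONICAL_COLUMNS = (
    "snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n", "n_cases",
)
MANDATORY_COLUMNS = ("chr", "pos", "ea", "oa", "beta", "se", "pval", "n")


class SumstatsFormatError(ValueError):
    """File-level problem: missing mandatory column, or no valid rows."""


class DuplicateVariantError(ValueError):
    """Two records share (chromosome, position, unordered allele pair)."""


def _chrom_rank(chrom: str) -> tuple[int, str]:
    c = str(chrom).upper()
    if c.startswith("CHR"):
        c = c[3:]
    if c.isdigit():
        return (int(c), c)
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    return (special.get(c, 99), c)


@dataclass(frozen=True)
class VariantKey:
    """A variant identified by position and allele pair.

    ``ea`` is the effect allele whose dosage the ``beta`` of an
    :class:`AssociationRecord` counts; ``oa`` is the other allele.
    """

    chrom: str
    pos: int
    ea: str
    oa: str
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ea, self.oa):
            if allele not in NUCLEOTIDES:
                raise ValueError(f"allele must be one of A/C/G/T, got {allele!r}")
        if self.ea == self.oa:
            raise ValueError(f"effect and other allele identical ({self.ea})")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return COMPLEMENT[self.ea] == self.oa

    def sort_key(self) -> tuple:
        return (*_chrom_rank(self.chrom), self.pos)

    def position_id(self) -> tuple[str, int]:
        return (str(self.chrom), self.pos)

    def unordered(self) -> tuple[str, int, frozenset]:
        return (str(self.chrom), self.pos, frozenset((self.ea, self.oa)))


@dataclass
class AssociationRecord:
    """One SNP's marginal association with a trait.

    ``beta`` and ``se`` are the estimated effect of one effect-allele copy
    and its standard error; for a binary trait ``beta`` is a log odds ratio.
    """

    key: VariantKey
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None
    n_cases: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError(f"beta must be finite, got {self.beta}")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"pval must be in (0, 1], got {self.pval}")
        if self.n < 2:
            raise ValueError(f"sample size must be >= 2, got {self.n}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"eaf must be in (0, 1), got {self.eaf}")
        if self.n_cases is not None and self.n_cases > self.n:
            raise ValueError(f"n_cases {self.n_cases} exceeds n {self.n}")


@dataclass
class SumstatsTable:
    """An ordered collection of association records for one trait.

    Records are kept sorted by (chromosome, position); constructing a table
    with two records at the same position and unordered allele pair raises
    :class:`DuplicateVariantError`.
    """

    records: list[AssociationRecord]
    trait_name: str = "trait"
    trait_type: str = "continuous"
    audit: list[tuple[int, str]] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type}")
        self.records = sorted(self.records, key=lambda r: r.key.sort_key())
        seen: dict = {}
        for rec in self.records:
            u = rec.key.unordered()
            if u in seen:
                raise DuplicateVariantError(
                    f"duplicate variant at {rec.key.chrom}:{rec.key.pos} "
                    f"(alleles {rec.key.ea}/{rec.key.oa})"
                )
            seen[u] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self.records)

    def by_position(self) -> dict[tuple[str, int], AssociationRecord]:
        return {r.key.position_id(): r for r in self.records}

    def subset(self, keep: Iterable[AssociationRecord]) -> "SumstatsTable":
        return SumstatsTable(list(keep), self.trait_name, self.trait_type)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "snp": r.key.rsid, "chr": str(r.key.chrom), "pos": r.key.pos,
                "ea": r.key.ea, "oa": r.key.oa, "eaf": r.eaf, "beta": r.beta,
                "se": r.se, "pval": r.pval, "n": r.n, "n_cases": r.n_cases,
            })
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _parse_row(row: Mapping[str, str]) -> AssociationRecord:
    def get(col: str) -> str | None:
        v = row.get(col)
        if v is None or v == "" or v == MISSING:
            return None
        return v

    key = VariantKey(
        chrom=str(get("chr")),
        pos=int(get("pos")),
        ea=str(get("ea")).upper(),
        oa=str(get("oa")).upper(),
        rsid=get("snp"),
    )
    eaf = get("eaf")
    n_cases = get("n_cases")
    return AssociationRecord(
        key=key,
        beta=float(get("beta")),
        se=float(get("se")),
        pval=float(get("pval")),
        n=int(float(get("n"))),
        eaf=None if eaf is None else float(eaf),
        n_cases=None if n_cases is None else int(float(n_cases)),
    )


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
) -> SumstatsTable:
    """Load a tab-delimited summary-statistics file.

    Parameters
    ----------
    path
        Tab-delimited text file with a header line.
    column_map
        Optional mapping from canonical column names (``chr``, ``pos`` ...)
        to the names actually used in the file header.
    trait_name, trait_type
        Metadata attached to the returned table.

    Rows violating record invariants (``se <= 0``, ``pval`` out of range,
    bad alleles ...) are rejected individually; each rejection is logged and
    recorded in the returned table's ``audit`` list as ``(row_index,
    reason)``.  A missing mandatory column, or a file in which every row
    fails, raises :class:`SumstatsFormatError`.  Duplicated variants raise
    :class:`DuplicateVariantError` naming the position.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rename = {}
    if column_map:
        rename = {actual: canon for canon, actual in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing mandatory column(s) {missing}; header is {list(df.columns)}"
        )

    records: list[AssociationRecord] = []
    audit: list[tuple[int, str]] = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        try:
            records.append(_parse_row(row))
        except (ValueError, TypeError) as exc:
            audit.append((idx, str(exc)))
            logger.warning("%s: row %d rejected: %s", path, idx, exc)
    if len(df) > 0 and not records:
        raise SumstatsFormatError(f"{path}: all {len(df)} rows failed validation")

    table = SumstatsTable(
        records,
        trait_name=trait_name if trait_name is not None else path.stem,
        trait_type=trait_type,
    )
    table.audit = audit
    return table


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return repr(float(value))


def write_sumstats(table: SumstatsTable, path: str | Path) -> Path:
    """Write a table in the canonical tab-delimited dialect.

    Floats are serialized with shortest round-trip ``repr`` so that
    ``read_sumstats(write_sumstats(t))`` reproduces ``t`` field-for-field;
    optional fields absent from a record are written as ``NA``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in table.records:
            fields = [
                r.key.rsid if r.key.rsid is not None else MISSING,
                str(r.key.chrom), str(r.key.pos), r.key.ea, r.key.oa,
                _fmt(r.eaf), _fmt(r.beta), _fmt(r.se), _fmt(r.pval),
                str(r.n), MISSING if r.n_cases is None else str(r.n_cases),
            ]
            fh.write("\t".join(fields) + "\n")
    return path


@dataclass
class ReferencePanel:
    """Genotype dosages used for LD computation.

    ``dosages`` is an ``n_ref x m`` matrix of effect-allele dosages in
    [0, 2]; column ``j`` belongs to ``variants[j]``.
    """

    variants: list[VariantKey]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"dosage columns ({self.dosages.shape[1]}) != variants ({len(self.variants)})"
            )
        if self.dosages.shape[0] < 2:
            raise ValueError("reference panel needs at least 2 individuals")
        self._index = {v.position_id(): j for j, v in enumerate(self.variants)}

    @property
    def n_ref(self) -> int:
        return self.dosages.shape[0]

    def column(self, chrom: str, pos: int) -> int | None:
        return self._index.get((str(chrom), pos))

    def r2(self, col_a: int, col_b: int) -> float:
        """Squared Pearson correlation between two dosage columns."""
        a = self.dosages[:, col_a]
        b = self.dosages[:, col_b]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom == 0:
            return 0.0
        return float((a @ b) / denom) ** 2

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write as plain text: a variant sidecar TSV and a dosage matrix."""
        prefix = Path(prefix)
        var_path = prefix.with_suffix(".variants.tsv")
        dos_path = prefix.with_suffix(".dosages.tsv")
        with open(var_path, "w") as fh:
            fh.write("snp\tchr\tpos\tea\toa\n")
            for v in self.variants:
                fh.write(f"{v.rsid or MISSING}\t{v.chrom}\t{v.pos}\t{v.ea}\t{v.oa}\n")
        np.savetxt(dos_path, self.dosages, fmt="%.6g", delimiter="\t")
        return var_path, dos_path

    @classmethod
    def load(cls, prefix: str | Path) -> "ReferencePanel":
        prefix = Path(prefix)
        vdf = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t", dtype=str)
        variants = [
            VariantKey(
                chrom=row["chr"], pos=int(row["pos"]), ea=row["ea"], oa=row["oa"],
                rsid=None if row["snp"] == MISSING else row["snp"],
            )
            for row in vdf.to_dict(orient="records")
        ]
        dosages = np.loadtxt(prefix.with_suffix(".dosages.tsv"), delimiter="\t", ndmin=2)
        return cls(variants=variants, dosages=dosages)
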