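import numpy as np
import pytest

from mrkit.harmonize import HarmonizedInstrument, HarmonizedSet
from mrkit.sumstats import AssociationRecord, SumstatsTable, VariantKey


def make_hset(bx, sx, by, sy, outcome_type="continuous") -> HarmonizedSet:
    """Assemble a HarmonizedSet from plain effect arrays (test helper)."""
    instruments = [
        HarmonizedInstrument(
            key=VariantKey(chrom=str((j % 22) + 1), pos=1000 + 10_000 * j,
                           ea="A", oa="G", rsid=f"rs{j}"),
            beta_x=float(bx[j]), se_x=float(sx[j]),
            beta_y=float(by[j]), se_y=float(sy[j]),
        )
        for j in range(len(bx))
    ]
    return HarmonizedSet(instruments=instruments, outcome_type=outcome_type)


def make_record(chrom="1", pos=1000, ea="A", oa="G", rsid=None, beta=0.1,
                se=0.01, pval=1e-9, n=10_000, eaf=0.3, n_cases=None) -> AssociationRecord:
    return AssociationRecord(
        key=VariantKey(chrom=chrom, pos=pos, ea=ea, oa=oa, rsid=rsid),
        beta=beta, se=se, pval=pval, n=n, eaf=eaf, n_cases=n_cases,
    )


@pytest.fixture
def three_iv_hset() -> HarmonizedSet:
    """The hand-checkable 3-instrument fixture.

    IVW theta = 140/300, fixed se = 1/sqrt(300), Cochran Q = 2/3 (df 2),
    Egger slope 0.400 / intercept 0.00571..., weighted median 0.5.
    """
    return make_hset(
        bx=[0.10, 0.20, 0.05], sx=[0.01, 0.01, 0.01],
        by=[0.05, 0.08, 0.025], sy=[0.01, 0.02, 0.005],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_hset(rng: np.random.Generator, k: int, theta: float = 0.4,
                outcome_type: str = "continuous") -> HarmonizedSet:
    """A generic well-behaved instrument set drawn at summary level."""
    bx_true = rng.uniform(0.02, 0.15, k)
    sx = rng.uniform(0.002, 0.01, k)
    sy = rng.uniform(0.002, 0.01, k)
    bx = bx_true + sx * rng.standard_normal(k)
    by = theta * bx_true + sy * rng.standard_normal(k)
    return make_hset(bx, sx, by, sy, outcome_type=outcome_type)
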