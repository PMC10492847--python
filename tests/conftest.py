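import numpy as np
import pytest

from ivmr.harmonize import HarmonizedPair, HarmonizedSet
from ivmr.sumstats import SNPAssociation, SummaryStatsTable


@pytest.fixture
def toy_pairs():
    """Three-SNP set with hand-computed IVW = 0.11667, se = 0.04082,
    Q = 0.8333 (ratios 0.2, 0.1, 0.1 with weights 100, 400, 100)."""
    return HarmonizedSet("exp", "out", [
        HarmonizedPair("rs1", 0.1, 0.01, 0.02, 0.01),
        HarmonizedPair("rs2", 0.2, 0.01, 0.02, 0.01),
        HarmonizedPair("rs3", 0.1, 0.01, 0.01, 0.01),
    ])


def random_harmonized(rng: np.random.Generator, k: int = 10,
                      theta: float = 0.1) -> HarmonizedSet:
    """Random but well-conditioned harmonized set for oracle checks."""
    bx = rng.uniform(0.05, 0.5, k) * rng.choice([-1, 1], k)
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.01, 0.05, k)
    by = theta * bx + rng.normal(0, sy)
    pairs = [HarmonizedPair(f"rs{i}", bx[i], sx[i], by[i], sy[i])
             for i in range(k)]
    return HarmonizedSet("exp", "out", pairs)


def snp(rsid="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
        beta=0.1, se=0.01, pvalue=1e-9, n=None):
    return SNPAssociation(rsid, chrom, pos, ea, oa, eaf, beta, se, pvalue, n)


@pytest.fixture
def small_table():
    records = [
        snp("rs1", "1", 1_000_000, "A", "G", 0.3, 0.12, 0.01, 1e-10),
        snp("rs2", "2", 2_000_000, "C", "T", 0.4, -0.10, 0.012, 1e-9),
        snp("rs3", "3", 3_000_000, "A", "C", 0.2, 0.08, 0.011, 1e-8),
    ]
    return SummaryStatsTable("trait", records)
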