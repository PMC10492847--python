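"""Synthetic paired GWAS summary statistics with known ground truth.

The generator emulates the summary-level structure a two-sample MR
analysis consumes: per-SNP exposure effects γ_j drawn from a normal
prior and resampled until genome-wide significant at the exposure
sample size (so the relevance assumption holds by construction),
outcome effects θ·γ_j + α_j with α_j the per-SNP horizontal-pleiotropy
shift (zero for valid instruments), and standard errors from the
unit-variance approximation se(β) ≈ 1/√(2N·MAF(1−MAF)).  Observed
betas add Normal(0, se) noise; p-values are two-sided Wald tests.

Realism knobs: background null SNPs, LD blocks that replicate an index
SNP's signal at a chosen r², palindromic (A/T, C/G) allele assignment
with near-0.5 EAF, a planted confounder-trait catalog, and SNPs
missing from the outcome table.  Everything is reproducible from the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import math

import numpy as np
from scipy import stats

from .errors import FeasibilityError
from .harmonize import HarmonizedPair, HarmonizedSet
from .instruments import TraitAssociationCatalog
from .sumstats import LDReference, SNPAssociation, SummaryStatsTable

GWS_FORWARD = 5e-8
GWS_REVERSE = 5e-6

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))
_PALINDROME_PAIRS = (("A", "T"), ("C", "G"))

#: bp spacing between simulated loci; far beyond any clump window
_LOCUS_SPACING = 25_000_000


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated two-sample study."""

    k: int = 44
    theta: float = 0.0
    n_exp: int = 86_640
    n_out: int = 212_334
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.15
    prop_invalid: float = 0.0
    mu_alpha: float = 0.0
    sd_alpha: float = 0.0
    n_null_snps: int = 0
    ld_block_spec: tuple[tuple[int, float], ...] = ()
    palindrome_fraction: float = 0.0
    confounder_spec: tuple[tuple[str, str, float], ...] = ()
    n_missing_outcome: int = 0
    sig_threshold: float = GWS_FORWARD
    seed: int = 20230909

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 <= self.prop_invalid <= 1.0):
            raise ValueError("prop_invalid must be in [0,1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")


@dataclass
class SimulatedStudy:
    """Exposure/outcome tables, LD reference, catalog, and the truth."""

    exposure_table: SummaryStatsTable
    outcome_table: SummaryStatsTable
    ld: LDReference
    catalog: TraitAssociationCatalog
    truth: dict
    config: SimulationConfig

    def harmonized_truth(self) -> HarmonizedSet:
        """Pair instrument rows directly (bypassing selection), for
        estimator-level experiments on the generated instruments."""
        pairs = []
        for rsid in self.truth["instrument_rsids"]:
            e = self.exposure_table.get(rsid)
            o = self.outcome_table.get(rsid)
            if e is None or o is None:
                continue
            pairs.append(HarmonizedPair(rsid, e.beta, e.se, o.beta, o.se,
                                        e.eaf, o.eaf))
        return HarmonizedSet(self.exposure_table.trait_label,
                             self.outcome_table.trait_label, pairs)


def se_approx(n: int, maf: np.ndarray | float) -> np.ndarray | float:
    """Unit-variance summary-stat SE approximation, 1/√(2N·MAF(1−MAF))."""
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _wald_p(beta, se):
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(beta)) / np.asarray(se))
    return np.maximum(p, 1e-300)  # keep inside (0, 1]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one study; bit-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    k = config.k
    lo, hi = config.maf_range

    maf = rng.uniform(lo, hi, size=k)
    se_exp = se_approx(config.n_exp, maf)
    se_out = se_approx(config.n_out, maf)

    # exposure effects: resample until the *true* effect is genome-wide
    # significant at n_exp, so the relevance assumption holds by design
    z_min = stats.norm.isf(config.sig_threshold / 2.0)
    gamma = np.empty(k)
    for j in range(k):
        ok = False
        for _ in range(10_000):
            g = rng.normal(0.0, config.gamma_sd)
            if abs(g) / se_exp[j] > z_min:
                gamma[j] = g
                ok = True
                break
        if not ok:
            raise FeasibilityError(
                f"significance at p < {config.sig_threshold} unreachable for "
                f"gamma_sd={config.gamma_sd} at n_exp={config.n_exp}")
    # effect alleles are coded to the exposure-increasing allele (as in
    # risk-allele tables), so mu_alpha ≠ 0 is directional in the Egger sense
    gamma = np.abs(gamma)

    n_invalid = int(round(config.prop_invalid * k))
    invalid = np.zeros(k, dtype=bool)
    invalid[rng.choice(k, size=n_invalid, replace=False)] = True
    alpha = np.where(invalid, rng.normal(config.mu_alpha, config.sd_alpha or 1e-12,
                                         size=k), 0.0)
    beta_out_true = config.theta * gamma + alpha

    beta_exp_obs = gamma + rng.normal(0.0, se_exp)
    beta_out_obs = beta_out_true + rng.normal(0.0, se_out)

    n_pal = int(round(config.palindrome_fraction * k))
    pal_idx = rng.choice(k, size=n_pal, replace=False) if n_pal else np.array([], int)
    pal_mask = np.zeros(k, dtype=bool)
    pal_mask[pal_idx] = True
    # palindromes get near-0.5 EAF so the intermediate-frequency rule fires
    eaf = maf.copy()
    eaf[pal_mask] = rng.uniform(0.45, 0.55, size=n_pal)

    rsids = [f"rs{1000 + j}" for j in range(k)]
    chroms = [str(1 + j % 22) for j in range(k)]
    positions = [1_000_000 + (j // 22) * _LOCUS_SPACING for j in range(k)]
    alleles = []
    for j in range(k):
        pool = _PALINDROME_PAIRS if pal_mask[j] else _ALLELE_PAIRS
        a1, a2 = pool[rng.integers(len(pool))]
        alleles.append((a1, a2))

    exp_records, out_records = [], []
    ld = LDReference()
    for j in range(k):
        ld.positions[rsids[j]] = (chroms[j], positions[j])
        exp_records.append(SNPAssociation(
            rsids[j], chroms[j], positions[j], *alleles[j], float(eaf[j]),
            float(beta_exp_obs[j]), float(se_exp[j]),
            float(_wald_p(beta_exp_obs[j], se_exp[j])), config.n_exp))

    missing_idx = set()
    if config.n_missing_outcome:
        missing_idx = set(rng.choice(k, size=config.n_missing_outcome,
                                     replace=False).tolist())
    for j in range(k):
        if j in missing_idx:
            continue
        out_records.append(SNPAssociation(
            rsids[j], chroms[j], positions[j], *alleles[j], float(eaf[j]),
            float(beta_out_obs[j]), float(se_out[j]),
            float(_wald_p(beta_out_obs[j], se_out[j])), config.n_out))

    # LD blocks: tag SNPs replicate an index instrument's signal at r,
    # with the same SE, so tags are significant but strictly less so
    tag_records = []
    block_truth = []
    for b, (size, r2) in enumerate(config.ld_block_spec):
        idx = b % k
        r = math.sqrt(r2)
        for t in range(size - 1):
            rsid = f"rs{9000 + b * 100 + t}"
            pos = positions[idx] + 10_000 * (t + 1)  # well inside any window
            tag_beta = r * beta_exp_obs[idx]
            tag_records.append(SNPAssociation(
                rsid, chroms[idx], pos, *alleles[idx], float(maf[idx]),
                float(tag_beta), float(se_exp[idx]),
                float(_wald_p(tag_beta, se_exp[idx])), config.n_exp))
            ld.positions[rsid] = (chroms[idx], pos)
            ld.set_r2(rsid, rsids[idx], r2)
            for prev in range(t):
                ld.set_r2(rsid, f"rs{9000 + b * 100 + prev}", r2)
            block_truth.append((rsid, rsids[idx], r2))

    # background null SNPs: gamma = 0, far from every instrument locus
    null_records = []
    if config.n_null_snps:
        null_maf = rng.uniform(lo, hi, size=config.n_null_snps)
        null_se = se_approx(config.n_exp, null_maf)
        null_beta = rng.normal(0.0, null_se)
        for j in range(config.n_null_snps):
            rsid = f"rs{500000 + j}"
            chrom = str(1 + j % 22)
            pos = 600_000_000 + (j // 22) * 100_000
            a1, a2 = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            null_records.append(SNPAssociation(
                rsid, chrom, pos, a1, a2, float(null_maf[j]),
                float(null_beta[j]), float(null_se[j]),
                float(_wald_p(null_beta[j], null_se[j])), config.n_exp))
            ld.positions[rsid] = (chrom, pos)

    catalog = TraitAssociationCatalog(list(config.confounder_spec))

    exposure = SummaryStatsTable("sim_exposure",
                                 exp_records + tag_records + null_records,
                                 metadata={"source": "ivmr.simulate",
                                           "genome_build": "synthetic"})
    outcome = SummaryStatsTable("sim_outcome", out_records,
                                metadata={"source": "ivmr.simulate",
                                          "genome_build": "synthetic"})
    truth = {
        "theta": config.theta,
        "gamma": gamma,
        "alpha": alpha,
        "invalid": invalid,
        "instrument_rsids": rsids,
        "palindromic_rsids": [rsids[j] for j in range(k) if pal_mask[j]],
        "missing_outcome_rsids": sorted(rsids[j] for j in missing_idx),
        "ld_tags": block_truth,
        "confounder_rsids": sorted({r for r, _, _ in config.confounder_spec}),
    }
    return SimulatedStudy(exposure, outcome, ld, catalog, truth, config)


def ibd_rosacea_scenario(direction: str = "forward",
                         seed: int = 20230909) -> SimulationConfig:
    """Study-shaped scenario configs for end-to-end tests.

    ``forward`` mirrors an IBD→rosacea analysis: 44 instruments selected
    at p < 5e-8 from an exposure GWAS of N = 86,640, outcome
    N = 212,334, causal OR 1.1291.  ``reverse`` mirrors
    rosacea→IBD: 12 instruments at the relaxed p < 5e-6 threshold from
    the small rosacea GWAS, null causal effect, and the weakest
    exposure effects the selection threshold admits.
    """
    if direction == "forward":
        return SimulationConfig(k=44, theta=math.log(1.1291), n_exp=86_640,
                                n_out=212_334, gamma_sd=0.15,
                                sig_threshold=GWS_FORWARD, seed=seed)
    if direction == "reverse":
        return SimulationConfig(k=12, theta=0.0, n_exp=212_334, n_out=86_640,
                                gamma_sd=0.02, sig_threshold=GWS_REVERSE,
                                seed=seed)
    raise ValueError(f"unknown direction {direction!r}")


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
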