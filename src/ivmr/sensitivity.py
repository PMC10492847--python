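"""Heterogeneity, pleiotropy, influence and outlier diagnostics.

The validity of an MR estimate rests on all instruments targeting the
same causal parameter.  Four complementary checks are provided:

* **Cochran's Q / I²** — heterogeneity of the per-SNP Wald ratios
  around the IVW estimate; Q ~ χ²(k−1) under homogeneity, and
  I² = max(0, (Q−df)/Q)·100 is the percentage of variation attributable
  to heterogeneity.
* **Egger intercept test** — a nonzero intercept in the Egger
  regression indicates directional horizontal pleiotropy.
* **Leave-one-out** — re-estimate with each SNP omitted in turn; a
  single influential or outlying SNP shows up as a large shift.
* **MR-PRESSO** — residual-sum-of-squares framework: a parametric
  bootstrap global test for pleiotropy, a per-SNP outlier test with
  Bonferroni adjustment, and a distortion test comparing the
  outlier-corrected estimate with estimates after random removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import DEFAULT_SEED, MREstimate, egger, ivw
from .harmonize import HarmonizedSet


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pvalue: float
    i2: float  # percentage in [0, 100]


@dataclass
class PleiotropyResult:
    intercept: float
    se: float
    pvalue: float


@dataclass
class LeaveOneOutTable:
    """k rows of (omitted_rsid, beta, se, ci, p) plus the all-SNP row."""

    frame: pd.DataFrame  # columns: omitted_rsid, beta, se, ci_low, ci_high, pvalue, flagged

    @property
    def k(self) -> int:
        return len(self.frame) - 1


@dataclass
class PressoResult:
    rss_obs: float
    global_pvalue: float
    outlier_pvalues: dict[str, float]
    outliers: list[str]
    distortion_pvalue: float | None
    corrected_estimate: MREstimate | None
    n_sim: int
    seed: int
    extra: dict = field(default_factory=dict)


def heterogeneity_pvalue(q: float, df: int) -> float:
    """Upper-tail χ² p for a Q statistic on df = k − 1."""
    return float(stats.chi2.sf(q, df))


def cochran_q(hs: HarmonizedSet, order: str = "first") -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios about the IVW estimate, with I²."""
    if hs.n_snp < 2:
        raise InsufficientInstrumentsError(2, hs.n_snp, "Cochran Q")
    est = ivw(hs, model="fixed", order=order)
    q = est.extra["cochran_q"]
    df = hs.n_snp - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(q, df, heterogeneity_pvalue(q, df), i2)


def pleiotropy_test(hs: HarmonizedSet) -> PleiotropyResult:
    """Egger intercept test for directional pleiotropy."""
    res = egger(hs)
    return PleiotropyResult(res.intercept, res.intercept_se, res.intercept_pvalue)


def leave_one_out(hs: HarmonizedSet, order: str = "first") -> LeaveOneOutTable:
    """Fixed-effect IVW re-estimated with each SNP omitted in turn.

    A row is flagged when its CI conflicts with the full-set estimate's
    sign conclusion (i.e. omitting that SNP flips whether the CI
    excludes zero).
    """
    if hs.n_snp < 3:
        raise InsufficientInstrumentsError(3, hs.n_snp, "leave-one-out")
    full = ivw(hs, model="fixed", order=order)
    full_signif = full.ci_low > 0 or full.ci_high < 0
    rows = []
    rsids = hs.rsids
    for rsid in rsids:
        sub = hs.subset([r for r in rsids if r != rsid])
        est = ivw(sub, model="fixed", order=order)
        signif = est.ci_low > 0 or est.ci_high < 0
        rows.append({"omitted_rsid": rsid, "beta": est.beta, "se": est.se,
                     "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "pvalue": est.pvalue, "flagged": signif != full_signif})
    rows.append({"omitted_rsid": "ALL", "beta": full.beta, "se": full.se,
                 "ci_low": full.ci_low, "ci_high": full.ci_high,
                 "pvalue": full.pvalue, "flagged": False})
    return LeaveOneOutTable(pd.DataFrame(rows))


def _loo_thetas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW (WLS-through-origin) estimates, vectorised.

    θ_{-j} = (Σ w x y − w_j x_j y_j) / (Σ w x² − w_j x_j²), with
    w = 1/se_out² — identical to pooling the Wald ratios with
    first-order weights.
    """
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def mr_presso(hs: HarmonizedSet, n_sim: int = 1000, seed: int = DEFAULT_SEED,
              outlier_sig: float = 0.05, weight_exposure: bool = False,
              n_distortion: int = 1000) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is RSS_obs = Σ_j w_j (β_out,j − θ_{-j}·β_exp,j)²
    with θ_{-j} the leave-one-out IVW estimate and w_j = 1/se_out,j²
    (optionally 1/(se_out² + θ²·se_exp²) with ``weight_exposure``).  The
    global p compares RSS_obs with ``n_sim`` parametric-bootstrap
    replicates drawn under the no-pleiotropy model; the per-SNP outlier
    test compares each observed weighted squared residual with its own
    simulated distribution, Bonferroni-adjusted (×k).  When outliers
    exist, the distortion test compares the outlier-corrected estimate
    with estimates after removing random subsets of the same size.
    """
    k = hs.n_snp
    if k < 4:
        raise InsufficientInstrumentsError(4, k, "MR-PRESSO")
    bx, sx, by, sy = hs.arrays()
    rng = np.random.default_rng(seed)

    def weights(theta_minus):
        if weight_exposure:
            return 1.0 / (sy ** 2 + theta_minus ** 2 * sx ** 2)
        return np.broadcast_to(1.0 / sy ** 2, bx.shape)

    w0 = 1.0 / sy ** 2
    theta_minus = _loo_thetas(bx, by, w0)
    w_obs = weights(theta_minus)
    resid_obs = w_obs * (by - theta_minus * bx) ** 2
    rss_obs = float(resid_obs.sum())

    # parametric bootstrap under the no-pleiotropy model, vectorised over sims
    bxs = rng.normal(bx, sx, size=(n_sim, k))
    bys = rng.normal(theta_minus * bx, sy, size=(n_sim, k))
    ws = np.broadcast_to(w0, (n_sim, k))
    s_xy = np.sum(ws * bxs * bys, axis=1, keepdims=True)
    s_xx = np.sum(ws * bxs * bxs, axis=1, keepdims=True)
    theta_minus_sim = (s_xy - ws * bxs * bys) / (s_xx - ws * bxs * bxs)
    if weight_exposure:
        ws_eff = 1.0 / (sy ** 2 + theta_minus_sim ** 2 * sx ** 2)
    else:
        ws_eff = ws
    resid_sim = ws_eff * (bys - theta_minus_sim * bxs) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))

    out_p: dict[str, float] = {}
    for j, rsid in enumerate(hs.rsids):
        p_emp = (1 + np.sum(resid_sim[:, j] >= resid_obs[j])) / (1 + n_sim)
        out_p[rsid] = float(min(1.0, p_emp * k))  # Bonferroni
    outliers = [r for r, p in out_p.items() if p < outlier_sig]

    distortion_p = None
    corrected = None
    if outliers:
        keep = [r for r in hs.rsids if r not in outliers]
        if len(keep) >= 2:
            corrected = ivw(hs.subset(keep), model="fixed")
            full = ivw(hs, model="fixed")
            d_obs = corrected.beta - full.beta
            n_out = len(outliers)
            d_sim = np.empty(n_distortion)
            rsids = np.array(hs.rsids)
            for b in range(n_distortion):
                drop = rng.choice(k, size=n_out, replace=False)
                mask = np.ones(k, bool)
                mask[drop] = False
                est = ivw(hs.subset(list(rsids[mask])), model="fixed")
                d_sim[b] = est.beta - full.beta
            distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs)))
                                 / (1 + n_distortion))
    return PressoResult(rss_obs, global_p, out_p, outliers, distortion_p,
                        corrected, n_sim, seed,
                        extra={"weight_exposure": weight_exposure})
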