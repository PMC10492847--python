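"""Causal-effect estimators for two-sample summary-data MR.

All methods consume a :class:`~ivmr.harmonize.HarmonizedSet` of per-SNP
effect pairs (β_exp, β_out) with standard errors, and estimate the
causal log-odds effect θ of exposure on outcome:

* **Wald ratio** — per-SNP estimate r_j = β_out,j / β_exp,j with
  first-order SE se_out/|β_exp| (default) or the second-order
  delta-method SE.
* **IVW** — precision-weighted mean of the ratios, weights 1/se(r_j)²;
  identical to weighted least squares of β_out on β_exp through the
  origin with weights 1/se_out².  Fixed-effect SE (Σw)^{-1/2}; the
  multiplicative random-effects model scales it by max(1, √(Q/(k−1))).
* **MR-Egger** — weighted regression of β_out on β_exp with a free
  intercept (after orienting every β_exp ≥ 0); a nonzero intercept
  indicates directional horizontal pleiotropy.
* **Weighted median** — the ratio at which the cumulative weight
  function crosses 1/2; consistent when valid instruments carry a
  weight majority.  SE by seeded parametric bootstrap.
* **Simple/weighted mode** — argmax of a normal-kernel density of the
  ratios; consistent when the largest cluster of instruments is valid.

Estimates are reported on the log-odds scale and exponentiated to odds
ratios with 95% CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, InsufficientInstrumentsError
from .harmonize import HarmonizedPair, HarmonizedSet

Z95 = 1.959964  # two-sided 95% normal quantile
DEFAULT_SEED = 20230909
MODE_GRID_POINTS = 10_000


class OddsRatio(NamedTuple):
    or_: float
    ci_low: float
    ci_high: float
    pvalue: float


@dataclass
class MREstimate:
    """One method's causal estimate on log-odds and OR scales."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    or_: float
    or_ci_low: float
    or_ci_high: float
    n_snp: int
    extra: dict = field(default_factory=dict)


@dataclass
class MRResultSet:
    """All estimates computed from one harmonized set."""

    exposure_label: str
    outcome_label: str
    estimates: dict[str, MREstimate]
    harmonized: HarmonizedSet

    def to_frame(self):
        import pandas as pd
        rows = [{"exposure": self.exposure_label, "outcome": self.outcome_label,
                 "method": e.method, "n_snp": e.n_snp, "beta": e.beta,
                 "se": e.se, "or": e.or_, "ci_low": e.or_ci_low,
                 "ci_high": e.or_ci_high, "pvalue": e.pvalue}
                for e in self.estimates.values()]
        return pd.DataFrame(rows)


def to_odds_ratio(beta: float, se: float) -> OddsRatio:
    """OR = exp(β), 95% CI = exp(β ∓ 1.959964·se), two-sided normal p."""
    if se <= 0:
        raise DomainError(f"se must be > 0, got {se}")
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return OddsRatio(math.exp(beta), math.exp(beta - Z95 * se),
                     math.exp(beta + Z95 * se), max(p, np.finfo(float).tiny))


def _make_estimate(method: str, beta: float, se: float, n_snp: int,
                   pvalue: float | None = None, extra: dict | None = None) -> MREstimate:
    orr = to_odds_ratio(beta, se)
    p = orr.pvalue if pvalue is None else pvalue
    return MREstimate(method, beta, se, beta - Z95 * se, beta + Z95 * se, p,
                      orr.or_, orr.ci_low, orr.ci_high, n_snp, extra or {})


def wald_ratio(pair: HarmonizedPair, order: str = "first") -> tuple[float, float]:
    """Per-SNP causal ratio and its standard error.

    First-order SE ignores exposure-side uncertainty (the convention of
    the standard MR tooling); ``order="second"`` adds the delta-method
    term and is never smaller.
    """
    if pair.beta_exp == 0:
        raise DomainError(f"{pair.rsid}: beta_exp is zero; Wald ratio undefined")
    ratio = pair.beta_out / pair.beta_exp
    if order == "first":
        se = pair.se_out / abs(pair.beta_exp)
    elif order == "second":
        se = math.sqrt(pair.se_out ** 2 / pair.beta_exp ** 2
                       + pair.beta_out ** 2 * pair.se_exp ** 2 / pair.beta_exp ** 4)
    else:
        raise ValueError(f"unknown order {order!r}")
    return ratio, se


def _ratio_arrays(hs: HarmonizedSet, order: str = "first"):
    r = np.empty(hs.n_snp)
    se = np.empty(hs.n_snp)
    for i, p in enumerate(hs.pairs):
        r[i], se[i] = wald_ratio(p, order)
    return r, se


def _require(hs: HarmonizedSet, k_min: int, what: str) -> None:
    if hs.n_snp < k_min:
        raise InsufficientInstrumentsError(k_min, hs.n_snp, what)


def ivw(hs: HarmonizedSet, model: str = "fixed", order: str = "first") -> MREstimate:
    """Inverse-variance-weighted pooled estimate.

    The point estimate is identical under the fixed and multiplicative
    random-effects models; only the SE differs (random-effects scales by
    max(1, √(Q/(k−1)))).
    """
    _require(hs, 2, "IVW")
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    r, se_r = _ratio_arrays(hs, order)
    w = 1.0 / se_r ** 2
    theta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - theta) ** 2))
    k = hs.n_snp
    scale = max(1.0, math.sqrt(q / (k - 1))) if k > 1 else 1.0
    se = se_fixed * scale if model == "random" else se_fixed
    return _make_estimate(f"ivw_{model}", theta, se, k,
                          extra={"cochran_q": q, "overdispersion": scale})


@dataclass
class EggerResult:
    """Egger slope (causal estimate) and intercept (pleiotropy) terms."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def egger(hs: HarmonizedSet) -> EggerResult:
    """MR-Egger weighted regression with a free intercept.

    Pairs are oriented so every β_exp ≥ 0 (joint sign flip), weights are
    1/se_out², and both SEs carry a multiplicative overdispersion factor
    bounded below at 1.  P-values use the t(k−2) reference.
    """
    _require(hs, 3, "MR-Egger")
    bx, sx, by, sy = hs.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    if np.ptp(x) == 0:
        raise DomainError("MR-Egger: zero variance in exposure effects")
    w = 1.0 / sy ** 2
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=w).fit()
    k = hs.n_snp
    sigma = math.sqrt(fit.scale)  # weighted residual SD
    # unit-variance covariance (X'WX)^-1, scaled by max(1, sigma): the
    # overdispersion factor is bounded below at 1 and survives sigma = 0
    xtwx_inv = np.linalg.inv(X.T @ (w[:, None] * X))
    se_int, se_slope = np.sqrt(np.diag(xtwx_inv)) * max(1.0, sigma)
    b_int, b_slope = fit.params
    p_slope = 2.0 * stats.t.sf(abs(b_slope) / se_slope, df=k - 2)
    p_int = 2.0 * stats.t.sf(abs(b_int) / se_int, df=k - 2)
    slope = _make_estimate("egger", float(b_slope), float(se_slope), k,
                           pvalue=float(p_slope),
                           extra={"residual_sd": sigma})
    return EggerResult(slope, float(b_int), float(se_int), float(p_int))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w  # midpoint cumulative weight
    below = np.flatnonzero(s < 0.5)
    if below.size == 0:
        return float(v[0])
    j = below[-1]
    if j == len(v) - 1:
        return float(v[-1])
    # linear interpolation between the bracketing ratios
    return float(v[j] + (v[j + 1] - v[j]) * (0.5 - s[j]) / (s[j + 1] - s[j]))


def weighted_median(hs: HarmonizedSet, weights: str = "ivw",
                    n_boot: int = 1000, seed: int = DEFAULT_SEED,
                    order: str = "first") -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    ``weights="ivw"`` uses inverse-variance weights on the ratios;
    ``weights="simple"`` gives the unweighted median.
    """
    _require(hs, 3, "weighted median")
    r, se_r = _ratio_arrays(hs, order)
    w = np.ones_like(r) if weights == "simple" else 1.0 / se_r ** 2
    theta = _weighted_median(r, w)
    bx, sx, by, sy = hs.arrays()
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        rs = bys / bxs
        ses = sy / np.abs(bxs)
        ws = np.ones_like(rs) if weights == "simple" else 1.0 / ses ** 2
        boots[b] = _weighted_median(rs, ws)
    se = float(boots.std(ddof=1))
    return _make_estimate(f"{'simple' if weights == 'simple' else 'weighted'}_median",
                          theta, se, hs.n_snp, extra={"n_boot": n_boot})


def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    s = r.std(ddof=1) if len(r) > 1 else 0.0
    mad = stats.median_abs_deviation(r, scale="normal")
    spread = min(s, mad) if mad > 0 else s
    return phi * 0.9 * spread * len(r) ** (-1 / 5)


def _kde_mode(r: np.ndarray, w: np.ndarray, h: float) -> float:
    if h <= 0 or np.ptp(r) == 0:
        return float(r[0])
    grid = np.linspace(r.min() - h, r.max() + h, MODE_GRID_POINTS)
    dens = (w[None, :] * stats.norm.pdf((grid[:, None] - r[None, :]) / h)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimate(hs: HarmonizedSet, weighted: bool = True, phi: float = 1.0,
                  n_boot: int = 1000, seed: int = DEFAULT_SEED,
                  order: str = "first") -> MREstimate:
    """Mode-based estimate: argmax of a normal-kernel density of ratios.

    Bandwidth h = φ·0.9·min(sd, MAD·1.4826)·k^(−1/5) on a 10,000-point
    grid spanning [min(r)−h, max(r)+h].  When all ratios coincide the
    common ratio is returned.  SE by seeded parametric bootstrap.
    """
    _require(hs, 3, "mode estimate")
    r, se_r = _ratio_arrays(hs, order)
    w = 1.0 / se_r ** 2 if weighted else np.ones_like(r)
    w = w / w.sum()
    theta = _kde_mode(r, w, _mode_bandwidth(r, phi))
    bx, sx, by, sy = hs.arrays()
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        rs = bys / bxs
        ws = 1.0 / (sy / np.abs(bxs)) ** 2 if weighted else np.ones_like(rs)
        ws = ws / ws.sum()
        boots[b] = _kde_mode(rs, ws, _mode_bandwidth(rs, phi))
    se = float(boots.std(ddof=1))
    return _make_estimate("weighted_mode" if weighted else "simple_mode",
                          theta, se, hs.n_snp,
                          extra={"phi": phi, "n_boot": n_boot})


def estimate_all(hs: HarmonizedSet, n_boot: int = 1000,
                 seed: int = DEFAULT_SEED, phi: float = 1.0,
                 ivw_model: str = "fixed") -> MRResultSet:
    """Run the five standard methods on one harmonized set."""
    egg = egger(hs)
    estimates = {
        "ivw": ivw(hs, model=ivw_model),
        "egger": egg.slope,
        "weighted_median": weighted_median(hs, "ivw", n_boot, seed),
        "simple_mode": mode_estimate(hs, weighted=False, phi=phi,
                                     n_boot=n_boot, seed=seed),
        "weighted_mode": mode_estimate(hs, weighted=True, phi=phi,
                                       n_boot=n_boot, seed=seed),
    }
    estimates["egger"].extra.update({"intercept": egg.intercept,
                                     "intercept_se": egg.intercept_se,
                                     "intercept_pvalue": egg.intercept_pvalue})
    return MRResultSet(hs.exposure_label, hs.outcome_label, estimates, hs)
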