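"""End-to-end bidirectional MR orchestration.

``run_mr`` executes one direction: instrument selection (significance →
LD clump → confounder screen) → harmonization → the five estimators →
sensitivity analyses (Cochran Q, Egger intercept, leave-one-out,
MR-PRESSO), with provenance counts at every stage.  ``run_bidirectional``
runs both directions with their own significance thresholds and
assembles a sensitivity table mirroring the usual published layout
(exposure, outcome, n_iv, Q, Q_p, Egger intercept + p, RSSobs,
global p, outliers).

The IVW estimate is the primary method for the causal verdict at
α = 0.05; the fixed-effect model is used when the heterogeneity p ≥
0.05 and the multiplicative random-effects model otherwise (both are
stored).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import PipelineStageError
from .estimators import (DEFAULT_SEED, MREstimate, MRResultSet, _make_estimate,
                         estimate_all, wald_ratio)
from .harmonize import HarmonizedSet, harmonize
from .instruments import (InstrumentSet, LDReference, SelectionConfig,
                          TraitAssociationCatalog, build_instrument_set)
from .sensitivity import (HeterogeneityResult, LeaveOneOutTable,
                          PleiotropyResult, PressoResult, cochran_q,
                          leave_one_out, mr_presso, pleiotropy_test)
from .sumstats import SummaryStatsTable, read_sumstats


@dataclass
class AnalysisConfig:
    """Inputs and tunables for one bidirectional trait pair.

    ``trait_a``/``trait_b`` may be in-memory tables or file paths.
    Direction "forward" instruments trait A (threshold ``p_forward``);
    "reverse" instruments trait B (threshold ``p_reverse``, conventionally
    relaxed when the B GWAS is small).
    """

    trait_a: SummaryStatsTable | str
    trait_b: SummaryStatsTable | str
    ld: LDReference
    catalog: TraitAssociationCatalog | None = None
    p_forward: float = 5e-8
    p_reverse: float = 5e-6
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    confounders_forward: tuple[str, ...] = ()
    confounders_reverse: tuple[str, ...] = ()
    confounder_p: float = 5e-8
    proxy_r2: float = 0.80
    palindrome_mode: str = "drop_intermediate"
    eaf_window: tuple[float, float] = (0.42, 0.58)
    n_a: int | None = None
    n_b: int | None = None
    n_boot: int = 1000
    presso_n_sim: int = 1000
    phi: float = 1.0
    seed: int = DEFAULT_SEED
    alpha: float = 0.05


@dataclass
class DirectionReport:
    """Everything computed for one exposure→outcome direction."""

    exposure_label: str
    outcome_label: str
    instruments: InstrumentSet
    harmonized: HarmonizedSet
    results: MRResultSet | None
    heterogeneity: HeterogeneityResult | None
    pleiotropy: PleiotropyResult | None
    presso: PressoResult | None
    loo: LeaveOneOutTable | None
    verdict: str
    primary: MREstimate | None
    status: str = "ok"
    log: list[dict] = field(default_factory=list)


@dataclass
class MRReport:
    forward: DirectionReport | None = None
    reverse: DirectionReport | None = None

    def directions(self) -> list[DirectionReport]:
        return [d for d in (self.forward, self.reverse) if d is not None]


def _as_table(t: SummaryStatsTable | str, label: str | None = None) -> SummaryStatsTable:
    if isinstance(t, SummaryStatsTable):
        return t
    return read_sumstats(t, trait_label=label)


def run_mr(config: AnalysisConfig, direction: str = "forward") -> DirectionReport:
    """Run one direction end-to-end.

    Raises :class:`PipelineStageError` naming the depleting stage when
    no instrument survives; with exactly one surviving instrument a
    degraded report is returned whose IVW slot holds the single-SNP Wald
    ratio (status ``"single_snp"``).
    """
    if direction == "forward":
        exposure = _as_table(config.trait_a)
        outcome = _as_table(config.trait_b)
        p_thr = config.p_forward
        confounders = config.confounders_forward
        n_exp = config.n_a
    elif direction == "reverse":
        exposure = _as_table(config.trait_b)
        outcome = _as_table(config.trait_a)
        p_thr = config.p_reverse
        confounders = config.confounders_reverse
        n_exp = config.n_b
    else:
        raise ValueError(f"unknown direction {direction!r}")

    sel = SelectionConfig(p_threshold=p_thr, clump_r2=config.clump_r2,
                          clump_window_kb=config.clump_window_kb,
                          confounder_traits=tuple(confounders),
                          confounder_p=config.confounder_p,
                          proxy_r2=config.proxy_r2, n_exposure=n_exp)
    iv = build_instrument_set(exposure, config.ld, config.catalog, sel)
    log = [{"stage": e.step, "n_in": e.n_in, "n_out": e.n_out,
            "dropped": list(e.dropped)} for e in iv.provenance]
    if iv.k == 0:
        depleting = next((e.step for e in iv.provenance if e.n_out == 0),
                         "selection")
        raise PipelineStageError(depleting, "no instruments survived")

    hs = harmonize(iv, outcome, config.palindrome_mode, config.eaf_window)
    log.append({"stage": "harmonize", "n_in": iv.k, "n_out": hs.n_snp,
                "dropped": [r for r, _ in hs.exclusions],
                "reasons": dict(hs.exclusions)})
    k = hs.n_snp
    if k == 0:
        raise PipelineStageError("harmonize", "no instruments survived")
    if k == 1:
        ratio, se = wald_ratio(hs.pairs[0])
        est = _make_estimate("wald_ratio", ratio, se, 1)
        verdict = "causal" if est.pvalue < config.alpha else "not_causal"
        return DirectionReport(hs.exposure_label, hs.outcome_label, iv, hs,
                               None, None, None, None, None, verdict, est,
                               status="single_snp", log=log)

    het = cochran_q(hs)
    ivw_model = "fixed" if het.pvalue >= 0.05 else "random"
    results = estimate_all(hs, n_boot=config.n_boot, seed=config.seed,
                           phi=config.phi, ivw_model=ivw_model)
    pleio = pleiotropy_test(hs) if k >= 3 else None
    loo = leave_one_out(hs) if k >= 3 else None
    presso = (mr_presso(hs, n_sim=config.presso_n_sim, seed=config.seed)
              if k >= 4 else None)
    primary = results.estimates["ivw"]
    verdict = "causal" if primary.pvalue < config.alpha else "not_causal"
    log.append({"stage": "estimate", "n_in": k, "n_out": k, "dropped": [],
                "ivw_model": ivw_model})
    return DirectionReport(hs.exposure_label, hs.outcome_label, iv, hs,
                           results, het, pleio, presso, loo, verdict, primary,
                           log=log)


def run_bidirectional(config: AnalysisConfig) -> MRReport:
    """Both directions; a failure in one direction does not abort the other."""
    report = MRReport()
    errors: dict[str, PipelineStageError] = {}
    for direction in ("forward", "reverse"):
        try:
            setattr(report, direction, run_mr(config, direction))
        except PipelineStageError as exc:
            errors[direction] = exc
    if report.forward is None and report.reverse is None:
        raise next(iter(errors.values()))
    for direction, exc in errors.items():
        setattr(report, f"{direction}_error", exc)
    return report


def sensitivity_frame(reports: list[DirectionReport]) -> pd.DataFrame:
    """Sensitivity table: one row per direction, published-table layout."""
    rows = []
    for d in reports:
        rows.append({
            "exposure": d.exposure_label,
            "outcome": d.outcome_label,
            "n_iv": d.harmonized.n_snp,
            "Q": d.heterogeneity.q if d.heterogeneity else float("nan"),
            "Q_p": d.heterogeneity.pvalue if d.heterogeneity else float("nan"),
            "egger_intercept": d.pleiotropy.intercept if d.pleiotropy else float("nan"),
            "egger_p": d.pleiotropy.pvalue if d.pleiotropy else float("nan"),
            "rss_obs": d.presso.rss_obs if d.presso else float("nan"),
            "presso_global_p": d.presso.global_pvalue if d.presso else float("nan"),
            "outliers": ",".join(d.presso.outliers) if d.presso and d.presso.outliers
                        else "None",
        })
    return pd.DataFrame(rows)


def results_frame(reports: list[DirectionReport]) -> pd.DataFrame:
    frames = [d.results.to_frame() for d in reports if d.results is not None]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def export_plot_data(report: MRReport | DirectionReport, outdir: str | Path) -> dict[str, Path]:
    """Write scatter / forest / funnel / leave-one-out TSVs per direction."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dirs = report.directions() if isinstance(report, MRReport) else [report]
    written: dict[str, Path] = {}
    for d in dirs:
        tag = f"{d.exposure_label}_to_{d.outcome_label}"
        scatter = d.harmonized.to_frame()[["rsid", "beta_exp", "se_exp",
                                           "beta_out", "se_out"]]
        if d.results is not None:
            for name, est in d.results.estimates.items():
                scatter[f"fit_{name}"] = est.beta * scatter["beta_exp"]
                if name == "egger":
                    scatter[f"fit_{name}"] += est.extra.get("intercept", 0.0)
        p = outdir / f"scatter_{tag}.tsv"
        scatter.to_csv(p, sep="\t", index=False, float_format="%.12g")
        written[f"scatter_{tag}"] = p

        forest_rows = []
        if d.results is not None:
            for est in d.results.estimates.values():
                forest_rows.append({"label": est.method, "kind": "method",
                                    "or": est.or_, "ci_low": est.or_ci_low,
                                    "ci_high": est.or_ci_high, "pvalue": est.pvalue})
        funnel_rows = []
        for pair in d.harmonized.pairs:
            ratio, se = wald_ratio(pair)
            orr = _make_estimate("wald_ratio", ratio, se, 1)
            forest_rows.append({"label": pair.rsid, "kind": "snp",
                                "or": orr.or_, "ci_low": orr.or_ci_low,
                                "ci_high": orr.or_ci_high, "pvalue": orr.pvalue})
            funnel_rows.append({"rsid": pair.rsid, "ratio": ratio,
                                "precision": 1.0 / se})
        p = outdir / f"forest_{tag}.tsv"
        pd.DataFrame(forest_rows).to_csv(p, sep="\t", index=False,
                                         float_format="%.12g")
        written[f"forest_{tag}"] = p
        p = outdir / f"funnel_{tag}.tsv"
        pd.DataFrame(funnel_rows).to_csv(p, sep="\t", index=False,
                                         float_format="%.12g")
        written[f"funnel_{tag}"] = p
        if d.loo is not None:
            p = outdir / f"leave_one_out_{tag}.tsv"
            d.loo.frame.to_csv(p, sep="\t", index=False, float_format="%.12g")
            written[f"leave_one_out_{tag}"] = p
    return written


def write_report(report: MRReport, outdir: str | Path) -> dict[str, Path]:
    """Write the sensitivity table, per-method results, plot data and a
    JSON-lines provenance log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = export_plot_data(report, outdir)
    dirs = report.directions()
    p = outdir / "sensitivity.tsv"
    sensitivity_frame(dirs).to_csv(p, sep="\t", index=False, float_format="%.12g")
    written["sensitivity"] = p
    p = outdir / "results.tsv"
    results_frame(dirs).to_csv(p, sep="\t", index=False, float_format="%.12g")
    written["results"] = p
    p = outdir / "provenance.jsonl"
    with open(p, "w") as fh:
        for d in dirs:
            for entry in d.log:
                fh.write(json.dumps({"exposure": d.exposure_label,
                                     "outcome": d.outcome_label, **entry}) + "\n")
    written["provenance"] = p
    return written
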