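"""Instrument selection and instrument-strength metrics.

Instrumental variables for a two-sample MR analysis are selected from an
exposure GWAS by three filters applied in order:

1. genome-wide significance (``p < p_threshold``, conventionally 5e-8
   for well-powered exposures, relaxed to 5e-6 for small ones);
2. greedy LD clumping (keep the most significant SNP, drop every SNP
   within ``window_kb`` on the same chromosome whose r² with a kept SNP
   exceeds ``r2_max``), so retained instruments are approximately
   independent;
3. a confounder screen against a local trait-association catalog (a
   PhenoScanner-style table): a SNP — or any LD proxy above ``proxy_r2``
   — associated with a listed confounder trait at ``p < confounder_p``
   is removed.

Strength is summarised by the variance explained per SNP,
``R² = 2·MAF·(1−MAF)·(beta/SD)²``, their sum over the (independent)
instruments, and the F statistic ``F = ((N−k−1)/k)·(R²/(1−R²))``;
``F > 10`` is the conventional strong-instrument rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DomainError, FormatError
from .sumstats import (LDReference, ProvenanceEntry, SNPAssociation,
                       SummaryStatsTable, _detect_delimiter, read_ld_reference)

__all__ = [
    "LDReference", "read_ld_reference", "TraitAssociationCatalog",
    "InstrumentSet", "SelectionConfig", "select_significant", "ld_clump",
    "screen_confounders", "variance_explained", "f_statistic",
    "build_instrument_set", "read_trait_catalog",
]


class TraitAssociationCatalog:
    """Local stand-in for a PhenoScanner-style SNP→trait lookup.

    Holds rows of (rsid, trait, pvalue) and an optional proxy map
    rsid → {(proxy_rsid, r²)} so the screen can catch associations
    carried by SNPs in LD with an instrument.
    """

    def __init__(self, rows: Iterable[tuple[str, str, float]] = (),
                 proxies: Mapping[str, Iterable[tuple[str, float]]] | None = None):
        self._by_rsid: dict[str, list[tuple[str, float]]] = {}
        for rsid, trait, p in rows:
            if not (0.0 < p <= 1.0):
                raise FormatError(f"catalog p-value for {rsid}/{trait} outside (0,1]")
            self._by_rsid.setdefault(rsid, []).append((trait, float(p)))
        self.proxies: dict[str, list[tuple[str, float]]] = {}
        for rsid, plist in (proxies or {}).items():
            for proxy, r2 in plist:
                if not (0.0 <= r2 <= 1.0):
                    raise FormatError(f"proxy r2 for {rsid}->{proxy} outside [0,1]")
                self.proxies.setdefault(rsid, []).append((proxy, float(r2)))

    def associations(self, rsid: str) -> list[tuple[str, float]]:
        return self._by_rsid.get(rsid, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_rsid.values())

    def hits(self, rsid: str, traits: set[str], p_thr: float,
             proxy_r2: float) -> list[tuple[str, str, float]]:
        """(offending_rsid, trait, p) entries that flag ``rsid``."""
        out = []
        for trait, p in self.associations(rsid):
            if trait in traits and p < p_thr:
                out.append((rsid, trait, p))
        for proxy, r2 in self.proxies.get(rsid, []):
            if r2 > proxy_r2:
                for trait, p in self.associations(proxy):
                    if trait in traits and p < p_thr:
                        out.append((proxy, trait, p))
        return out


def read_trait_catalog(path: str | Path,
                       proxy_path: str | Path | None = None) -> TraitAssociationCatalog:
    """Read catalog TSV (rsid, trait, pvalue) + optional proxy TSV
    (rsid, proxy_rsid, r2)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_delimiter(path))
    if not {"rsid", "trait", "pvalue"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns rsid, trait, pvalue")
    rows = [(str(r), str(t), float(p))
            for r, t, p in df[["rsid", "trait", "pvalue"]].itertuples(index=False)]
    proxies: dict[str, list[tuple[str, float]]] = {}
    if proxy_path is not None:
        proxy_path = Path(proxy_path)
        pdf = pd.read_csv(proxy_path, sep=_detect_delimiter(proxy_path))
        if not {"rsid", "proxy_rsid", "r2"}.issubset(pdf.columns):
            raise FormatError(f"{proxy_path}: expected columns rsid, proxy_rsid, r2")
        for r, pr, r2 in pdf[["rsid", "proxy_rsid", "r2"]].itertuples(index=False):
            proxies.setdefault(str(r), []).append((str(pr), float(r2)))
    return TraitAssociationCatalog(rows, proxies)


@dataclass
class SelectionConfig:
    """Thresholds and study-level constants for instrument selection."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    confounder_traits: tuple[str, ...] = ()
    confounder_p: float = 5e-8
    proxy_r2: float = 0.80
    n_exposure: int | None = None
    trait_sd: float = 1.0


@dataclass
class InstrumentSet:
    """Post-selection instruments with strength metrics and provenance."""

    exposure_label: str
    instruments: list[SNPAssociation]
    per_snp_r2: dict[str, float]
    total_r2: float
    f_statistic: float | None
    n_exposure: int | None
    provenance: list[ProvenanceEntry] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.instruments)

    @property
    def is_strong(self) -> bool | None:
        # strict inequality: F = 10 exactly is still "weak"
        return None if self.f_statistic is None else self.f_statistic > 10.0

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.instruments]


def _tie_key(rec: SNPAssociation):
    # deterministic clump order: pvalue, chrom, pos, rsid
    return (rec.pvalue, rec.chrom, rec.pos, rec.rsid)


def select_significant(table: SummaryStatsTable,
                       p_threshold: float) -> SummaryStatsTable:
    """Keep records with ``pvalue < p_threshold``, sorted by ascending p."""
    if not (0.0 < p_threshold <= 1.0):
        raise DomainError(f"p_threshold must be in (0,1], got {p_threshold}")
    kept = sorted((r for r in table.records if r.pvalue < p_threshold),
                  key=_tie_key)
    dropped = [r.rsid for r in table.records if r.pvalue >= p_threshold]
    step = ProvenanceEntry("select_significant", len(table.records), len(kept),
                           dropped, {"p_threshold": p_threshold})
    return table.replace_records(kept, step)


def ld_clump(table: SummaryStatsTable, ld: LDReference,
             r2_max: float = 0.001, window_kb: int = 10_000) -> SummaryStatsTable:
    """Greedy LD clumping.

    Records are visited in deterministic order (ascending p, then chrom,
    pos, rsid); a record is kept unless some already-kept SNP on the
    same chromosome lies within ``window_kb`` AND has r² > ``r2_max``
    with it.  SNPs absent from the LD reference are retained as isolated
    (logged), since clumping against an external panel cannot resolve
    them.
    """
    window_bp = int(window_kb) * 1000
    ordered = sorted(table.records, key=_tie_key)
    kept: list[SNPAssociation] = []
    dropped: list[str] = []
    drop_index: dict[str, str] = {}
    no_position: list[str] = []
    for rec in ordered:
        pos = ld.position(rec.rsid)
        if pos is None:
            pos = (rec.chrom, rec.pos)
            if rec.rsid not in ld.positions:
                no_position.append(rec.rsid)
        removed_by = None
        for idx in kept:
            ipos = ld.position(idx.rsid) or (idx.chrom, idx.pos)
            if ipos[0] != pos[0]:
                continue
            if abs(ipos[1] - pos[1]) <= window_bp and ld.r2(rec.rsid, idx.rsid) > r2_max:
                removed_by = idx.rsid
                break
        if removed_by is None:
            kept.append(rec)
        else:
            dropped.append(rec.rsid)
            drop_index[rec.rsid] = removed_by
    step = ProvenanceEntry("ld_clump", len(ordered), len(kept), dropped,
                           {"r2_max": r2_max, "window_kb": window_kb,
                            "removed_by": drop_index,
                            "not_in_ld_reference": no_position})
    return table.replace_records(kept, step)


def screen_confounders(table: SummaryStatsTable, catalog: TraitAssociationCatalog,
                       confounder_traits: set[str] | Iterable[str],
                       p_thr: float = 5e-8,
                       proxy_r2: float = 0.80) -> SummaryStatsTable:
    """Remove SNPs associated (directly or via an LD proxy with
    r² > ``proxy_r2``) with any listed confounder trait at p < ``p_thr``."""
    traits = set(confounder_traits)
    if not traits:
        raise DomainError("confounder_traits must be nonempty")
    kept, dropped, reasons = [], [], {}
    for rec in table.records:
        hits = catalog.hits(rec.rsid, traits, p_thr, proxy_r2)
        if hits:
            dropped.append(rec.rsid)
            reasons[rec.rsid] = hits
        else:
            kept.append(rec)
    step = ProvenanceEntry("screen_confounders", len(table.records), len(kept),
                           dropped, {"p_thr": p_thr, "proxy_r2": proxy_r2,
                                     "hits": reasons})
    return table.replace_records(kept, step)


def variance_explained(assoc: SNPAssociation, trait_sd: float = 1.0) -> float:
    """Per-SNP exposure variance explained, 2·MAF·(1−MAF)·(beta/SD)².

    MAF is the minor-allele frequency, min(eaf, 1−eaf), so the result is
    invariant to which allele is labelled the effect allele.
    """
    if trait_sd <= 0:
        raise DomainError(f"trait_sd must be > 0, got {trait_sd}")
    if assoc.eaf is None or not (0.0 < assoc.eaf < 1.0):
        raise DomainError(f"{assoc.rsid}: eaf required in (0,1) for R²")
    maf = min(assoc.eaf, 1.0 - assoc.eaf)
    return 2.0 * maf * (1.0 - maf) * (assoc.beta / trait_sd) ** 2


def f_statistic(total_r2: float, n: int, k: int) -> float:
    """Cragg–Donald-style F, ((N−k−1)/k)·(R²/(1−R²))."""
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise DomainError(f"need n > k+1 (n={n}, k={k})")
    if not (0.0 <= total_r2 < 1.0):
        raise DomainError(f"total_r2 must be in [0,1), got {total_r2}")
    return ((n - k - 1) / k) * (total_r2 / (1.0 - total_r2))


def build_instrument_set(table: SummaryStatsTable, ld: LDReference,
                         catalog: TraitAssociationCatalog | None,
                         config: SelectionConfig) -> InstrumentSet:
    """Run significance filter → LD clump → confounder screen and
    attach strength metrics.

    An empty final set is returned with a warning flag in provenance,
    not raised — downstream estimators then refuse.
    """
    t = select_significant(table, config.p_threshold)
    t = ld_clump(t, ld, config.clump_r2, config.clump_window_kb)
    if catalog is not None and config.confounder_traits:
        t = screen_confounders(t, catalog, config.confounder_traits,
                               config.confounder_p, config.proxy_r2)
    per_snp = {}
    for rec in t.records:
        try:
            per_snp[rec.rsid] = variance_explained(rec, config.trait_sd)
        except DomainError:
            per_snp[rec.rsid] = float("nan")
    total = float(sum(v for v in per_snp.values() if v == v))
    k = len(t.records)
    f = None
    # the summed-R² approximation can exceed 1 for very strong effects,
    # where the F formula's domain ends; F is then left undefined
    if (config.n_exposure is not None and k >= 1
            and config.n_exposure > k + 1 and 0.0 <= total < 1.0):
        f = f_statistic(total, config.n_exposure, k)
    prov = list(t.provenance)
    if k == 0:
        prov.append(ProvenanceEntry("warning_empty_set", 0, 0, [],
                                    {"message": "no instruments survived selection"}))
    return InstrumentSet(table.trait_label, list(t.records), per_snp, total, f,
                         config.n_exposure, prov)
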