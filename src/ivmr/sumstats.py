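"""GWAS summary-statistics tables and LD references.

The data model is rsid-keyed summary-level data: one
:class:`SNPAssociation` per variant per trait, carrying the effect
allele, the other allele, the effect-allele frequency (EAF), the
per-allele effect ``beta`` (log-odds for binary traits), its standard
error, the association p-value and optionally the sample size.

Files are delimited text with a header row.  The delimiter is
auto-detected between tab and comma; tab is the write default.  Column
dialects differ wildly between GWAS exports ("BETA", "b", "Effect"...),
so readers take an explicit column map or fall back to a built-in alias
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError

VALID_BASES = frozenset("ACGT")

#: Canonical field names for a summary-statistics table.
FIELDS = ("rsid", "chrom", "pos", "effect_allele", "other_allele",
          "eaf", "beta", "se", "pvalue", "n")

REQUIRED_FIELDS = FIELDS[:9]  # n is optional per record

# Common column-name dialects, lowercased.  Used when no explicit map is given.
_ALIASES: dict[str, tuple[str, ...]] = {
    "rsid": ("rsid", "snp", "id", "markername", "variant_id", "rs_id"),
    "chrom": ("chrom", "chr", "chromosome", "#chrom"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "effect_allele": ("effect_allele", "ea", "a1", "allele1", "alt"),
    "other_allele": ("other_allele", "oa", "a2", "allele2", "ref",
                     "non_effect_allele"),
    "eaf": ("eaf", "af", "maf", "effect_allele_frequency", "freq", "frq"),
    "beta": ("beta", "b", "effect", "effect_size", "log_odds"),
    "se": ("se", "stderr", "standard_error", "sebeta"),
    "pvalue": ("pvalue", "p", "pval", "p_value", "p.value"),
    "n": ("n", "samplesize", "n_total", "sample_size"),
}


@dataclass(frozen=True)
class SNPAssociation:
    """One SNP's summary-level association with one trait.

    Raises ``ValueError`` on construction when an invariant is violated:
    alleles must be distinct single bases; ``se > 0``; ``0 < eaf < 1``
    when present; ``0 < pvalue <= 1``.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int | None = None

    def __post_init__(self):
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_BASES or oa not in VALID_BASES:
            raise ValueError(f"{self.rsid}: alleles must be single bases A/C/G/T, "
                             f"got {ea!r}/{oa!r}")
        if ea == oa:
            raise ValueError(f"{self.rsid}: effect and other allele identical ({ea})")
        if not (self.se > 0):
            raise ValueError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.rsid}: eaf must be in (0,1), got {self.eaf}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.rsid}: pvalue must be in (0,1], got {self.pvalue}")
        if self.pos <= 0:
            raise ValueError(f"{self.rsid}: pos must be a positive 1-based integer")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.rsid}: n must be positive")


@dataclass
class ProvenanceEntry:
    """One filtering step's audit record: counts in/out and dropped rsids."""

    step: str
    n_in: int
    n_out: int
    dropped: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)


@dataclass
class SummaryStatsTable:
    """Ordered collection of :class:`SNPAssociation` for one trait."""

    trait_label: str
    records: list[SNPAssociation] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    rejections: list[tuple[int, str]] = field(default_factory=list)
    provenance: list[ProvenanceEntry] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for r in self.records:
            if r.rsid in seen:
                raise IntegrityError(f"duplicate rsid {r.rsid} in table "
                                     f"{self.trait_label!r}")
            seen.add(r.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SNPAssociation]:
        return iter(self.records)

    def get(self, rsid: str) -> SNPAssociation | None:
        return self._index().get(rsid)

    def _index(self) -> dict[str, SNPAssociation]:
        idx = self.__dict__.get("_idx")
        if idx is None or len(idx) != len(self.records):
            idx = {r.rsid: r for r in self.records}
            self.__dict__["_idx"] = idx
        return idx

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{f: getattr(r, f) for f in FIELDS}
                             for r in self.records], columns=list(FIELDS))

    def replace_records(self, records: Sequence[SNPAssociation],
                        step: ProvenanceEntry | None = None) -> "SummaryStatsTable":
        """New table with the same labels/provenance plus one more step."""
        prov = list(self.provenance) + ([step] if step else [])
        return SummaryStatsTable(self.trait_label, list(records),
                                 dict(self.metadata), provenance=prov)


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise FormatError(f"{path}: could not detect a tab or comma delimiter")


def infer_column_map(columns: Iterable[str]) -> dict[str, str]:
    """Map canonical field names to file columns using the alias table."""
    lower = {c.lower(): c for c in columns}
    cmap: dict[str, str] = {}
    for fieldname, aliases in _ALIASES.items():
        for a in aliases:
            if a in lower:
                cmap[fieldname] = lower[a]
                break
    return cmap


def read_sumstats(path: str | Path, column_map: Mapping[str, str] | None = None,
                  trait_label: str | None = None) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical field names (:data:`FIELDS`) to the
    file's column names; when omitted, common dialects are recognised
    automatically.  Rows violating a record invariant (e.g. ``se <= 0``,
    indel alleles) are rejected and logged on ``table.rejections``, never
    silently dropped.  A duplicated rsid raises :class:`IntegrityError`.
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cmap = dict(column_map) if column_map is not None else infer_column_map(df.columns)
    missing = [f for f in REQUIRED_FIELDS if f not in cmap]
    if missing:
        raise FormatError(f"{path}: no column mapped for required fields {missing}")
    for f in cmap.values():
        if f not in df.columns:
            raise FormatError(f"{path}: mapped column {f!r} not in header")

    records: list[SNPAssociation] = []
    rejections: list[tuple[int, str]] = []
    seen: set[str] = set()
    has_n = "n" in cmap and cmap["n"] in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            raw = {f: row[cmap[f]] for f in REQUIRED_FIELDS}
            n_raw = row[cmap["n"]] if has_n else ""
            eaf_raw = str(raw["eaf"]).strip()
            rec = SNPAssociation(
                rsid=str(raw["rsid"]).strip(),
                chrom=str(raw["chrom"]).strip(),
                pos=int(float(raw["pos"])),
                effect_allele=str(raw["effect_allele"]).strip().upper(),
                other_allele=str(raw["other_allele"]).strip().upper(),
                eaf=float(eaf_raw) if eaf_raw not in ("", "NA", "nan") else None,
                beta=float(raw["beta"]),
                se=float(raw["se"]),
                pvalue=float(raw["pvalue"]),
                n=int(float(n_raw)) if str(n_raw).strip() not in ("", "NA", "nan") else None,
            )
        except (ValueError, KeyError) as exc:
            rejections.append((i, str(exc)))
            continue
        if rec.rsid in seen:
            raise IntegrityError(f"{path}: duplicate rsid {rec.rsid}")
        seen.add(rec.rsid)
        records.append(rec)

    label = trait_label if trait_label is not None else path.stem
    table = SummaryStatsTable(label, records,
                              metadata={"source": str(path), "genome_build": ""})
    table.rejections = rejections
    return table


def write_sumstats(table: SummaryStatsTable, path: str | Path, sep: str = "\t") -> Path:
    """Write a table as delimited text; round-trips to 12 significant digits."""
    path = Path(path)
    df = table.to_frame()
    df.to_csv(path, sep=sep, index=False, float_format="%.12g", na_rep="NA")
    return path


# ---------------------------------------------------------------------------
# LD reference


class LDReference:
    """Symmetric pairwise r-squared lookup plus SNP positions.

    Unknown pairs default to r² = 0 (assumed independent); self-pairs
    are 1.  Positions map rsid → (chrom, pos).
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None,
                 positions: Mapping[str, tuple[str, int]] | None = None):
        self._r2: dict[frozenset, float] = {}
        self.positions: dict[str, tuple[str, int]] = dict(positions or {})
        for (a, b), r2 in (pairs or {}).items():
            self.set_r2(a, b, r2)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise FormatError(f"r2({a},{b}) = {r2} outside [0,1]")
        if a != b:
            self._r2[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def position(self, rsid: str) -> tuple[str, int] | None:
        return self.positions.get(rsid)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.positions

    def __len__(self) -> int:
        return len(self._r2)


def read_ld_reference(pairs_path: str | Path,
                      positions_path: str | Path | None = None) -> LDReference:
    """Read a long-format LD table (rsid_a, rsid_b, r2) and optional
    position table (rsid, chrom, pos)."""
    pairs_path = Path(pairs_path)
    sep = _detect_delimiter(pairs_path)
    df = pd.read_csv(pairs_path, sep=sep)
    need = {"rsid_a", "rsid_b", "r2"}
    if not need.issubset(df.columns):
        raise FormatError(f"{pairs_path}: expected columns {sorted(need)}")
    ref = LDReference()
    for a, b, r2 in df[["rsid_a", "rsid_b", "r2"]].itertuples(index=False):
        r2 = float(r2)
        if math.isnan(r2):
            raise FormatError(f"{pairs_path}: missing r2 for pair ({a},{b})")
        ref.set_r2(str(a), str(b), r2)
    if positions_path is not None:
        positions_path = Path(positions_path)
        sep = _detect_delimiter(positions_path)
        pos = pd.read_csv(positions_path, sep=sep)
        if not {"rsid", "chrom", "pos"}.issubset(pos.columns):
            raise FormatError(f"{positions_path}: expected columns rsid, chrom, pos")
        for rsid, chrom, p in pos[["rsid", "chrom", "pos"]].itertuples(index=False):
            ref.positions[str(rsid)] = (str(chrom), int(p))
    return ref
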