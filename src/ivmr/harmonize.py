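"""Allele harmonization of exposure instruments with outcome statistics.

Two-sample MR pairs each instrument's exposure effect with the outcome
effect *for the same effect allele*.  Outcome files may report the swap
of the exposure's alleles (effect and other exchanged), in which case
the outcome beta changes sign and the EAF is complemented.  Palindromic
SNPs (A/T or C/G) are strand-ambiguous: when their allele frequency is
intermediate (near 0.5) the orientation cannot be recovered and the SNP
is dropped; away from 0.5 the minor allele identifies the orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .instruments import InstrumentSet
from .sumstats import SummaryStatsTable, _detect_delimiter

PALINDROMIC_SETS = ({"A", "T"}, {"C", "G"})

#: exclusion reason codes
MISSING = "missing_in_outcome"
PAL_INTERMEDIATE = "palindromic_intermediate"
PAL_ALL = "palindromic_all_mode"
INCOMPATIBLE = "incompatible_alleles"


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is A/T or C/G (strand-ambiguous)."""
    return {a1, a2} in PALINDROMIC_SETS


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one SNP on a common effect allele."""

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self):
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.rsid}: standard errors must be > 0")


@dataclass
class HarmonizedSet:
    """Aligned effect pairs plus an exclusion log.

    ``count(instruments) == len(pairs) + len(exclusions)`` always holds
    for the output of :func:`harmonize`.
    """

    exposure_label: str
    outcome_label: str
    pairs: list[HarmonizedPair] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    @property
    def rsids(self) -> list[str]:
        return [p.rsid for p in self.pairs]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        bx = np.array([p.beta_exp for p in self.pairs], dtype=float)
        sx = np.array([p.se_exp for p in self.pairs], dtype=float)
        by = np.array([p.beta_out for p in self.pairs], dtype=float)
        sy = np.array([p.se_out for p in self.pairs], dtype=float)
        return bx, sx, by, sy

    def subset(self, keep: list[str]) -> "HarmonizedSet":
        keepset = set(keep)
        return HarmonizedSet(self.exposure_label, self.outcome_label,
                             [p for p in self.pairs if p.rsid in keepset],
                             list(self.exclusions))

    def to_frame(self) -> pd.DataFrame:
        cols = ["rsid", "beta_exp", "se_exp", "beta_out", "se_out",
                "eaf_exp", "eaf_out", "flipped", "palindromic"]
        return pd.DataFrame([{c: getattr(p, c) for c in cols}
                             for p in self.pairs], columns=cols)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.12g", na_rep="NA")
        return path


def read_harmonized(path: str | Path, exposure_label: str = "exposure",
                    outcome_label: str = "outcome") -> HarmonizedSet:
    """Ingest an exported harmonized TSV (the interchange format used to
    re-run estimators on externally harmonized instrument tables)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_delimiter(path), na_values=["NA"])
    need = {"rsid", "beta_exp", "se_exp", "beta_out", "se_out"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    pairs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        pairs.append(HarmonizedPair(
            rsid=str(d["rsid"]),
            beta_exp=float(d["beta_exp"]), se_exp=float(d["se_exp"]),
            beta_out=float(d["beta_out"]), se_out=float(d["se_out"]),
            eaf_exp=None if pd.isna(d.get("eaf_exp")) else float(d["eaf_exp"]),
            eaf_out=None if pd.isna(d.get("eaf_out")) else float(d["eaf_out"]),
            flipped=bool(d.get("flipped", False)),
            palindromic=bool(d.get("palindromic", False))))
    return HarmonizedSet(exposure_label, outcome_label, pairs)


def _intermediate(eaf: float | None, low: float, high: float) -> bool:
    return eaf is not None and low < eaf < high


def harmonize(instruments: InstrumentSet | SummaryStatsTable,
              outcome: SummaryStatsTable,
              mode: str = "drop_intermediate",
              eaf_window: tuple[float, float] = (0.42, 0.58)) -> HarmonizedSet:
    """Align exposure instruments with outcome summary statistics.

    Per rsid: absent from the outcome → excluded; same allele
    orientation → kept as-is; swapped alleles → outcome beta
    sign-flipped and EAF complemented; incompatible allele sets →
    excluded.  Palindromic SNPs: under ``mode="drop_intermediate"``,
    excluded iff either study's EAF falls inside ``eaf_window`` (or the
    outcome EAF is missing); otherwise the orientation is resolved by
    requiring the same allele to be minor in both studies.  Under
    ``mode="drop_all"`` every palindromic SNP is excluded.
    """
    if mode not in ("drop_intermediate", "drop_all"):
        raise ValueError(f"unknown palindrome mode {mode!r}")
    exp_records = (instruments.instruments if isinstance(instruments, InstrumentSet)
                   else instruments.records)
    exp_label = (instruments.exposure_label if isinstance(instruments, InstrumentSet)
                 else instruments.trait_label)
    low, high = eaf_window
    pairs: list[HarmonizedPair] = []
    exclusions: list[tuple[str, str]] = []

    for exp in exp_records:
        out = outcome.get(exp.rsid)
        if out is None:
            exclusions.append((exp.rsid, MISSING))
            continue
        pal = is_palindromic(exp.effect_allele, exp.other_allele)
        exp_set = {exp.effect_allele, exp.other_allele}
        out_set = {out.effect_allele, out.other_allele}
        if exp_set != out_set:
            exclusions.append((exp.rsid, INCOMPATIBLE))
            continue
        if pal:
            if mode == "drop_all":
                exclusions.append((exp.rsid, PAL_ALL))
                continue
            if (out.eaf is None or _intermediate(exp.eaf, low, high)
                    or _intermediate(out.eaf, low, high)):
                exclusions.append((exp.rsid, PAL_INTERMEDIATE))
                continue
            # Alleles alone cannot orient a palindrome (the swap equals the
            # strand flip); use minor-allele concordance instead.
            nominal_eaf_out = (out.eaf if out.effect_allele == exp.effect_allele
                               else 1.0 - out.eaf)
            flipped = (exp.eaf < 0.5) != (nominal_eaf_out < 0.5)
            sign_base = 1.0 if out.effect_allele == exp.effect_allele else -1.0
            sign = sign_base * (-1.0 if flipped else 1.0)
            eaf_out = 1.0 - nominal_eaf_out if flipped else nominal_eaf_out
            pairs.append(HarmonizedPair(
                exp.rsid, exp.beta, exp.se, sign * out.beta, out.se,
                exp.eaf, eaf_out, flipped=sign < 0, palindromic=True))
            continue
        if out.effect_allele == exp.effect_allele:
            pairs.append(HarmonizedPair(exp.rsid, exp.beta, exp.se,
                                        out.beta, out.se, exp.eaf, out.eaf,
                                        flipped=False, palindromic=False))
        else:  # swapped orientation
            eaf_out = None if out.eaf is None else 1.0 - out.eaf
            pairs.append(HarmonizedPair(exp.rsid, exp.beta, exp.se,
                                        -out.beta, out.se, exp.eaf, eaf_out,
                                        flipped=True, palindromic=False))
    return HarmonizedSet(exp_label, outcome.trait_label, pairs, exclusions)
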