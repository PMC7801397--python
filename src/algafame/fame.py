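"""FAME composition tables: parsing, validation, classes and fold-changes.

A gas-chromatography FAME (fatty acid methyl ester) profile is a vector of
percent-of-total-oil values keyed by lipid shorthand (``C16:0``,
``C18:3n3``...). This module parses the shorthand, validates profiles,
separates major from minor species (the < 1 % reporting filter), sums the
SFA/MUFA/PUFA class totals, and builds the treatment-contrast log2
fold-change matrix used for heat-map display.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FattyAcid",
    "parse_shorthand",
    "FameProfile",
    "validate_profile",
    "filter_major",
    "ClassTotals",
    "class_totals",
    "FoldChangeMatrix",
    "fold_change_matrix",
    "read_fame_table",
    "profiles_to_frame",
]

_SHORTHAND_RE = re.compile(r"^C(\d+):(\d+)(?:n(\d+))?$")

# Atomic masses fixed for bit-stable outputs.
_MASS_C = 12.011
_MASS_H = 1.008
_MASS_O = 15.999


@dataclass(frozen=True)
class FattyAcid:
    """One FAME species identified by its Cn:d shorthand.

    ``fa_class`` follows the double-bond count: SFA (d = 0), MUFA (d = 1),
    PUFA (d >= 2). ``methyl_ester_mass`` is the formula mass of the methyl
    ester C_{n+1} H_{2(n+1)-2d} O2 in g mol-1.
    """

    shorthand: str
    carbons: int
    double_bonds: int

    @property
    def fa_class(self) -> str:
        if self.double_bonds == 0:
            return "SFA"
        if self.double_bonds == 1:
            return "MUFA"
        return "PUFA"

    @property
    def methyl_ester_mass(self) -> float:
        n, d = self.carbons, self.double_bonds
        if n < 2:
            raise ValueError(f"{self.shorthand}: need at least 2 carbons")
        if d > n / 2:
            raise ValueError(
                f"{self.shorthand}: {d} double bonds chemically impossible for {n} carbons"
            )
        n_c = n + 1
        n_h = 2 * (n + 1) - 2 * d
        return n_c * _MASS_C + n_h * _MASS_H + 2 * _MASS_O


def parse_shorthand(text: str) -> FattyAcid:
    """Parse ``C{n}:{d}`` lipid shorthand, optionally with an omega suffix.

    >>> parse_shorthand("C18:3n3").fa_class
    'PUFA'
    """
    m = _SHORTHAND_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed fatty-acid shorthand: {text!r}")
    carbons = int(m.group(1))
    double_bonds = int(m.group(2))
    if carbons <= 0:
        raise ValueError(f"malformed fatty-acid shorthand: {text!r} (zero carbons)")
    return FattyAcid(text.strip(), carbons, double_bonds)


@dataclass
class FameProfile:
    """Percent-of-total-oil composition for one (treatment, day, replicate).

    ``composition`` maps canonical shorthand to percentage. Profiles need not
    sum to exactly 100 (unannotated chromatogram peaks exist) but may not
    exceed 100 plus a tolerance.
    """

    treatment: str
    day: int
    replicate: int
    composition: dict[str, float] = field(default_factory=dict)

    @property
    def fatty_acids(self) -> list[FattyAcid]:
        return [parse_shorthand(k) for k in self.composition]

    @property
    def total(self) -> float:
        return float(sum(self.composition.values()))

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, float]],
        treatment: str = "",
        day: int = 0,
        replicate: int = 1,
    ) -> "FameProfile":
        comp: dict[str, float] = {}
        for name, pct in pairs:
            key = parse_shorthand(name).shorthand
            if key in comp:
                raise ValueError(f"duplicate fatty acid {key!r} in profile")
            comp[key] = float(pct)
        return cls(treatment, day, replicate, comp)


def validate_profile(profile: FameProfile, tolerance: float = 1.0) -> FameProfile:
    """Check a profile for negative entries, malformed keys and excess totals.

    Returns the profile unchanged on success. The total may exceed 100 by at
    most ``tolerance`` percentage points (replicate GC totals drift slightly).
    """
    for name, pct in profile.composition.items():
        parse_shorthand(name)
        if pct < 0:
            raise ValueError(f"negative percentage for {name}: {pct}")
    total = profile.total
    if total > 100.0 + tolerance:
        raise ValueError(
            f"profile total {total:.4g}% exceeds 100 + tolerance ({tolerance}%)"
        )
    return profile


def filter_major(
    profile: FameProfile, threshold: float = 1.0
) -> tuple[FameProfile, FameProfile]:
    """Split a profile into major (>= threshold %) and minor species.

    Comparison happens at reporting precision (one decimal place), so a
    species printed as "1.0 %" counts as major under the default 1 %
    threshold. Reporting uses the major set; fuel-property estimation always
    uses the full profile.
    """
    major: dict[str, float] = {}
    minor: dict[str, float] = {}
    for name, pct in profile.composition.items():
        (major if round(pct, 1) >= threshold else minor)[name] = pct
    meta = (profile.treatment, profile.day, profile.replicate)
    return FameProfile(*meta, major), FameProfile(*meta, minor)


class ClassTotals(NamedTuple):
    sfa: float
    mufa: float
    pufa: float


def class_totals(profile: FameProfile) -> ClassTotals:
    """Sum percentages into SFA / MUFA / PUFA class totals."""
    sums = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    for name, pct in profile.composition.items():
        sums[parse_shorthand(name).fa_class] += pct
    return ClassTotals(sums["SFA"], sums["MUFA"], sums["PUFA"])


@dataclass
class FoldChangeMatrix:
    """Treatment-contrast matrix (rows: fatty acids, columns: days).

    ``values`` holds the raw statistic; ``clipped()`` returns the display
    copy limited to [-1, 1] to mirror a symmetric heat-map colour scale.
    Cells whose denominator mean is zero are NaN (flagged missing), never
    infinite. ``mode`` is ``log2_ratio`` (log2(mean_NS / mean_NR), default)
    or ``as_written_legacy`` (log2(mean_NS) / log2(mean_NR) - 1).
    """

    values: pd.DataFrame
    mode: str = "log2_ratio"

    def clipped(self, lo: float = -1.0, hi: float = 1.0) -> pd.DataFrame:
        return self.values.clip(lower=lo, upper=hi)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="fatty_acid")


_FC_MODES = ("log2_ratio", "as_written_legacy")


def _mean_by_day(profiles: Iterable[FameProfile]) -> pd.DataFrame:
    frames = []
    for p in profiles:
        for name, pct in p.composition.items():
            frames.append({"day": p.day, "fatty_acid": name, "percent": pct})
    if not frames:
        raise ValueError("no profiles supplied")
    df = pd.DataFrame(frames)
    return df.groupby(["fatty_acid", "day"])["percent"].mean().unstack("day")


def fold_change_matrix(
    ns: Iterable[FameProfile],
    nr: Iterable[FameProfile],
    mode: str = "log2_ratio",
) -> FoldChangeMatrix:
    """Build the NS-vs-NR fold-change matrix from replicate means.

    Only days present in both treatments are kept (no overlap is an error);
    the fatty-acid sets must match.
    """
    if mode not in _FC_MODES:
        raise ValueError(f"mode must be one of {_FC_MODES}, got {mode!r}")
    m_ns = _mean_by_day(ns)
    m_nr = _mean_by_day(nr)
    days = sorted(set(m_ns.columns) & set(m_nr.columns))
    if not days:
        raise ValueError("no overlapping days between NS and NR profiles")
    fas = sorted(set(m_ns.index) | set(m_nr.index))
    if set(m_ns.index) != set(m_nr.index):
        raise ValueError(
            "fatty-acid sets differ between treatments: "
            f"{sorted(set(m_ns.index) ^ set(m_nr.index))}"
        )
    a = m_ns.loc[fas, days].to_numpy(dtype=float)
    b = m_nr.loc[fas, days].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "log2_ratio":
            vals = np.where((a > 0) & (b > 0), np.log2(np.where(b > 0, a / b, 1.0)), np.nan)
            vals = np.where((a == b), 0.0, vals)  # exact identity maps to 0 even at 0/0
        else:
            la, lb = np.log2(a), np.log2(b)
            vals = np.where(np.isfinite(la) & np.isfinite(lb) & (lb != 0), la / lb - 1.0, np.nan)
    values = pd.DataFrame(vals, index=fas, columns=days)
    return FoldChangeMatrix(values=values, mode=mode)


# ---------------------------------------------------------------------------
# Table I/O

_META_COLUMNS = ("treatment", "day", "replicate")


def read_fame_table(path) -> list[FameProfile]:
    """Read a FAME table in long or wide format (sniffed by header).

    Long format has columns ``treatment, day, replicate, fatty_acid,
    percent``; wide format has the three metadata columns followed by one
    column per fatty-acid shorthand.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"FAME table missing columns: {missing}")
    if {"fatty_acid", "percent"}.issubset(df.columns):
        return _profiles_from_long(df)
    return _profiles_from_wide(df)


def _profiles_from_long(df: pd.DataFrame) -> list[FameProfile]:
    profiles = []
    for (trt, day, rep), sub in df.groupby(list(_META_COLUMNS), sort=True):
        profiles.append(
            FameProfile.from_pairs(
                zip(sub["fatty_acid"], sub["percent"]), str(trt), int(day), int(rep)
            )
        )
    return profiles


def _profiles_from_wide(df: pd.DataFrame) -> list[FameProfile]:
    fa_cols = [c for c in df.columns if c not in _META_COLUMNS]
    for c in fa_cols:
        parse_shorthand(c)
    profiles = []
    for rec in df.itertuples(index=False):
        row = dict(zip(df.columns, rec))
        comp = [(c, row[c]) for c in fa_cols if np.isfinite(row[c])]
        profiles.append(
            FameProfile.from_pairs(
                comp, str(row["treatment"]), int(row["day"]), int(row["replicate"])
            )
        )
    return profiles


def profiles_to_frame(profiles: Iterable[FameProfile]) -> pd.DataFrame:
    """Tidy long-format frame from a collection of profiles."""
    rows = [
        {
            "treatment": p.treatment,
            "day": p.day,
            "replicate": p.replicate,
            "fatty_acid": name,
            "percent": pct,
        }
        for p in profiles
        for name, pct in p.composition.items()
    ]
    return pd.DataFrame(rows)
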