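"""Biodiesel fuel-property estimation from FAME composition.

Implements the six published correlations used to screen an oil's biodiesel
quality directly from its fatty-acid methyl ester (FAME) percentage profile:

* cetane number (CN) — eight-term linear model in the named species,
* degree of unsaturation (DU) = MUFA + 2·dienes + 3·trienes,
* saponification value (SV) = sum of 560·N/M (mg KOH g-1),
* iodine value (IV) = sum of 254·D·N/M (g I2 per 100 g),
* long-chain saturation factor (LCSF) — weighted saturated C16–C24 sum,
* cold filter plugging point (CFPP) = 3.1417·LCSF − 16.477 (°C),

where N is the percent composition, M the methyl-ester molecular mass and D
the double-bond count. A registry of national biodiesel specifications
(EN 14214, ASTM D6751, RANP/2008, SIRIM MS 123) supports compliance checks
on CN and CFPP.

Two LCSF coefficient sets are provided because the published 0.6 weight for
C16:0 is inconsistent with tabulated LCSF values from the same model family
(a 40 % palmitic profile alone would put LCSF above 24, versus tabulated
values under 17); the ``table_consistent`` set uses 0.1 for C16:0 and is the
default. Every report records which set produced it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .fame import FameProfile, FattyAcid, class_totals, parse_shorthand

__all__ = [
    "methyl_ester_mass",
    "cetane_number",
    "degree_of_unsaturation",
    "saponification_value",
    "iodine_value",
    "lcsf",
    "cfpp",
    "FuelProperties",
    "estimate_fuel_properties",
    "fuel_property_table",
    "StandardSpec",
    "builtin_standards",
    "load_standards",
    "evaluate_standards",
    "LCSF_COEFFICIENT_SETS",
]


def methyl_ester_mass(fa: FattyAcid) -> float:
    """Molecular mass (g mol-1) of the methyl ester of ``fa``.

    The ester adds one carbon: C_{n+1} H_{2(n+1)-2d} O2, evaluated with
    atomic masses C 12.011, H 1.008, O 15.999.
    """
    return fa.methyl_ester_mass


# CN model terms keyed by (carbons, double_bonds); C18:3 aggregates all
# trienoic C18 isomers (n3, n6, ...) since the shorthand suffix does not
# change the term.
_CN_INTERCEPT = 55.87
_CN_COEFFS: Mapping[tuple[int, int], float] = {
    (12, 0): 0.0747,
    (14, 0): 0.098,
    (16, 0): 0.164,
    (18, 0): 0.176,
    (16, 1): -0.050,
    (18, 1): 0.001,
    (18, 2): -0.140,
    (18, 3): -0.273,
}


def cetane_number(profile: FameProfile) -> float:
    """Eight-term linear cetane-number estimate.

    Species outside the model's eight named terms contribute zero; the model
    is applied exactly as published, not extended.
    """
    cn = _CN_INTERCEPT
    for name, pct in profile.composition.items():
        fa = parse_shorthand(name)
        cn += _CN_COEFFS.get((fa.carbons, fa.double_bonds), 0.0) * pct
    return cn


def degree_of_unsaturation(profile: FameProfile) -> float:
    """DU = MUFA + 2 x (dienes) + 3 x (trienes), in composition-percent units."""
    du = 0.0
    for name, pct in profile.composition.items():
        d = parse_shorthand(name).double_bonds
        if d == 1:
            du += pct
        elif d == 2:
            du += 2.0 * pct
        elif d == 3:
            du += 3.0 * pct
    return du


def saponification_value(profile: FameProfile) -> float:
    """SV (mg KOH g-1) = sum over species of 560 * N / M."""
    return sum(
        560.0 * pct / parse_shorthand(name).methyl_ester_mass
        for name, pct in profile.composition.items()
    )


def iodine_value(profile: FameProfile) -> float:
    """IV (g I2 per 100 g) = sum over species of 254 * D * N / M."""
    return sum(
        254.0 * parse_shorthand(name).double_bonds * pct
        / parse_shorthand(name).methyl_ester_mass
        for name, pct in profile.composition.items()
    )


LCSF_COEFFICIENT_SETS: Mapping[str, Mapping[int, float]] = {
    # Published form: 0.6 x C16:0 + 0.5 x C18:0 + 1 x C20:0 + 1.5 x C22:0 + 2 x C24:0
    "as_printed": {16: 0.6, 18: 0.5, 20: 1.0, 22: 1.5, 24: 2.0},
    # C16 weight 0.1, the value consistent with tabulated LCSF magnitudes.
    "table_consistent": {16: 0.1, 18: 0.5, 20: 1.0, 22: 1.5, 24: 2.0},
}


def lcsf(profile: FameProfile, coefficient_set: str = "table_consistent") -> float:
    """Long-chain saturation factor over the saturated C16..C24 species."""
    try:
        coeffs = LCSF_COEFFICIENT_SETS[coefficient_set]
    except KeyError:
        raise ValueError(
            f"unknown LCSF coefficient set {coefficient_set!r}; "
            f"choose from {sorted(LCSF_COEFFICIENT_SETS)}"
        ) from None
    total = 0.0
    for name, pct in profile.composition.items():
        fa = parse_shorthand(name)
        if fa.double_bonds == 0 and fa.carbons in coeffs:
            total += coeffs[fa.carbons] * pct
    return total


def cfpp(lcsf_value: float) -> float:
    """Cold filter plugging point (degC) = 3.1417 * LCSF - 16.477."""
    return 3.1417 * lcsf_value - 16.477


@dataclass(frozen=True)
class FuelProperties:
    """The six estimated biodiesel properties for one FAME profile."""

    cn: float
    du: float
    sv: float
    iv: float
    lcsf: float
    cfpp: float
    lcsf_coefficient_set: str = "table_consistent"

    def rounded(self, ndigits: int = 1) -> "FuelProperties":
        """Copy rounded half-up to reporting precision (one decimal)."""

        def _round(x: float) -> float:
            import decimal

            q = decimal.Decimal(10) ** -ndigits
            return float(
                decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
            )

        return FuelProperties(
            cn=_round(self.cn),
            du=_round(self.du),
            sv=_round(self.sv),
            iv=_round(self.iv),
            lcsf=_round(self.lcsf),
            cfpp=_round(self.cfpp),
            lcsf_coefficient_set=self.lcsf_coefficient_set,
        )


def estimate_fuel_properties(
    profile: FameProfile, coefficient_set: str = "table_consistent"
) -> FuelProperties:
    """All six properties from one profile (full profile, no minor filter)."""
    lc = lcsf(profile, coefficient_set)
    return FuelProperties(
        cn=cetane_number(profile),
        du=degree_of_unsaturation(profile),
        sv=saponification_value(profile),
        iv=iodine_value(profile),
        lcsf=lc,
        cfpp=cfpp(lc),
        lcsf_coefficient_set=coefficient_set,
    )


def fuel_property_table(
    profiles: Iterable[FameProfile], coefficient_set: str = "table_consistent"
):
    """Per-replicate fuel-property frame (one row per treatment/day/replicate)."""
    import pandas as pd

    rows = []
    for p in profiles:
        fp = estimate_fuel_properties(p, coefficient_set)
        rows.append(
            {
                "treatment": p.treatment,
                "day": p.day,
                "replicate": p.replicate,
                "du": fp.du,
                "lcsf": fp.lcsf,
                "cn": fp.cn,
                "sv": fp.sv,
                "iv": fp.iv,
                "cfpp": fp.cfpp,
                "lcsf_coefficient_set": coefficient_set,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standards registry


@dataclass(frozen=True)
class StandardSpec:
    """One national/regional biodiesel specification (CN and CFPP limits)."""

    code: str
    region: str
    cn_min: float
    cfpp_min: float | None = None
    cfpp_max: float | None = None

    def __post_init__(self) -> None:
        if self.cn_min <= 0:
            raise ValueError("cn_min must be positive")
        if (
            self.cfpp_min is not None
            and self.cfpp_max is not None
            and self.cfpp_min > self.cfpp_max
        ):
            raise ValueError("cfpp_min must not exceed cfpp_max")


def _specs_from_yaml(text: str) -> list[StandardSpec]:
    raw = yaml.safe_load(text)
    return [
        StandardSpec(
            code=entry["code"],
            region=entry["region"],
            cn_min=float(entry["cn_min"]),
            cfpp_min=None if entry.get("cfpp_min") is None else float(entry["cfpp_min"]),
            cfpp_max=None if entry.get("cfpp_max") is None else float(entry["cfpp_max"]),
        )
        for entry in raw["standards"]
    ]


def builtin_standards() -> list[StandardSpec]:
    """The built-in registry: EN 14214, ASTM D6751, RANP/2008, SIRIM MS 123."""
    text = resources.files("algafame.data").joinpath("standards.yaml").read_text()
    return _specs_from_yaml(text)


def load_standards(path) -> list[StandardSpec]:
    """Load a user-supplied YAML registry (same schema as the built-in one)."""
    with open(path) as fh:
        return _specs_from_yaml(fh.read())


def evaluate_standards(
    props: FuelProperties, specs: Iterable[StandardSpec] | None = None
):
    """Per-specification pass/fail on CN and CFPP plus an overall verdict.

    CN passes when cn >= cn_min; CFPP passes when it lies inside
    [cfpp_min, cfpp_max], with an absent bound unconstrained. Returns a
    DataFrame with one row per spec and an ``overall_pass`` attribute in
    ``.attrs``.
    """
    import pandas as pd

    if specs is None:
        specs = builtin_standards()
    rows = []
    for spec in specs:
        cn_ok = props.cn >= spec.cn_min
        cfpp_ok = True
        if spec.cfpp_min is not None and props.cfpp < spec.cfpp_min:
            cfpp_ok = False
        if spec.cfpp_max is not None and props.cfpp > spec.cfpp_max:
            cfpp_ok = False
        rows.append(
            {
                "code": spec.code,
                "region": spec.region,
                "cn": props.cn,
                "cn_min": spec.cn_min,
                "cn_pass": cn_ok,
                "cfpp": props.cfpp,
                "cfpp_min": spec.cfpp_min,
                "cfpp_max": spec.cfpp_max,
                "cfpp_pass": cfpp_ok,
                "passes": cn_ok and cfpp_ok,
                "lcsf_coefficient_set": props.lcsf_coefficient_set,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["overall_pass"] = bool(report["passes"].all())
    return report
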