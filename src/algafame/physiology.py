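"""Culture physiology: cell density, chlorophyll, biomass and oil productivity.

Converts raw batch-culture measurements (optical densities, dry biomass,
gravimetric oil) into the derived time series used to characterise
nitrate-starved (NS) versus nitrate-replete (NR) microalgal cultures:

* cell density from OD at 681 nm through a linear calibration,
* chlorophyll a/b from the two-wavelength methanol-extract equations
  (665.2 nm and 652.4 nm),
* biomass productivity as a finite-difference rate (g L-1 day-1),
* gravimetric oil content (% of dry weight) and volumetric oil
  productivity (mg L-1 day-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scistats

__all__ = [
    "CalibrationModel",
    "STUDY_CALIBRATION",
    "InvalidCalibrationError",
    "fit_calibration",
    "cell_density",
    "Chlorophyll",
    "chlorophyll",
    "biomass_productivity",
    "oil_content",
    "oil_productivity",
    "read_observations",
    "physiology_points",
    "productivity_series",
]


class InvalidCalibrationError(ValueError):
    """Raised when calibration input cannot support a least-squares line."""


@dataclass(frozen=True)
class CalibrationModel:
    """Linear OD -> cell density calibration.

    slope is in 10^8 cells mL-1 per OD unit, intercept in 10^8 cells mL-1.
    ``r_squared`` is present for fitted models and ``None`` for a fixed
    published model.
    """

    slope: float
    intercept: float
    wavelength_nm: float = 681.0
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


#: The study's fixed calibration at 681 nm: density = 4.7151 * OD - 0.0605.
STUDY_CALIBRATION = CalibrationModel(slope=4.7151, intercept=-0.0605)


def fit_calibration(
    pairs: Sequence[tuple[float, float]], wavelength_nm: float = 681.0
) -> CalibrationModel:
    """Fit an OLS line through (OD, cell density) pairs.

    Density values are expected in 10^8 cells mL-1 (divide raw counts per mL
    by 1e8 before fitting). At least three pairs with non-constant OD are
    required.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise InvalidCalibrationError(
            f"need at least 3 calibration pairs, got {len(pairs)}"
        )
    od = np.asarray([p[0] for p in pairs], dtype=float)
    dens = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(od) == 0:
        raise InvalidCalibrationError("OD values have zero variance")
    res = _scistats.linregress(od, dens)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        wavelength_nm=wavelength_nm,
        r_squared=float(res.rvalue**2),
    )


def cell_density(od: float, model: CalibrationModel = STUDY_CALIBRATION) -> float:
    """Cell density (10^8 cells mL-1) from OD at the calibration wavelength.

    Predictions below zero (OD under the calibration root) are clamped to 0
    with a warning rather than reported as negative counts.
    """
    if od < 0:
        raise ValueError(f"optical density must be non-negative, got {od}")
    raw = model.slope * od + model.intercept
    if raw < 0:
        warnings.warn(
            f"OD {od:.4f} predicts negative cell density ({raw:.4g}); clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return raw


class Chlorophyll(NamedTuple):
    chl_a: float
    chl_b: float
    total: float


def chlorophyll(od_665_2: float, od_652_4: float) -> Chlorophyll:
    """Chlorophyll a, b and total (ug mL-1) from methanol-extract ODs.

    Ca = 16.72*OD665.2 - 9.16*OD652.4 and Cb = 34.09*OD652.4 - 15.28*OD665.2.
    Negative components are reported as-is with a warning: they indicate a
    problem with the extract, and clamping would hide it.
    """
    if od_665_2 < 0 or od_652_4 < 0:
        raise ValueError("optical densities must be non-negative")
    chl_a = 16.72 * od_665_2 - 9.16 * od_652_4
    chl_b = 34.09 * od_652_4 - 15.28 * od_665_2
    if chl_a < 0 or chl_b < 0:
        warnings.warn(
            f"negative chlorophyll component (a={chl_a:.4g}, b={chl_b:.4g}); "
            "check the methanol extract",
            stacklevel=2,
        )
    return Chlorophyll(chl_a, chl_b, chl_a + chl_b)


def biomass_productivity(b1: float, b2: float, t1: float, t2: float) -> float:
    """Volumetric biomass productivity (g L-1 day-1) = (B2 - B1) / (T2 - T1).

    Negative rates are meaningful (biomass declines during early stress
    exposure) and are returned as-is.
    """
    if t2 <= t1:
        raise ValueError(f"interval must have t2 > t1, got ({t1}, {t2})")
    return (b2 - b1) / (t2 - t1)


def oil_content(oil_mass: float, dry_mass: float) -> float:
    """Gravimetric oil content as % of dry cell weight."""
    if dry_mass <= 0:
        raise ValueError(f"dry mass must be positive, got {dry_mass}")
    if oil_mass < 0 or oil_mass > dry_mass:
        raise ValueError(
            f"oil mass must lie in [0, dry mass]; got {oil_mass} vs {dry_mass}"
        )
    return 100.0 * oil_mass / dry_mass


def oil_productivity(bp: float, oil_content_pct: float) -> float:
    """Oil productivity (mg L-1 day-1) = BP * (oil content % / 100) * 1000.

    The percentage is applied as a fraction so units close
    (g L-1 day-1 -> mg L-1 day-1); the sign follows the biomass productivity.
    """
    if not 0.0 <= oil_content_pct <= 100.0:
        raise ValueError(f"oil content must be in [0, 100] %, got {oil_content_pct}")
    return bp * (oil_content_pct / 100.0) * 1000.0


# ---------------------------------------------------------------------------
# Table-level processing

OBSERVATION_COLUMNS = [
    "treatment",
    "day",
    "replicate",
    "od_681",
    "od_665_2",
    "od_652_4",
    "dry_biomass_g_per_L",
    "oil_mass_g",
    "dry_mass_extracted_g",
]


def read_observations(path) -> pd.DataFrame:
    """Read a culture observation table (CSV or TSV, sniffed by header)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in OBSERVATION_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    for opt in OBSERVATION_COLUMNS[7:]:
        if opt not in df.columns:
            df[opt] = np.nan
    return df[OBSERVATION_COLUMNS].copy()


def physiology_points(
    observations: pd.DataFrame, model: CalibrationModel = STUDY_CALIBRATION
) -> pd.DataFrame:
    """Per-replicate derived physiology at each (treatment, day).

    Returns a tidy frame with cell_density (10^8 cells mL-1), chl_a / chl_b /
    chl_total (ug mL-1), dry biomass carried through, and oil_content (% DW)
    where the gravimetric columns are present.
    """
    rows = []
    for rec in observations.itertuples(index=False):
        chl = chlorophyll(rec.od_665_2, rec.od_652_4)
        oc = np.nan
        if np.isfinite(rec.oil_mass_g) and np.isfinite(rec.dry_mass_extracted_g):
            oc = oil_content(rec.oil_mass_g, rec.dry_mass_extracted_g)
        rows.append(
            {
                "treatment": rec.treatment,
                "day": int(rec.day),
                "replicate": int(rec.replicate),
                "cell_density": cell_density(rec.od_681, model),
                "chl_a": chl.chl_a,
                "chl_b": chl.chl_b,
                "chl_total": chl.total,
                "dry_biomass_g_per_L": rec.dry_biomass_g_per_L,
                "oil_content": oc,
            }
        )
    return pd.DataFrame(rows)


def productivity_series(
    observations: pd.DataFrame,
    baseline_day: int | None = 0,
    aggregate: str = "replicate",
) -> pd.DataFrame:
    """Biomass and oil productivities per treatment and interval.

    ``baseline_day=0`` (default) computes every rate against the fixed
    pre-treatment baseline, which is what produces the characteristic
    negative early-exposure productivities; ``baseline_day=None`` uses
    consecutive sampling intervals instead.

    ``aggregate`` picks whether rates are computed per replicate flask and
    then averaged ("replicate", default) or from the replicate-mean biomass
    ("mean").
    """
    if aggregate not in ("replicate", "mean"):
        raise ValueError(f"aggregate must be 'replicate' or 'mean', got {aggregate!r}")
    obs = observations.copy()
    obs["oil_content_pct"] = np.where(
        np.isfinite(obs["oil_mass_g"]) & np.isfinite(obs["dry_mass_extracted_g"]),
        100.0 * obs["oil_mass_g"] / obs["dry_mass_extracted_g"],
        np.nan,
    )
    group_cols = ["treatment", "day"] if aggregate == "mean" else [
        "treatment",
        "replicate",
        "day",
    ]
    series = (
        obs.groupby(group_cols, sort=True)[["dry_biomass_g_per_L", "oil_content_pct"]]
        .mean()
        .reset_index()
    )

    def _intervals(days: list[int]) -> list[tuple[int, int]]:
        days = sorted(days)
        if baseline_day is not None:
            if baseline_day not in days:
                raise ValueError(f"baseline day {baseline_day} not in sampled days {days}")
            return [(baseline_day, d) for d in days if d > baseline_day]
        return list(zip(days[:-1], days[1:]))

    rows = []
    key_cols = group_cols[:-1]  # all but "day"
    for key, sub in series.groupby(key_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        by_day = sub.set_index("day")
        for t1, t2 in _intervals(list(by_day.index)):
            bp = biomass_productivity(
                by_day.at[t1, "dry_biomass_g_per_L"],
                by_day.at[t2, "dry_biomass_g_per_L"],
                t1,
                t2,
            )
            oc = by_day.at[t2, "oil_content_pct"]
            op = oil_productivity(bp, oc) if np.isfinite(oc) else np.nan
            rows.append(
                dict(
                    zip(key_cols, key),
                    t1=t1,
                    t2=t2,
                    biomass_productivity=bp,
                    oil_productivity=op,
                )
            )
    out = pd.DataFrame(rows)
    if aggregate == "replicate":
        out = (
            out.groupby(["treatment", "t1", "t2"], sort=True)[
                ["biomass_productivity", "oil_productivity"]
            ]
            .mean()
            .reset_index()
        )
    return out
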