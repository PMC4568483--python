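"""Contraction-rate endpoint: OLS slope of area vs time over the initial window.

The cytotoxic endpoint of the assay is the rate of spheroid size change over
the first 150 min after compound addition, estimated by an ordinary
least-squares line through the per-well (time, projected area) points and
reported with contraction positive: ``rate = -slope``, so a toxicant that
stops contraction drives the endpoint toward 0. Rates are then normalized to
the mean of the matching vehicle-control wells, separately per solvent group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataError, InsufficientDataError, NormalizationError
from .plate_io import PlateLayout
from .segmentation import QC_LOW_CONTRAST, QC_NO_OBJECT

DEFAULT_WINDOW_MIN = 150.0

#: QC flags whose points are dropped before fitting, under default filtering.
DEFAULT_EXCLUDE_FLAGS = frozenset({QC_NO_OBJECT, QC_LOW_CONTRAST})

RATE_COLUMNS = [
    "well",
    "compound",
    "concentration_uM",
    "role",
    "solvent",
    "rate",
    "normalized_rate",
    "n_points",
    "r_squared",
    "window_min",
]


@dataclass(frozen=True)
class FilterConfig:
    """Which QC-flagged measurement points to exclude from time series."""

    exclude_flags: frozenset[str] = DEFAULT_EXCLUDE_FLAGS
    normalize_to_initial: bool = False  # divide each series by its first area


@dataclass(frozen=True)
class TimeSeries:
    """One well's (time, area) series, times strictly increasing."""

    well: str
    times_min: np.ndarray
    areas_mm2: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        a = np.asarray(self.areas_mm2, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise DataError(f"well {self.well}: times and areas must be aligned 1D arrays")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise DataError(f"well {self.well}: duplicate or decreasing time points")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "areas_mm2", a)

    def __len__(self) -> int:
        return len(self.times_min)


@dataclass(frozen=True)
class ContractionRate:
    """The endpoint of one well: negated OLS area slope over the window."""

    well: str
    window_min: float
    slope: float  # signed OLS slope, mm^2/min (negative while contracting)
    rate: float  # -slope: contraction positive
    n_points: int
    r_squared: float
    normalized_rate: float | None = None  # rate / mean vehicle rate, same solvent


def build_timeseries(
    measurements: pd.DataFrame,
    well: str,
    filter_cfg: FilterConfig | None = None,
) -> TimeSeries:
    """Extract one well's QC-filtered time series from a measurement table."""
    if filter_cfg is None:
        filter_cfg = FilterConfig()
    sub = measurements[measurements["well"] == well]
    if sub.empty:
        raise DataError(f"no measurements for well {well}")
    if sub["time_min"].duplicated().any():
        t = float(sub["time_min"][sub["time_min"].duplicated()].iloc[0])
        raise DataError(f"well {well}: duplicate measurement at t = {t} min")
    flags = sub["qc_flags"].fillna("").map(lambda s: set(s.split(";")) if s else set())
    keep = ~flags.map(lambda f: bool(f & filter_cfg.exclude_flags))
    sub = sub[keep].sort_values("time_min")
    times = sub["time_min"].to_numpy(dtype=float)
    areas = sub["area_mm2"].to_numpy(dtype=float)
    if filter_cfg.normalize_to_initial and len(areas) and areas[0] > 0:
        areas = areas / areas[0]
    return TimeSeries(well=well, times_min=times, areas_mm2=areas)


def ols_slope(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS slope and R^2 of values on times.

    ``slope = sum((t - tbar)(y - ybar)) / sum((t - tbar)^2)``; for a constant
    series (zero value variance) R^2 is reported as 0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    tc = t - t.mean()
    yc = y - y.mean()
    stt = float(np.dot(tc, tc))
    if stt == 0:
        raise InsufficientDataError("all time points identical")
    slope = float(np.dot(tc, yc) / stt)
    syy = float(np.dot(yc, yc))
    r2 = 0.0 if syy == 0 else slope * slope * stt / syy
    return slope, r2


def contraction_rate(
    ts: TimeSeries, window_min: float = DEFAULT_WINDOW_MIN
) -> ContractionRate:
    """Endpoint of one well: OLS fit on points with time <= window (inclusive)."""
    if window_min <= 0:
        raise DataError("window_min must be > 0")
    mask = ts.times_min <= window_min + 1e-9
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(
            f"well {ts.well}: only {n} usable points within {window_min} min (need >= 3)"
        )
    slope, r2 = ols_slope(ts.times_min[mask], ts.areas_mm2[mask])
    return ContractionRate(
        well=ts.well,
        window_min=window_min,
        slope=slope,
        rate=-slope,
        n_points=n,
        r_squared=r2,
    )


def normalize_rates(
    rates: list[ContractionRate], layout: PlateLayout
) -> list[ContractionRate]:
    """Fill ``normalized_rate`` = rate / mean vehicle rate, per solvent group.

    Treatment wells are matched to the vehicle wells sharing their solvent
    annotation (all wells form a single group when the layout carries no
    solvent column). Raises :class:`NormalizationError` when a group has no
    vehicle rates or their mean is not positive.
    """
    by_well = {r.well: r for r in rates}
    specs = {w.name: w for w in layout.wells}
    for r in rates:
        if r.well not in specs:
            raise NormalizationError(f"rate for well {r.well} not in layout")

    solvents = {specs[r.well].solvent for r in rates}
    out: list[ContractionRate] = []
    for r in rates:
        spec = specs[r.well]
        group_solvent = spec.solvent
        veh = [
            by_well[w.name].rate
            for w in layout.vehicle_wells(group_solvent)
            if w.name in by_well
        ]
        if not veh and group_solvent is not None:
            # solvent-annotated treatment but un-annotated vehicles: fall back
            veh = [by_well[w.name].rate for w in layout.vehicle_wells() if w.name in by_well]
        if not veh:
            raise NormalizationError(
                f"well {r.well}: no vehicle wells with rates for solvent {group_solvent!r}"
            )
        mean_veh = float(np.mean(veh))
        if mean_veh <= 0:
            raise NormalizationError(
                f"solvent {group_solvent!r}: mean vehicle rate {mean_veh:.3g} <= 0 (assay failed)"
            )
        out.append(replace(r, normalized_rate=r.rate / mean_veh))
    return out


def rates_table(
    measurements: pd.DataFrame,
    layout: PlateLayout,
    window_min: float = DEFAULT_WINDOW_MIN,
    filter_cfg: FilterConfig | None = None,
) -> pd.DataFrame:
    """Endpoint table for a whole plate: one row per measurable non-empty well.

    Wells with too few usable points inside the window are skipped (they are
    reported by the CLI as warnings, never as exceptions).
    """
    rates: list[ContractionRate] = []
    skipped: list[str] = []
    for well in sorted(layout.non_empty_wells(), key=lambda w: (w.row, w.col)):
        if not (measurements["well"] == well.name).any():
            skipped.append(well.name)
            continue
        ts = build_timeseries(measurements, well.name, filter_cfg)
        try:
            rates.append(contraction_rate(ts, window_min))
        except InsufficientDataError:
            skipped.append(well.name)
    rates = normalize_rates(rates, layout)
    rows = []
    for r in rates:
        spec = layout.well(r.well)
        rows.append(
            {
                "well": r.well,
                "compound": spec.compound or "",
                "concentration_uM": spec.concentration_um,
                "role": spec.role,
                "solvent": spec.solvent or "",
                "rate": r.rate,
                "normalized_rate": r.normalized_rate,
                "n_points": r.n_points,
                "r_squared": r.r_squared,
                "window_min": r.window_min,
            }
        )
    df = pd.DataFrame(rows, columns=RATE_COLUMNS)
    df.attrs["skipped_wells"] = skipped
    return df
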