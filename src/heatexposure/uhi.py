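"""Urban heat island intensity (UHII) from temperature vs. urban fraction.

The working definition: regress the per-cell period-mean 2-m temperature on
the per-cell urban fraction over all non-water cells,

    T = URB_FRC * UHII + T(vegetation)

so the slope is the UHII (degC per unit urban fraction) and the intercept
is the baseline temperature of zero-fraction vegetated land. Open-water
cells are always excluded; vegetation cells anchor the zero-fraction end.

Days are partitioned into a daytime window (default 06:00-18:00 local) and
the complementary night window spanning midnight (18:00-06:00); a night is
labelled by the date on which it begins.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .domain import TemperatureCube, UrbanSurfaceGrid, VEGETATION
from .errors import (
    DegenerateDesignError,
    EmptyOutputError,
    ParameterError,
    PlacementError,
    SampleSizeError,
)

logger = logging.getLogger("heatexposure")


@dataclass(frozen=True)
class DiurnalMask:
    """Day/night partition of the 24-hour local clock.

    Daytime is ``[day_start, day_end)``; night is the complement and spans
    midnight.
    """

    day_start: int = 6
    day_end: int = 18

    def __post_init__(self) -> None:
        if not 0 <= self.day_start < self.day_end <= 24:
            raise ParameterError(
                f"require 0 <= day_start < day_end <= 24, got "
                f"[{self.day_start}, {self.day_end})"
            )

    @property
    def n_day_hours(self) -> int:
        return self.day_end - self.day_start

    @property
    def n_night_hours(self) -> int:
        return 24 - self.n_day_hours


@dataclass(frozen=True)
class PeriodMeans:
    """Per-date, per-cell day and night mean temperature grids."""

    day_dates: pd.DatetimeIndex
    day_means: np.ndarray  # (n_day_dates, y, x)
    night_dates: pd.DatetimeIndex
    night_means: np.ndarray  # (n_night_dates, y, x)

    def grids(self, period: str) -> tuple[pd.DatetimeIndex, np.ndarray]:
        if period == "day":
            return self.day_dates, self.day_means
        if period == "night":
            return self.night_dates, self.night_means
        raise ParameterError(f"period must be 'day' or 'night', got {period!r}")


@dataclass(frozen=True)
class UHIIEstimate:
    """One ordinary-least-squares fit of temperature on urban fraction."""

    date: pd.Timestamp
    period: str
    slope: float
    intercept: float
    r_value: float
    p_value: float
    stderr: float
    n_cells: int

    def ci95(self) -> tuple[float, float]:
        """Two-sided 95% confidence interval for the slope."""
        half = stats.t.ppf(0.975, self.n_cells - 2) * self.stderr
        return self.slope - half, self.slope + half


def _window_labels(
    timestamps: pd.DatetimeIndex, mask: DiurnalMask
) -> tuple[np.ndarray, np.ndarray]:
    """Return (is_day, window_date) per timestamp.

    Night hours before ``day_start`` belong to the night that began the
    previous evening, so they are labelled with the previous date.
    """
    hours = timestamps.hour.to_numpy()
    is_day = (hours >= mask.day_start) & (hours < mask.day_end)
    dates = timestamps.normalize().to_numpy()
    window_date = dates.copy()
    early_night = hours < mask.day_start
    window_date[early_night] -= np.timedelta64(1, "D")
    return is_day, window_date


def period_means(cube: TemperatureCube, mask: DiurnalMask = DiurnalMask()) -> PeriodMeans:
    """Mean temperature grid per (date, period), complete windows only.

    A day window must contain all ``day_end - day_start`` hours and a night
    window all remaining hours of the 24-hour cycle; incomplete leading or
    trailing windows are dropped with a logged count.
    """
    is_day, window_date = _window_labels(cube.timestamps, mask)
    out: dict[str, tuple[pd.DatetimeIndex, np.ndarray]] = {}
    n_dropped = 0
    for period, sel, required in (
        ("day", is_day, mask.n_day_hours),
        ("night", ~is_day, mask.n_night_hours),
    ):
        dates_sel = window_date[sel]
        values_sel = cube.values[sel]
        uniq, inverse, counts = np.unique(
            dates_sel, return_inverse=True, return_counts=True
        )
        complete = counts == required
        n_dropped += int((~complete).sum())
        sums = np.zeros((len(uniq),) + cube.grid.shape)
        np.add.at(sums, inverse, values_sel)
        means = sums[complete] / required
        out[period] = (pd.DatetimeIndex(uniq[complete]), means)
    if n_dropped:
        logger.info("period_means: dropped %d incomplete windows", n_dropped)
    if len(out["day"][0]) == 0 and len(out["night"][0]) == 0:
        raise EmptyOutputError("cube contains no complete day or night window")
    return PeriodMeans(
        day_dates=out["day"][0],
        day_means=out["day"][1],
        night_dates=out["night"][0],
        night_means=out["night"][1],
    )


def fit_uhii(
    mean_grid: np.ndarray,
    surface: UrbanSurfaceGrid,
    date: pd.Timestamp | None = None,
    period: str = "",
) -> UHIIEstimate:
    """OLS fit of a per-cell temperature grid on urban fraction.

    Uses every vegetation and urban cell; open-water cells are excluded, as
    are cells masked NaN in the grid. Requires >= 3 usable cells with >= 2
    distinct urban fractions.
    """
    mean_grid = np.asarray(mean_grid, dtype=float)
    if mean_grid.shape != surface.shape:
        raise ParameterError(
            f"grid shape {mean_grid.shape} does not match surface {surface.shape}"
        )
    usable = surface.land_mask & ~np.isnan(mean_grid)
    x = surface.urban_fraction[usable]
    y = mean_grid[usable]
    if x.size < 3:
        raise SampleSizeError(f"only {x.size} usable land cells (need >= 3)")
    if np.unique(x).size < 2:
        raise DegenerateDesignError(
            "all usable cells share one urban fraction; the UHII slope is "
            "unidentifiable"
        )
    fit = stats.linregress(x, y)
    return UHIIEstimate(
        date=date,
        period=period,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
        n_cells=int(x.size),
    )


def daily_uhii_series(
    cube: TemperatureCube,
    surface: UrbanSurfaceGrid | None = None,
    mask: DiurnalMask = DiurnalMask(),
    period: str = "night",
    pooled: bool = False,
) -> list[UHIIEstimate]:
    """One UHII estimate per complete date, in date order.

    By default each fit uses the per-cell period-mean grid (one point per
    cell); with ``pooled=True`` all hourly values in the window are pooled
    (one point per cell-hour). A date whose fit fails raises, naming the
    date — failures are reported, never silently skipped.
    """
    surface = surface if surface is not None else cube.grid
    if not pooled:
        pm = period_means(cube, mask)
        dates, grids = pm.grids(period)
        out = []
        for date, grid in zip(dates, grids):
            try:
                out.append(fit_uhii(grid, surface, date=date, period=period))
            except (SampleSizeError, DegenerateDesignError) as exc:
                raise type(exc)(f"{date.date()} ({period}): {exc}") from exc
        return out
    # pooled mode: regress every hourly value in the window on its cell's fraction
    is_day, window_date = _window_labels(cube.timestamps, mask)
    sel_period = is_day if period == "day" else ~is_day
    required = mask.n_day_hours if period == "day" else mask.n_night_hours
    dates_sel = window_date[sel_period]
    uniq, counts = np.unique(dates_sel, return_counts=True)
    out = []
    usable = surface.land_mask
    for date in uniq[counts == required]:
        hours_sel = sel_period & (window_date == date)
        block = cube.values[hours_sel][:, usable]  # (hours, cells)
        x = np.tile(surface.urban_fraction[usable], block.shape[0])
        y = block.ravel()
        fit = stats.linregress(x, y)
        out.append(
            UHIIEstimate(
                date=pd.Timestamp(date),
                period=period,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_value=float(fit.rvalue),
                p_value=float(fit.pvalue),
                stderr=float(fit.stderr),
                n_cells=int(y.size),
            )
        )
    return out


def uhii_table(estimates: list[UHIIEstimate]) -> pd.DataFrame:
    """Daily UHII estimates as a tidy table."""
    return pd.DataFrame(
        {
            "date": [e.date.date() if e.date is not None else None for e in estimates],
            "period": [e.period for e in estimates],
            "slope": [e.slope for e in estimates],
            "intercept": [e.intercept for e in estimates],
            "r": [e.r_value for e in estimates],
            "p": [e.p_value for e in estimates],
            "n_cells": [e.n_cells for e in estimates],
        }
    )


def bresenham_path(
    start: tuple[int, int], end: tuple[int, int]
) -> list[tuple[int, int]]:
    """8-connected discrete line from start to end (inclusive)."""
    r0, c0 = start
    r1, c1 = end
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    path = []
    r, c = r0, c0
    while True:
        path.append((r, c))
        if (r, c) == (r1, c1):
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return path


@dataclass(frozen=True)
class CrossSection:
    """Period-mean temperature along an urban-to-rural transect.

    ``tu`` is the mean over positions with urban fraction >= the urban
    threshold, ``tr`` the mean over zero-fraction vegetation positions, and
    ``delta_t = tu - tr``; any of the three is None when the transect lacks
    the corresponding positions.
    """

    name: str
    period: str
    rows: np.ndarray
    cols: np.ndarray
    urban_fraction: np.ndarray
    temperature: np.ndarray
    tu: float | None
    tr: float | None
    delta_t: float | None


def extract_cross_section(
    cube: TemperatureCube,
    surface: UrbanSurfaceGrid,
    start: tuple[int, int],
    end: tuple[int, int],
    mask: DiurnalMask = DiurnalMask(),
    date_sets: dict[str, list] | None = None,
    urban_threshold: float = 0.5,
) -> list[CrossSection]:
    """Transect temperatures per named date set and period.

    Traverses the discrete line from ``start`` to ``end``, averages each
    position's day and night means over every named date set (default: one
    set named 'all' containing every complete date), and summarises the
    urban (``tu``) and rural (``tr``) ends.
    """
    for pt in (start, end):
        r, c = pt
        if not (0 <= r < surface.n_y and 0 <= c < surface.n_x):
            raise PlacementError(f"endpoint {pt} outside the grid")
        if not surface.land_mask[r, c]:
            raise PlacementError(f"endpoint {pt} is on open water")
    path = bresenham_path(start, end)
    rows = np.array([p[0] for p in path])
    cols = np.array([p[1] for p in path])
    classes = surface.land_class[rows, cols]
    if np.unique(classes).size < 2:
        logger.warning("cross-section lies entirely within one land class")
    frac = surface.urban_fraction[rows, cols]

    pm = period_means(cube, mask)
    if date_sets is None:
        date_sets = {"all": None}
    out = []
    for name, dates in date_sets.items():
        for period in ("day", "night"):
            all_dates, grids = pm.grids(period)
            if dates is None:
                keep = np.ones(len(all_dates), dtype=bool)
            else:
                wanted = pd.DatetimeIndex(dates)
                keep = all_dates.isin(wanted)
                if keep.sum() < len(wanted):
                    missing = wanted.difference(all_dates[keep])
                    raise ParameterError(
                        f"date set {name!r}: dates {list(missing.date)} have no "
                        f"complete {period} window"
                    )
            temp = grids[keep][:, rows, cols].mean(axis=0)
            urban_sel = frac >= urban_threshold
            rural_sel = (frac == 0.0) & (classes == VEGETATION)
            tu = float(temp[urban_sel].mean()) if urban_sel.any() else None
            tr = float(temp[rural_sel].mean()) if rural_sel.any() else None
            if tu is None or tr is None:
                logger.warning(
                    "cross-section %s/%s: %s positions missing; delta_t undefined",
                    name,
                    period,
                    "urban" if tu is None else "rural",
                )
            out.append(
                CrossSection(
                    name=name,
                    period=period,
                    rows=rows,
                    cols=cols,
                    urban_fraction=frac,
                    temperature=temp,
                    tu=tu,
                    tr=tr,
                    delta_t=(tu - tr) if tu is not None and tr is not None else None,
                )
            )
    return out


def cross_section_table(sections: list[CrossSection]) -> pd.DataFrame:
    """Long-format transect table: one row per (section, period, position)."""
    frames = []
    for cs in sections:
        frames.append(
            pd.DataFrame(
                {
                    "date_set": cs.name,
                    "period": cs.period,
                    "position": np.arange(len(cs.rows)),
                    "row": cs.rows,
                    "col": cs.cols,
                    "urban_fraction": cs.urban_fraction,
                    "temperature": cs.temperature,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
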