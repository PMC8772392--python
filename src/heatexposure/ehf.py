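"""Excess Heat Factor (EHF) heat-stress mapping per grid cell.

The EHF combines two excess-heat indices computed from daily temperature
statistics (each of Tmax, Tmin, Tmean defines a variant of the map):

* significance index     EHI_sig  = T3 - T95   (degC)
* acclimatisation index  EHI_accl = T3 - T30   (degC)
* excess heat factor     EHF = EHI_sig * max(1, EHI_accl)   (degC^2)

T3 is the mean over an explicit set of consecutive event days (for the
2012 Chicago episode, July 4-6), T30 the mean over the 30 days preceding
the event, and T95 the 95th percentile of the daily statistic over a
multi-year baseline climatology. A cell is classed *high* severity when
EHF exceeds a threshold (default 2 degC^2), *positive* when 0 < EHF <=
threshold, and *none* when EHF <= 0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import TemperatureCube, UrbanSurfaceGrid
from .errors import (
    CoverageError,
    EmptyOutputError,
    ParameterError,
    SampleSizeError,
    SchemaError,
)

logger = logging.getLogger("heatexposure")

VARIANTS = ("tmax", "tmin", "tmean")

#: Severity codes used on disk; -1 marks masked (open-water) cells.
SEVERITY_NONE = 0
SEVERITY_POSITIVE = 1
SEVERITY_HIGH = 2
SEVERITY_MASKED = -1

DEFAULT_HIGH_THRESHOLD = 2.0  # degC^2
MIN_CLIMATOLOGY_SAMPLES = 20


@dataclass(frozen=True)
class DailyStatistics:
    """Per-cell daily Tmax/Tmin/Tmean series over complete local days."""

    dates: pd.DatetimeIndex
    tmax: np.ndarray  # (n_days, y, x)
    tmin: np.ndarray
    tmean: np.ndarray

    def variant(self, name: str) -> np.ndarray:
        if name not in VARIANTS:
            raise ParameterError(f"variant must be one of {VARIANTS}, got {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class ClimatologyBaseline:
    """Per-cell 95th-percentile baseline for one daily-statistic variant."""

    variant: str
    t95: np.ndarray  # (y, x)
    n_days: int
    percentile_method: str
    n_years: int | None = None


@dataclass(frozen=True)
class EHFField:
    """Per-cell excess-heat indices, EHF and severity for one variant."""

    variant: str
    t3: np.ndarray
    t30: np.ndarray
    t95: np.ndarray
    ehi_sig: np.ndarray
    ehi_accl: np.ndarray
    ehf: np.ndarray
    severity: np.ndarray  # int8 codes, -1 on masked cells
    high_threshold: float


def daily_statistics(cube: TemperatureCube) -> DailyStatistics:
    """Reduce an hourly cube to daily Tmax/Tmin/Tmean over complete days.

    A complete local calendar day contributes all 24 hourly values;
    incomplete leading/trailing days are excluded and logged.
    """
    dates = cube.timestamps.normalize()
    uniq, inverse, counts = np.unique(
        dates.to_numpy(), return_inverse=True, return_counts=True
    )
    complete = counts == 24
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("daily_statistics: excluded %d incomplete days", n_dropped)
    if not complete.any():
        raise EmptyOutputError("cube contains no complete 24-hour day")
    keep_days = np.flatnonzero(complete)
    shape = cube.grid.shape
    tmax = np.empty((keep_days.size,) + shape)
    tmin = np.empty_like(tmax)
    tmean = np.empty_like(tmax)
    for out_i, day_i in enumerate(keep_days):
        block = cube.values[inverse == day_i]
        tmax[out_i] = block.max(axis=0)
        tmin[out_i] = block.min(axis=0)
        tmean[out_i] = block.mean(axis=0)
    return DailyStatistics(
        dates=pd.DatetimeIndex(uniq[complete]), tmax=tmax, tmin=tmin, tmean=tmean
    )


def compute_t95(
    climatology: np.ndarray,
    variant: str = "tmean",
    n_years: int | None = None,
    min_samples: int = MIN_CLIMATOLOGY_SAMPLES,
) -> ClimatologyBaseline:
    """Per-cell 95th percentile of a (day, y, x) daily climatology.

    Uses linear interpolation between closest order statistics (the numpy
    'linear' method); the rule is recorded in the result's metadata since
    percentile conventions shift T95 by tenths of a degree. Requires at
    least ``min_samples`` daily values per cell.
    """
    if variant not in VARIANTS:
        raise ParameterError(f"variant must be one of {VARIANTS}, got {variant!r}")
    clim = np.asarray(climatology, dtype=float)
    if clim.ndim != 3:
        raise SchemaError(f"climatology must be (day, y, x), got shape {clim.shape}")
    n_valid = (~np.isnan(clim)).sum(axis=0)
    if (n_valid < min_samples).any():
        r, c = np.argwhere(n_valid < min_samples)[0]
        raise SampleSizeError(
            f"cell ({r}, {c}) has only {n_valid[r, c]} daily values; "
            f"need >= {min_samples} for a stable 95th percentile"
        )
    t95 = np.nanquantile(clim, 0.95, axis=0, method="linear")
    return ClimatologyBaseline(
        variant=variant,
        t95=t95,
        n_days=int(clim.shape[0]),
        percentile_method="linear",
        n_years=n_years,
    )


def rolling_previous_mean(
    daily: DailyStatistics,
    window: int,
    as_of: pd.Timestamp | str,
    variant: str = "tmean",
) -> np.ndarray:
    """Mean over exactly ``window`` consecutive days ending at ``as_of``.

    Every day of the window must be present in the daily series; a missing
    day raises :class:`CoverageError` listing the absent dates — partial
    means are never returned.
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    as_of = pd.Timestamp(as_of).normalize()
    wanted = pd.date_range(end=as_of, periods=window, freq="D")
    return mean_over_dates(daily, list(wanted), variant)


def mean_over_dates(
    daily: DailyStatistics, dates: list, variant: str = "tmean"
) -> np.ndarray:
    """Per-cell mean of a daily statistic over an explicit date list."""
    wanted = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    pos = daily.dates.get_indexer(wanted)
    if (pos < 0).any():
        missing = [str(d.date()) for d in wanted[pos < 0]]
        raise CoverageError(f"daily series is missing required dates: {missing}")
    return daily.variant(variant)[pos].mean(axis=0)


def compute_ehf(
    t3: np.ndarray,
    t30: np.ndarray,
    t95: np.ndarray,
    variant: str = "tmean",
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
    water_mask: np.ndarray | None = None,
) -> EHFField:
    """Combine T3/T30/T95 grids into excess-heat indices and severity.

    Cells under ``water_mask`` (and cells NaN in any input) are masked:
    NaN in the float fields, severity code -1.
    """
    t3, t30, t95 = (np.asarray(a, dtype=float) for a in (t3, t30, t95))
    if not (t3.shape == t30.shape == t95.shape):
        raise SchemaError(
            f"T3 {t3.shape}, T30 {t30.shape} and T95 {t95.shape} grids must be "
            "congruent"
        )
    if water_mask is not None:
        water_mask = np.asarray(water_mask, dtype=bool)
        if water_mask.shape != t3.shape:
            raise SchemaError("water_mask shape does not match the grids")
        t3 = np.where(water_mask, np.nan, t3)
        t30 = np.where(water_mask, np.nan, t30)
        t95 = np.where(water_mask, np.nan, t95)
    ehi_sig = t3 - t95
    ehi_accl = t3 - t30
    ehf = ehi_sig * np.maximum(1.0, ehi_accl)
    severity = classify_severity(ehf, high_threshold)
    return EHFField(
        variant=variant,
        t3=t3,
        t30=t30,
        t95=t95,
        ehi_sig=ehi_sig,
        ehi_accl=ehi_accl,
        ehf=ehf,
        severity=severity,
        high_threshold=high_threshold,
    )


def classify_severity(
    ehf: np.ndarray, high_threshold: float = DEFAULT_HIGH_THRESHOLD
) -> np.ndarray:
    """Severity codes: 0 none (EHF <= 0), 1 positive, 2 high (> threshold).

    Masked (NaN) cells get code -1.
    """
    if high_threshold < 0:
        raise ParameterError("high_threshold must be >= 0")
    ehf = np.asarray(ehf, dtype=float)
    severity = np.full(ehf.shape, SEVERITY_NONE, dtype=np.int8)
    severity[ehf > 0] = SEVERITY_POSITIVE
    severity[ehf > high_threshold] = SEVERITY_HIGH
    severity[np.isnan(ehf)] = SEVERITY_MASKED
    return severity


def ehf_episode_map(
    cube: TemperatureCube,
    climatology: np.ndarray,
    t3_dates: list,
    variant: str = "tmean",
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
    t30_window: int = 30,
    surface: UrbanSurfaceGrid | None = None,
) -> EHFField:
    """Full per-cell EHF map for one episode and one variant.

    Chains the stage operations: daily statistics from the hourly cube, T3
    over the explicit event dates, T30 over the ``t30_window`` days ending
    the day before the event, T95 from the multi-year climatology, then the
    index arithmetic and severity classification. Open-water cells of the
    cube's surface are masked through.
    """
    surface = surface if surface is not None else cube.grid
    if variant not in VARIANTS:
        raise ParameterError(f"variant must be one of {VARIANTS}, got {variant!r}")
    t3_idx = pd.DatetimeIndex(pd.to_datetime(t3_dates)).normalize().sort_values()
    if len(t3_idx) >= 2:
        steps = np.diff(t3_idx.values)
        if not (steps == np.timedelta64(1, "D")).all():
            raise ParameterError(f"t3_dates must be consecutive days, got {list(t3_idx.date)}")
    try:
        daily = daily_statistics(cube)
    except EmptyOutputError as exc:
        raise EmptyOutputError(f"daily_statistics stage: {exc}") from exc
    try:
        t3 = mean_over_dates(daily, list(t3_idx), variant)
        t30 = rolling_previous_mean(
            daily, t30_window, t3_idx[0] - pd.Timedelta(days=1), variant
        )
    except CoverageError as exc:
        raise CoverageError(f"T3/T30 stage: {exc}") from exc
    try:
        baseline = compute_t95(climatology, variant)
    except (SampleSizeError, SchemaError) as exc:
        raise type(exc)(f"T95 stage: {exc}") from exc
    return compute_ehf(
        t3,
        t30,
        baseline.t95,
        variant=variant,
        high_threshold=high_threshold,
        water_mask=surface.water_mask,
    )


def severity_summary(field: EHFField) -> pd.DataFrame:
    """Land-cell counts per severity class for one EHF field."""
    labels = {
        SEVERITY_NONE: "none",
        SEVERITY_POSITIVE: "positive",
        SEVERITY_HIGH: "high",
    }
    rows = []
    land = field.severity != SEVERITY_MASKED
    for code, label in labels.items():
        rows.append(
            {
                "variant": field.variant,
                "severity": label,
                "n_cells": int((field.severity[land] == code).sum()),
            }
        )
    return pd.DataFrame(rows)
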