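"""Core data containers: surface grid, scenario, temperature cube, stations.

The spatial domain is a regular grid of square cells indexed ``(row, col)``
with row 0 at the north edge. Each cell carries a land class and an urban
fraction (the fraction of impervious surface, 0-1). Urban fraction is zero
for open water and vegetation; the three urban classes map to the fixed
fractions 0.50 (low-intensity residential), 0.90 (high-intensity
residential) and 0.95 (industrial/commercial) used in NLCD-style
aggregation.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError

# Integer land-class codes used on disk and in memory.
OPEN_WATER = 0
VEGETATION = 1
LOW_INTENSITY_RESIDENTIAL = 2
HIGH_INTENSITY_RESIDENTIAL = 3
INDUSTRIAL_COMMERCIAL = 4

LAND_CLASS_NAMES = {
    OPEN_WATER: "open_water",
    VEGETATION: "vegetation",
    LOW_INTENSITY_RESIDENTIAL: "low_intensity_residential",
    HIGH_INTENSITY_RESIDENTIAL: "high_intensity_residential",
    INDUSTRIAL_COMMERCIAL: "industrial_commercial",
}

#: Urban fraction assigned to each land class in categorical mode.
CLASS_URBAN_FRACTION = {
    OPEN_WATER: 0.0,
    VEGETATION: 0.0,
    LOW_INTENSITY_RESIDENTIAL: 0.50,
    HIGH_INTENSITY_RESIDENTIAL: 0.90,
    INDUSTRIAL_COMMERCIAL: 0.95,
}


@dataclass(frozen=True)
class UrbanSurfaceGrid:
    """Static per-cell urban fraction and land class on a regular grid.

    Parameters
    ----------
    urban_fraction : ndarray of shape (n_y, n_x)
        Fraction of impervious surface per cell, in [0, 1]. Zero for
        open-water and vegetation cells.
    land_class : ndarray of shape (n_y, n_x)
        Integer land-class codes (see :data:`LAND_CLASS_NAMES`).
    cell_size : float
        Cell edge length in kilometres (metadata only).
    """

    urban_fraction: np.ndarray
    land_class: np.ndarray
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        uf = np.asarray(self.urban_fraction, dtype=float)
        lc = np.asarray(self.land_class, dtype=np.int8)
        object.__setattr__(self, "urban_fraction", uf)
        object.__setattr__(self, "land_class", lc)
        if uf.ndim != 2 or uf.shape != lc.shape:
            raise SchemaError(
                f"urban_fraction {uf.shape} and land_class {lc.shape} must be "
                "congruent 2-D (y, x) arrays"
            )
        if not np.isin(lc, list(LAND_CLASS_NAMES)).all():
            bad = sorted(set(np.unique(lc)) - set(LAND_CLASS_NAMES))
            raise SchemaError(f"unknown land-class codes {bad}")
        if np.any((uf < 0.0) | (uf > 1.0)):
            raise SchemaError("urban_fraction outside [0, 1]")
        zero_classes = (lc == OPEN_WATER) | (lc == VEGETATION)
        if np.any(uf[zero_classes] != 0.0):
            raise SchemaError(
                "urban_fraction must be 0 on open_water and vegetation cells"
            )

    @property
    def n_y(self) -> int:
        return self.urban_fraction.shape[0]

    @property
    def n_x(self) -> int:
        return self.urban_fraction.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.urban_fraction.shape

    @property
    def water_mask(self) -> np.ndarray:
        """Boolean (n_y, n_x): True on open-water cells."""
        return self.land_class == OPEN_WATER

    @property
    def land_mask(self) -> np.ndarray:
        """Boolean (n_y, n_x): True everywhere except open water."""
        return self.land_class != OPEN_WATER

    @property
    def vegetation_mask(self) -> np.ndarray:
        return self.land_class == VEGETATION

    @property
    def urban_mask(self) -> np.ndarray:
        """Cells with non-zero urban fraction."""
        return self.urban_fraction > 0.0


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the synthetic hourly-temperature generative process.

    The deterministic part of the process is a sinusoidal diurnal cycle
    peaking at 15:00 local, a multi-day heatwave pulse with separate urban
    and rural amplitudes, a nighttime warming proportional to urban
    fraction (the injected urban heat island), and a static exponential
    lake-breeze cooling field; Gaussian noise is added on top. Defaults
    emulate a Chicago-like mid-summer episode: a four-day heatwave that
    warms rural land by ~4 degC and urban land by ~2.5 degC, a ~2 degC
    nighttime urban-fraction-proportional warming, and up to 5 degC of
    coastal cooling.
    """

    n_days: int = 35
    start_date: str = "2012-06-04"
    baseline_mean: float = 26.0
    diurnal_amplitude: float = 5.0
    hw_start_day: int = 30
    hw_end_day: int = 33
    hw_amplitude_rural: float = 4.0
    hw_amplitude_urban: float = 2.5
    true_uhii_night: float = 2.0
    lake_cooling_amplitude: float = 5.0
    lake_decay_length: float = 3.0
    noise_sd: float = 0.3
    seed: int = 0
    climatology_years: int = 10
    climatology_days_per_year: int = 92

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ParameterError("n_days must be >= 1")
        if not (0 <= self.hw_start_day <= self.hw_end_day < self.n_days):
            raise ParameterError(
                "heatwave window must satisfy "
                f"0 <= hw_start_day <= hw_end_day < n_days, got "
                f"[{self.hw_start_day}, {self.hw_end_day}] with n_days={self.n_days}"
            )
        for name in (
            "diurnal_amplitude",
            "hw_amplitude_rural",
            "hw_amplitude_urban",
            "lake_cooling_amplitude",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.lake_decay_length <= 0:
            raise ParameterError("lake_decay_length must be > 0")
        if self.climatology_years < 1:
            raise ParameterError("climatology_years must be >= 1")
        if self.climatology_days_per_year < 1:
            raise ParameterError("climatology_days_per_year must be >= 1")
        # normalise the start date eagerly so bad input fails at build time
        pd.Timestamp(self.start_date)

    def replace(self, **kwargs) -> "SyntheticScenario":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TemperatureCube:
    """Hourly 2-m temperature on the grid: values are (time, y, x) in degC."""

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    grid: UrbanSurfaceGrid

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if len(ts) < 1:
            raise SchemaError("empty time axis")
        if len(ts) > 1:
            steps = np.diff(ts.values)
            if not (steps == np.timedelta64(1, "h")).all():
                raise SchemaError(
                    "time axis must be strictly increasing with a constant "
                    "1-hour step"
                )
        if vals.shape != (len(ts),) + self.grid.shape:
            raise SchemaError(
                f"values shape {vals.shape} does not match "
                f"(n_times={len(ts)}, n_y={self.grid.n_y}, n_x={self.grid.n_x})"
            )

    @property
    def n_times(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class StationSeries:
    """Hourly temperature observations at one point location.

    ``location`` is a fractional ``(row, col)`` grid coordinate; the
    generating cell (if known) is recorded in ``true_cell``.
    """

    station_id: str
    location: tuple[float, float]
    timestamps: pd.DatetimeIndex
    obs: np.ndarray
    true_cell: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        obs = np.asarray(self.obs, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "obs", obs)
        if obs.shape != (len(ts),):
            raise SchemaError(
                f"station {self.station_id}: obs length {obs.shape} does not "
                f"match {len(ts)} timestamps"
            )
        if not ts.is_monotonic_increasing or ts.has_duplicates:
            raise SchemaError(
                f"station {self.station_id}: timestamps must be strictly "
                "increasing and unique"
            )

    def as_series(self) -> pd.Series:
        """Observations as a pandas Series indexed by timestamp."""
        return pd.Series(self.obs, index=self.timestamps, name=self.station_id)
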