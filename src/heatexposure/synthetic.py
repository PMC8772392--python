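"""Synthetic urban-rural domains and hourly temperature with known structure.

Every downstream stage of the pipeline (station evaluation, urban heat
island regression, Excess Heat Factor mapping) is exercised against cubes
generated here, so each injected signal — the true nighttime warming per
unit urban fraction, the heatwave pulse amplitudes, the lake-breeze cooling
— is known exactly and recoverable.

The surface generator lays out an idealised coastal city: concentric urban
rings (industrial/commercial core, high- and low-intensity residential)
embedded in vegetation, with a band of open-water columns on the east edge
standing in for a lake. Urban fractions are categorical (0.95/0.90/0.50/0),
matching NLCD-style class aggregation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .domain import (
    CLASS_URBAN_FRACTION,
    HIGH_INTENSITY_RESIDENTIAL,
    INDUSTRIAL_COMMERCIAL,
    LOW_INTENSITY_RESIDENTIAL,
    OPEN_WATER,
    VEGETATION,
    StationSeries,
    SyntheticScenario,
    TemperatureCube,
    UrbanSurfaceGrid,
)
from .errors import ParameterError

# Diurnal partition used by the generator's nighttime warming term: the
# night window is 18:00-06:00 local, matching the analysis default.
NIGHT_START_HOUR = 18
NIGHT_END_HOUR = 6

# Local hour of the diurnal temperature peak.
DIURNAL_PEAK_HOUR = 15.0


def generate_surface(
    n_y: int,
    n_x: int,
    urban_center: tuple[int, int] = None,
    class_radii: tuple[float, float, float, float] = None,
    lake_cols: int = 2,
    cell_size: float = 1.0,
) -> UrbanSurfaceGrid:
    """Build a categorical urban-fraction surface with a lake band.

    Concentric rings around ``urban_center`` are assigned, inside out,
    industrial/commercial (fraction 0.95), high-intensity residential
    (0.90), low-intensity residential (0.50) and vegetation (0); the
    ``lake_cols`` easternmost columns are open water (fraction 0),
    overriding any ring.

    Parameters
    ----------
    urban_center : (row, col)
        Ring centre; defaults to the grid centre shifted toward the lake.
    class_radii : four strictly increasing radii in cells
        Outer radii of the industrial, high-, low-intensity and vegetation
        rings; cells beyond the last radius are vegetation too.
    lake_cols : int
        Number of easternmost open-water columns; must be < n_x.
    """
    if n_y < 1 or n_x < 1:
        raise ParameterError("grid dimensions must be positive")
    if not 0 <= lake_cols < n_x:
        raise ParameterError(f"lake_cols={lake_cols} must be in [0, n_x)")
    if urban_center is None:
        urban_center = (n_y // 2, (n_x - lake_cols) * 2 // 3)
    if class_radii is None:
        base = min(n_y, n_x - lake_cols) / 2.0
        class_radii = (base * 0.25, base * 0.45, base * 0.7, base)
    radii = tuple(float(r) for r in class_radii)
    if len(radii) != 4:
        raise ParameterError("class_radii must contain exactly four radii")
    if not all(a < b for a, b in zip(radii, radii[1:])):
        raise ParameterError(f"class_radii must be strictly increasing, got {radii}")
    if radii[-1] > max(n_y, n_x):
        raise ParameterError(
            f"largest radius {radii[-1]} exceeds the grid extent "
            f"max({n_y}, {n_x})"
        )

    rows, cols = np.indices((n_y, n_x))
    dist = np.hypot(rows - urban_center[0], cols - urban_center[1])
    land_class = np.full((n_y, n_x), VEGETATION, dtype=np.int8)
    land_class[dist <= radii[2]] = LOW_INTENSITY_RESIDENTIAL
    land_class[dist <= radii[1]] = HIGH_INTENSITY_RESIDENTIAL
    land_class[dist <= radii[0]] = INDUSTRIAL_COMMERCIAL
    if lake_cols > 0:
        land_class[:, n_x - lake_cols :] = OPEN_WATER

    urban_fraction = np.vectorize(CLASS_URBAN_FRACTION.get)(land_class).astype(float)
    return UrbanSurfaceGrid(urban_fraction, land_class, cell_size=cell_size)


def _night_indicator(hours: np.ndarray) -> np.ndarray:
    return (hours >= NIGHT_START_HOUR) | (hours < NIGHT_END_HOUR)


def lake_cooling_field(surface: UrbanSurfaceGrid, scenario: SyntheticScenario) -> np.ndarray:
    """Static cooling field (degC, positive = cooling) decaying away from the lake.

    Distance is counted in whole columns west of the open-water band; if the
    surface has no water the field is zero everywhere.
    """
    water_cols = np.flatnonzero(surface.water_mask.any(axis=0))
    cooling = np.zeros(surface.shape)
    if scenario.lake_cooling_amplitude == 0 or water_cols.size == 0:
        return cooling
    lake_edge = water_cols.min()
    col_idx = np.arange(surface.n_x)
    dist = np.clip(lake_edge - col_idx, 0, None).astype(float)
    cooling[:, :] = scenario.lake_cooling_amplitude * np.exp(
        -dist / scenario.lake_decay_length
    )[None, :]
    return cooling


def deterministic_temperature(
    surface: UrbanSurfaceGrid,
    scenario: SyntheticScenario,
    include_heatwave: bool = True,
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Noise-free component of the hourly temperature cube.

    Returns the hourly timestamps and a (time, y, x) array:

    ``T = baseline + A*sin(2*pi*(hour - 9)/24) + HW + night*uhii*frac - lake``

    The sine phase puts the diurnal peak at 15:00 local. The heatwave pulse
    adds ``hw_amplitude_urban`` on urban cells (fraction > 0) and
    ``hw_amplitude_rural`` on vegetation cells during the heatwave window;
    open water gets no pulse. The nighttime urban-heat-island term is
    ``true_uhii_night * urban_fraction`` during 18:00-06:00 local.
    """
    n_hours = scenario.n_days * 24
    timestamps = pd.date_range(scenario.start_date, periods=n_hours, freq="h")
    hours = timestamps.hour.to_numpy()
    day_index = np.arange(n_hours) // 24

    diurnal = scenario.baseline_mean + scenario.diurnal_amplitude * np.sin(
        2.0 * np.pi * (hours - (DIURNAL_PEAK_HOUR - 6.0)) / 24.0
    )
    temp = np.broadcast_to(
        diurnal[:, None, None], (n_hours,) + surface.shape
    ).copy()

    if include_heatwave:
        in_hw = (day_index >= scenario.hw_start_day) & (day_index <= scenario.hw_end_day)
        hw_field = np.zeros(surface.shape)
        hw_field[surface.urban_mask] = scenario.hw_amplitude_urban
        hw_field[surface.vegetation_mask] = scenario.hw_amplitude_rural
        temp[in_hw] += hw_field[None, :, :]

    night = _night_indicator(hours)
    temp[night] += scenario.true_uhii_night * surface.urban_fraction[None, :, :]

    temp -= lake_cooling_field(surface, scenario)[None, :, :]
    return timestamps, temp


def generate_temperature_cube(
    surface: UrbanSurfaceGrid,
    scenario: SyntheticScenario,
    include_heatwave: bool = True,
    seed: int | None = None,
) -> TemperatureCube:
    """Hourly temperature cube: deterministic structure plus Gaussian noise.

    Identical ``(surface, scenario)`` pairs regenerate bit-identical cubes;
    changing the seed changes only the noise realisation. ``seed`` overrides
    ``scenario.seed`` when given (used for per-year climatology draws).
    """
    timestamps, temp = deterministic_temperature(surface, scenario, include_heatwave)
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed if seed is None else seed)
        temp = temp + rng.normal(0.0, scenario.noise_sd, size=temp.shape)
    return TemperatureCube(timestamps, temp, surface)


_VARIANTS = ("tmax", "tmin", "tmean")


def generate_climatology(
    surface: UrbanSurfaceGrid,
    scenario: SyntheticScenario,
    variant: str = "tmean",
) -> np.ndarray:
    """Multi-year daily climatology from the non-heatwave generative process.

    Emulates a long-term daily gridded weather archive: for each of
    ``scenario.climatology_years`` baseline years, an hourly cube is drawn
    from the scenario's process *without* the heatwave pulse (year seeds are
    ``scenario.seed + year_index``) and reduced to the requested daily
    statistic.

    Returns
    -------
    ndarray of shape (climatology_years * climatology_days_per_year, n_y, n_x)
        Daily values of ``variant`` in {'tmax', 'tmin', 'tmean'}.
    """
    if variant not in _VARIANTS:
        raise ParameterError(f"variant must be one of {_VARIANTS}, got {variant!r}")
    year_scenario = scenario.replace(
        n_days=scenario.climatology_days_per_year,
        hw_start_day=0,
        hw_end_day=0,
        hw_amplitude_rural=0.0,
        hw_amplitude_urban=0.0,
    )
    reducer = {"tmax": np.max, "tmin": np.min, "tmean": np.mean}[variant]
    out = []
    for year in range(scenario.climatology_years):
        cube = generate_temperature_cube(
            surface, year_scenario, include_heatwave=False, seed=scenario.seed + year
        )
        daily = cube.values.reshape(
            scenario.climatology_days_per_year, 24, *surface.shape
        )
        out.append(reducer(daily, axis=1))
    return np.concatenate(out, axis=0)


def sample_stations(
    cube: TemperatureCube,
    n_stations: int,
    obs_noise_sd: float = 0.5,
    seed: int = 0,
) -> list[StationSeries]:
    """Sample noisy point observations from the cube at random land cells.

    Stations are placed uniformly at random on distinct land (non-water)
    cells, snapped to cell centres; observations are the cell's hourly
    series plus independent Gaussian noise.
    """
    if n_stations < 1:
        raise ParameterError("n_stations must be >= 1")
    if obs_noise_sd < 0:
        raise ParameterError("obs_noise_sd must be >= 0")
    surface = cube.grid
    land_rows, land_cols = np.nonzero(surface.land_mask)
    if n_stations > land_rows.size:
        raise ParameterError(
            f"n_stations={n_stations} exceeds the {land_rows.size} land cells"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(land_rows.size, size=n_stations, replace=False)
    stations = []
    for i, pick in enumerate(picks):
        r, c = int(land_rows[pick]), int(land_cols[pick])
        obs = cube.values[:, r, c].copy()
        if obs_noise_sd > 0:
            obs = obs + rng.normal(0.0, obs_noise_sd, size=obs.shape)
        stations.append(
            StationSeries(
                station_id=f"S{i:03d}",
                location=(float(r), float(c)),
                timestamps=cube.timestamps,
                obs=obs,
                true_cell=(r, c),
            )
        )
    return stations
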