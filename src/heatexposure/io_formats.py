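"""File I/O: CF-style NetCDF for grids, CSV for stations, flat YAML config.

Conventions (fixed and validated on read):

* gridded files carry dims in ``(time, y, x)`` order for cubes and
  ``(y, x)`` for static fields; temperature in degC with a ``units``
  attribute; urban fraction dimensionless in [0, 1]; land class as coded
  integers 0=open_water, 1=vegetation, 2=low_intensity_residential,
  3=high_intensity_residential, 4=industrial_commercial;
* times are local wall-clock instants with no time-zone attached — any
  UTC conversion is the caller's job, done once at ingest;
* station CSVs are comma-separated UTF-8 with a header and the columns
  ``station_id, time, temperature_C, row, col`` (ISO-8601 local times,
  '.' decimal).

Readers never silently coerce invalid values; every rejection names the
offending record.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .domain import (
    LAND_CLASS_NAMES,
    StationSeries,
    TemperatureCube,
    UrbanSurfaceGrid,
)
from .errors import SchemaError

logger = logging.getLogger("heatexposure")

#: NetCDF engine used throughout (classic NetCDF-3 files).
NC_ENGINE = "scipy"

STATION_COLUMNS = ["station_id", "time", "temperature_C", "row", "col"]


def setup_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; DEBUG level when verbose."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@dataclass(frozen=True)
class GriddedDatasetHandle:
    """Provenance record for a gridded file written by this module."""

    path: Path
    dims: dict
    variable_names: tuple
    time_encoding: str


def _land_class_attrs() -> dict:
    codes = sorted(LAND_CLASS_NAMES)
    return {
        "long_name": "land class",
        "flag_values": np.array(codes, dtype=np.int32),
        "flag_meanings": " ".join(LAND_CLASS_NAMES[c] for c in codes),
    }


def write_cube(
    cube: TemperatureCube, surface: UrbanSurfaceGrid, path: str | Path
) -> GriddedDatasetHandle:
    """Write a temperature cube plus its static surface to one NetCDF file."""
    if cube.values.shape[1:] != surface.shape:
        raise SchemaError(
            f"cube grid {cube.values.shape[1:]} does not match surface "
            f"{surface.shape}"
        )
    path = Path(path)
    time_units = f"hours since {cube.timestamps[0].isoformat(sep=' ')}"
    ds = xr.Dataset(
        {
            "temperature": (
                ("time", "y", "x"),
                cube.values,
                {"units": "degC", "long_name": "2-m air temperature"},
            ),
            "urban_fraction": (
                ("y", "x"),
                surface.urban_fraction,
                {"units": "1", "long_name": "fraction of impervious surface"},
            ),
            "land_class": (
                ("y", "x"),
                surface.land_class.astype(np.int32),
                _land_class_attrs(),
            ),
        },
        coords={"time": cube.timestamps},
        attrs={"Conventions": "CF-1.8", "cell_size_km": surface.cell_size},
    )
    ds.to_netcdf(
        path,
        engine=NC_ENGINE,
        encoding={"time": {"units": time_units, "calendar": "standard"}},
    )
    return GriddedDatasetHandle(
        path=path,
        dims={"time": cube.n_times, "y": surface.n_y, "x": surface.n_x},
        variable_names=("temperature", "urban_fraction", "land_class"),
        time_encoding=f"{time_units} (standard calendar)",
    )


def read_cube(path: str | Path) -> tuple[TemperatureCube, UrbanSurfaceGrid]:
    """Read and validate a gridded file written by :func:`write_cube`.

    NaN blocks in the temperature variable are kept as NaN (an explicit
    mask) and their count is logged; all other schema violations raise
    :class:`SchemaError` naming the offending variable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine=NC_ENGINE) as ds:
        ds = ds.load()
    for name in ("temperature", "urban_fraction", "land_class"):
        if name not in ds:
            raise SchemaError(f"{path}: missing required variable '{name}'")
    temp = ds["temperature"]
    if temp.dims != ("time", "y", "x"):
        raise SchemaError(
            f"{path}: temperature dims {temp.dims} must be ('time', 'y', 'x')"
        )
    if temp.attrs.get("units") is None:
        raise SchemaError(f"{path}: temperature is missing a 'units' attribute")
    for name in ("urban_fraction", "land_class"):
        if ds[name].dims != ("y", "x"):
            raise SchemaError(f"{path}: {name} dims must be ('y', 'x')")
    frac = ds["urban_fraction"].values.astype(float)
    if np.any((frac < 0) | (frac > 1)):
        raise SchemaError(f"{path}: urban_fraction outside [0, 1]")
    n_masked = int(np.isnan(temp.values).sum())
    if n_masked:
        logger.info("%s: %d masked (NaN) temperature values", path, n_masked)
    surface = UrbanSurfaceGrid(
        urban_fraction=frac,
        land_class=ds["land_class"].values.astype(np.int8),
        cell_size=float(ds.attrs.get("cell_size_km", 1.0)),
    )
    times = pd.DatetimeIndex(ds["time"].values)
    if len(times) > 1 and not (np.diff(times.values) == np.timedelta64(1, "h")).all():
        raise SchemaError(f"{path}: irregular time axis (expected hourly steps)")
    cube = TemperatureCube(times, temp.values.astype(float), surface)
    return cube, surface


def write_daily_field(
    values: np.ndarray,
    path: str | Path,
    variable: str,
    units: str = "degC",
    attrs: dict | None = None,
) -> Path:
    """Write a (day, y, x) daily field (e.g. a climatology) to NetCDF."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise SchemaError(f"expected a (day, y, x) array, got shape {values.shape}")
    ds = xr.Dataset(
        {variable: (("day", "y", "x"), values, {"units": units})},
        attrs=attrs or {},
    )
    ds.to_netcdf(path, engine=NC_ENGINE)
    return Path(path)


def read_daily_field(path: str | Path, variable: str) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine=NC_ENGINE) as ds:
        if variable not in ds:
            raise SchemaError(f"{path}: missing required variable '{variable}'")
        if ds[variable].dims != ("day", "y", "x"):
            raise SchemaError(
                f"{path}: {variable} dims {ds[variable].dims} must be "
                "('day', 'y', 'x')"
            )
        return ds[variable].values.astype(float)


def write_ehf_field(field, path: str | Path) -> Path:
    """Write an EHF field (ehi_sig, ehi_accl, ehf, severity) to NetCDF.

    Severity codes: 0 none, 1 positive, 2 high, -1 masked (open water).
    """
    ds = xr.Dataset(
        {
            "ehi_sig": (("y", "x"), field.ehi_sig, {"units": "degC"}),
            "ehi_accl": (("y", "x"), field.ehi_accl, {"units": "degC"}),
            "ehf": (("y", "x"), field.ehf, {"units": "degC2"}),
            "severity": (
                ("y", "x"),
                field.severity.astype(np.int32),
                {
                    "flag_values": np.array([-1, 0, 1, 2], dtype=np.int32),
                    "flag_meanings": "masked none positive high",
                },
            ),
        },
        attrs={
            "variant": field.variant,
            "high_threshold_degC2": field.high_threshold,
        },
    )
    ds.to_netcdf(path, engine=NC_ENGINE)
    return Path(path)


def write_station_csv(stations: list[StationSeries], path: str | Path) -> Path:
    """Write stations to a long-format CSV, one row per (station, hour)."""
    frames = []
    for st in stations:
        frames.append(
            pd.DataFrame(
                {
                    "station_id": st.station_id,
                    "time": st.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                    "temperature_C": st.obs,
                    "row": st.location[0],
                    "col": st.location[1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def read_station_csv(path: str | Path) -> list[StationSeries]:
    """Read station series from CSV; sorts rows by time within a station.

    Duplicate (station, time) rows and unparseable timestamps are rejected
    with the offending station / line number named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    parsed = pd.to_datetime(df["time"], format="ISO8601", errors="coerce")
    bad = np.flatnonzero(parsed.isna().to_numpy())
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise SchemaError(
            f"{path}: unparseable time at line {bad[0] + 2}: "
            f"{df['time'].iloc[bad[0]]!r}"
        )
    df = df.assign(time=parsed)
    dups = df.duplicated(subset=["station_id", "time"], keep=False)
    if dups.any():
        first = df.loc[dups].iloc[0]
        raise SchemaError(
            f"{path}: duplicate (station, time) row: "
            f"({first['station_id']}, {first['time']})"
        )
    stations = []
    for sid, group in df.groupby("station_id", sort=True):
        group = group.sort_values("time")
        stations.append(
            StationSeries(
                station_id=str(sid),
                location=(float(group["row"].iloc[0]), float(group["col"].iloc[0])),
                timestamps=pd.DatetimeIndex(group["time"]),
                obs=group["temperature_C"].to_numpy(dtype=float),
            )
        )
    return stations


def load_config(path: str | Path) -> dict:
    """Load a flat key: value config file (YAML syntax, one level deep)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a flat key: value mapping")
    return data


def save_config(config: dict, path: str | Path) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, default_flow_style=False, sort_keys=True)
    return Path(path)
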