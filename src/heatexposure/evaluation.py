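"""Station-based model-performance statistics: MB, GE, RMSE.

For each station the modelled series (the cube value at the station's
nearest grid cell) is paired with the observed series on their common
timestamps and three metrics are computed over the n paired hours:

* mean bias            MB   = mean(mod - obs)
* mean gross error     GE   = mean(|mod - obs|)
* root mean sq. error  RMSE = sqrt(mean((mod - obs)^2))

Benchmark flags mark stations within the suggested surface-temperature
performance envelopes (configurable; defaults |MB| <= 0.5 degC and
GE <= 2.0 degC). Aggregation across stations is an unweighted mean of the
per-station metrics.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import StationSeries, TemperatureCube, UrbanSurfaceGrid
from .errors import EmptyOverlapError, ParameterError, PlacementError

logger = logging.getLogger("heatexposure")

#: Default performance benchmarks (degC). Kept as data, never baked into logic.
DEFAULT_MB_BENCHMARK = 0.5
DEFAULT_GE_BENCHMARK = 2.0


@dataclass(frozen=True)
class EvalResult:
    """Per-station (or aggregate) evaluation statistics."""

    station_id: str
    n: int
    mb: float
    ge: float
    rmse: float
    mb_ok: bool
    ge_ok: bool


def match_station_to_cell(
    station: StationSeries, surface: UrbanSurfaceGrid
) -> tuple[int, int]:
    """Nearest cell centre to the station's fractional (row, col) location.

    Ties at a cell boundary break toward the lower (row, col) index.
    """
    row, col = station.location
    if not (-0.5 <= row <= surface.n_y - 0.5 and -0.5 <= col <= surface.n_x - 0.5):
        raise PlacementError(
            f"station {station.station_id} at ({row}, {col}) lies outside the "
            f"{surface.n_y}x{surface.n_x} grid"
        )
    # ceil(x - 0.5) rounds to nearest with half-way cases toward the lower index
    r = min(max(math.ceil(row - 0.5), 0), surface.n_y - 1)
    c = min(max(math.ceil(col - 0.5), 0), surface.n_x - 1)
    return r, c


def compute_metrics(
    obs: pd.Series,
    mod: pd.Series,
    station_id: str = "",
    mb_benchmark: float = DEFAULT_MB_BENCHMARK,
    ge_benchmark: float = DEFAULT_GE_BENCHMARK,
) -> EvalResult:
    """MB/GE/RMSE between observed and modelled series.

    Series are aligned on their common timestamps; unpaired timestamps are
    dropped (count logged), never interpolated. Raises
    :class:`EmptyOverlapError` if no pairs remain.
    """
    common = obs.index.intersection(mod.index)
    dropped = (len(obs) - len(common)) + (len(mod) - len(common))
    if dropped:
        logger.info(
            "station %s: dropped %d unpaired timestamps", station_id or "?", dropped
        )
    if len(common) == 0:
        raise EmptyOverlapError(
            f"station {station_id or '?'}: no common timestamps between "
            "observed and modelled series"
        )
    diff = mod.loc[common].to_numpy(dtype=float) - obs.loc[common].to_numpy(dtype=float)
    mb = float(np.mean(diff))
    ge = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    return EvalResult(
        station_id=station_id,
        n=len(common),
        mb=mb,
        ge=ge,
        rmse=rmse,
        mb_ok=abs(mb) <= mb_benchmark,
        ge_ok=ge <= ge_benchmark,
    )


def aggregate_metrics(
    results: list[EvalResult],
    mb_benchmark: float = DEFAULT_MB_BENCHMARK,
    ge_benchmark: float = DEFAULT_GE_BENCHMARK,
) -> EvalResult:
    """Unweighted mean of MB/GE/RMSE across stations; n is the total pairs."""
    if not results:
        raise ParameterError("cannot aggregate an empty list of results")
    mb = float(np.mean([r.mb for r in results]))
    ge = float(np.mean([r.ge for r in results]))
    rmse = float(np.mean([r.rmse for r in results]))
    return EvalResult(
        station_id="ALL",
        n=int(sum(r.n for r in results)),
        mb=mb,
        ge=ge,
        rmse=rmse,
        mb_ok=abs(mb) <= mb_benchmark,
        ge_ok=ge <= ge_benchmark,
    )


def evaluate_stations(
    stations: list[StationSeries],
    cube: TemperatureCube,
    mb_benchmark: float = DEFAULT_MB_BENCHMARK,
    ge_benchmark: float = DEFAULT_GE_BENCHMARK,
) -> pd.DataFrame:
    """Evaluate the cube against every station; returns the metrics table.

    One row per station plus a final unweighted-mean 'ALL' row, with
    columns station_id, n, MB, GE, RMSE, mb_ok, ge_ok.
    """
    results = []
    for st in stations:
        r, c = match_station_to_cell(st, cube.grid)
        mod = pd.Series(cube.values[:, r, c], index=cube.timestamps)
        results.append(
            compute_metrics(
                st.as_series(), mod, st.station_id, mb_benchmark, ge_benchmark
            )
        )
    results.append(aggregate_metrics(results, mb_benchmark, ge_benchmark))
    return pd.DataFrame(
        {
            "station_id": [r.station_id for r in results],
            "n": [r.n for r in results],
            "MB": [r.mb for r in results],
            "GE": [r.ge for r in results],
            "RMSE": [r.rmse for r in results],
            "mb_ok": [r.mb_ok for r in results],
            "ge_ok": [r.ge_ok for r in results],
        }
    )
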