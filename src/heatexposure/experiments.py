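"""Seeded validation experiments: parameter recovery and null calibration.

These are the package's own correctness studies, run against the synthetic
generator whose injected structure is known exactly:

* UHII parameter recovery — does the nighttime regression recover the
  injected warming-per-unit-urban-fraction, and do its 95% confidence
  intervals attain nominal coverage?
* Null control — with no injected urban-fraction signal, do the nightly
  slope intervals cover zero at the nominal rate?
* Percentile null calibration — when an episode is drawn from the same
  process as the climatology, daily values exceed the per-cell 95th
  percentile baseline on ~5% of cell-days by construction.

Each experiment isolates the effect under study: the recovery scenarios
switch off the heatwave pulse and the lake-breeze field, because both are
deterministic confounders that correlate with urban fraction by design and
would bias the recovered slope away from the injected value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domain import SyntheticScenario, UrbanSurfaceGrid
from .ehf import compute_t95
from .synthetic import generate_climatology, generate_surface, generate_temperature_cube
from .uhi import daily_uhii_series

#: Grid with exactly 1000 land cells (25 rows x 40 land columns + 2 water).
RECOVERY_GRID = dict(n_y=25, n_x=42, lake_cols=2)


def _recovery_surface() -> UrbanSurfaceGrid:
    return generate_surface(**RECOVERY_GRID)


def _recovery_scenario(true_slope: float, noise_sd: float, seed: int) -> SyntheticScenario:
    return SyntheticScenario(
        n_days=2,
        hw_start_day=0,
        hw_end_day=0,
        hw_amplitude_rural=0.0,
        hw_amplitude_urban=0.0,
        true_uhii_night=true_slope,
        lake_cooling_amplitude=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of a seeded UHII parameter-recovery experiment."""

    true_slope: float
    slopes: np.ndarray
    coverage: float  # fraction of replicates whose 95% CI covers the truth
    n_cells: int

    @property
    def mean_slope(self) -> float:
        return float(self.slopes.mean())

    @property
    def mean_abs_error(self) -> float:
        return float(np.abs(self.slopes - self.true_slope).mean())


def uhii_recovery_experiment(
    n_replicates: int = 100,
    true_slope: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> RecoveryResult:
    """Recover the injected nighttime UHII over seeded replicates.

    Each replicate draws a fresh noise realisation of a two-day cube on the
    1000-land-cell grid, estimates the nightly slope series, and checks
    whether each 95% CI covers the injected slope.
    """
    surface = _recovery_surface()
    slopes, covered, n_cells = [], [], 0
    for rep in range(n_replicates):
        scenario = _recovery_scenario(true_slope, noise_sd, seed + rep)
        cube = generate_temperature_cube(surface, scenario)
        estimates = daily_uhii_series(cube, surface, period="night")
        for est in estimates:
            lo, hi = est.ci95()
            slopes.append(est.slope)
            covered.append(lo <= true_slope <= hi)
            n_cells = est.n_cells
    return RecoveryResult(
        true_slope=true_slope,
        slopes=np.array(slopes),
        coverage=float(np.mean(covered)),
        n_cells=n_cells,
    )


def null_exceedance_experiment(
    seed: int = 0,
    n_y: int = 40,
    n_x: int = 52,
    lake_cols: int = 2,
    climatology_years: int = 10,
    days_per_year: int = 92,
    noise_sd: float = 0.3,
) -> float:
    """Fraction of land cell-days exceeding the T95 baseline under the null.

    The climatology and a fresh one-year episode are drawn from the same
    non-heatwave process (independent seeds); per construction of the 95th
    percentile the per-cell exceedance rate of single daily values is ~5%.
    Returns the pooled land-cell exceedance fraction (dimensionless).
    """
    surface = generate_surface(n_y, n_x, lake_cols=lake_cols)
    scenario = SyntheticScenario(
        hw_amplitude_rural=0.0,
        hw_amplitude_urban=0.0,
        noise_sd=noise_sd,
        seed=seed,
        climatology_years=climatology_years,
        climatology_days_per_year=days_per_year,
    )
    clim = generate_climatology(surface, scenario, "tmean")
    baseline = compute_t95(clim, "tmean", n_years=climatology_years)
    episode = generate_climatology(
        surface,
        scenario.replace(seed=seed + 100003, climatology_years=1),
        "tmean",
    )
    exceed = episode > baseline.t95[None, :, :]
    return float(exceed[:, surface.land_mask].mean())
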