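"""Global extrapolation from a station production vs satellite-PIC regression.

A simple OLS of annual CaCO3 production against annual-mean surface
satellite PIC (the non-zero intercept absorbs the deep, satellite-
invisible production of the subtropics) is applied to a global PIC
climatology, weighted by spherical cell area, and summed.  A
complementary minimum estimate applies station-level rates to the
fraction of the ocean with low (< 10 mg m-3) surface PIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .constants import EARTH_RADIUS_M, MOLAR_MASS_C, MOLAR_MASS_CACO3


@dataclass(frozen=True)
class StationPoint:
    """One station: annual production and the satellite PIC predictor."""

    station: str
    annual_production: float  # mol m-2 yr-1
    satellite_pic: float  # mg m-3

    def __post_init__(self):
        if self.annual_production < 0 or self.satellite_pic < 0:
            raise ValueError("production and satellite PIC must be >= 0")


@dataclass(frozen=True)
class RegressionFit:
    intercept: float  # mol m-2 yr-1
    slope: float  # mol m-2 yr-1 per mg m-3
    r_squared: float
    std_error: float  # residual standard error, mol m-2 yr-1
    n: int
    p_value: float = float("nan")

    def predict(self, pic):
        return self.intercept + self.slope * np.asarray(pic, dtype=float)


def fit_pic_regression(points: list[StationPoint]) -> RegressionFit:
    """OLS with intercept of production on satellite PIC.

    R2 = 1 - SSres/SStot and residual SE = sqrt(SSres/(n-2)).  Constant
    y (zero residual variance around a flat line) degenerates to slope 0
    with R2 reported as 0 and a warning.
    """
    if len(points) < 3:
        raise ValueError("at least 3 stations are required")
    x = np.array([p.satellite_pic for p in points])
    y = np.array([p.annual_production for p in points])
    if np.ptp(x) == 0:
        raise ValueError("satellite PIC has zero variance across stations")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ssres = float(res.ssr)
    if np.ptp(y) == 0:
        warnings.warn("constant production across stations; R^2 undefined, reported as 0")
        r2 = 0.0
    else:
        r2 = float(res.rsquared)
    return RegressionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r_squared=r2,
        std_error=float(np.sqrt(ssres / (len(points) - 2))),
        n=len(points),
        p_value=float(res.pvalues[1]),
    )


@dataclass
class PICGrid:
    """Regular lat x lon (x month) satellite PIC field, mg m-3.

    ``values`` is (nlat, nlon) for an annual field or (12, nlat, nlon)
    for a monthly climatology; missing retrievals are NaN.  The ocean
    mask defaults to cells with at least one valid monthly retrieval.
    """

    latitudes: np.ndarray  # cell centres, degrees
    longitudes: np.ndarray
    values: np.ndarray
    ocean_mask: np.ndarray | None = None

    def __post_init__(self):
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.abs(self.latitudes) > 90):
            raise ValueError("latitudes must lie in [-90, 90]")
        expected = (self.latitudes.size, self.longitudes.size)
        if self.values.shape not in (expected, (12, *expected)):
            raise ValueError(f"values shape {self.values.shape} does not match grid {expected}")
        if self.ocean_mask is None:
            # cells with at least one valid monthly retrieval count as ocean
            self.ocean_mask = ~np.isnan(self.annual())
        self.ocean_mask = np.asarray(self.ocean_mask, dtype=bool)
        if self.ocean_mask.shape != expected:
            raise ValueError("ocean mask shape does not match the grid")

    @property
    def monthly(self) -> bool:
        return self.values.ndim == 3

    def annual(self) -> np.ndarray:
        """Annual field: unweighted mean over months with valid retrievals."""
        if not self.monthly:
            return self.values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    def month(self, m: int) -> np.ndarray:
        if not self.monthly:
            raise ValueError("grid holds a single annual field")
        return self.values[m - 1]

    def cell_areas(self, earth_radius: float = EARTH_RADIUS_M) -> np.ndarray:
        """Spherical cell areas, m2: R^2 dlambda (sin(lat+) - sin(lat-)).

        Uses exact latitude-band sines so that a regular global grid
        sums to 4 pi R^2 to machine precision.
        """
        lat_edges = _edges(self.latitudes, clip=(-90.0, 90.0))
        lon_edges = _edges(self.longitudes)
        sin_lat = np.sin(np.radians(lat_edges))
        band = sin_lat[1:] - sin_lat[:-1]
        dlon = np.radians(np.diff(lon_edges))
        return earth_radius**2 * np.abs(band[:, None] * dlon[None, :])

    def value_at(self, latitude: float, longitude: float, month: int | None = None) -> float:
        """Nearest-cell lookup (station predictor extraction)."""
        i = int(np.argmin(np.abs(self.latitudes - latitude)))
        j = int(np.argmin(np.abs(self.longitudes - longitude)))
        f = self.annual() if month is None else self.month(month)
        return float(f[i, j])


def _edges(centres: np.ndarray, clip: tuple[float, float] | None = None) -> np.ndarray:
    mid = (centres[:-1] + centres[1:]) / 2.0
    first = centres[0] - (mid[0] - centres[0])
    last = centres[-1] + (centres[-1] - mid[-1])
    edges = np.concatenate([[first], mid, [last]])
    if clip is not None:
        edges = np.clip(edges, *clip)
    return edges


@dataclass
class GlobalTotal:
    total_mol_yr: float
    total_pg_c_yr: float
    ocean_area_m2: float
    fit: RegressionFit


def integrate_global(
    grid: PICGrid, fit: RegressionFit, earth_radius: float = EARTH_RADIUS_M
) -> GlobalTotal:
    """Area-weighted global production: sum over ocean cells of
    max(0, intercept + slope x PIC) x cell area, in mol yr-1 and Pg C yr-1.

    Predictions are floored at zero before integration so the total is
    defined for any coefficients.
    """
    mask = grid.ocean_mask
    if not mask.any():
        warnings.warn("empty ocean mask; global total is zero")
        return GlobalTotal(0.0, 0.0, 0.0, fit)
    areas = grid.cell_areas(earth_radius)
    pic = np.nan_to_num(grid.annual(), nan=0.0)
    production = np.maximum(0.0, fit.predict(pic))
    total = float((production * areas)[mask].sum())
    return GlobalTotal(
        total_mol_yr=total,
        total_pg_c_yr=convert_units("mol_to_PgC", total),
        ocean_area_m2=float(areas[mask].sum()),
        fit=fit,
    )


@dataclass
class LowPICEstimate:
    area_fraction: float
    ocean_area_m2: float
    per_rate_mol_yr: dict  # station rate (mol m-2 yr-1) -> mol yr-1
    mean_mol_yr: float


def low_pic_minimum(
    grid: PICGrid,
    station_rates,
    threshold: float = 10.0,
    earth_radius: float = EARTH_RADIUS_M,
) -> LowPICEstimate:
    """Minimum global production from the low-PIC fraction of the ocean.

    fraction = ocean area with annual PIC < threshold / total ocean
    area; the minimum estimate is fraction x ocean area x rate for each
    supplied station rate, plus their mean.
    """
    mask = grid.ocean_mask
    areas = grid.cell_areas(earth_radius)
    ocean_area = float(areas[mask].sum())
    annual = grid.annual()
    low = mask & (annual < threshold)
    fraction = float(areas[low].sum() / ocean_area) if ocean_area > 0 else 0.0
    rates = [float(r) for r in np.atleast_1d(station_rates)]
    per_rate = {r: fraction * ocean_area * r for r in rates}
    return LowPICEstimate(
        area_fraction=fraction,
        ocean_area_m2=ocean_area,
        per_rate_mol_yr=per_rate,
        mean_mol_yr=float(np.mean(list(per_rate.values()))) if per_rate else 0.0,
    )


def convert_units(kind: str, value: float) -> float:
    """Reporting-boundary unit conversions.

    mol_to_PgC: mol CaCO3 yr-1 -> Pg C yr-1 (x 12.011 g/mol / 1e15);
    mmolCaCO3_to_mg: mmol m-3 -> mg m-3 (x 100.09);
    mgCaCO3_to_mol: mg -> mol (/ 100.09 / 1e3).
    """
    if value < 0:
        raise ValueError("value must be >= 0")
    if kind == "mol_to_PgC":
        return value * MOLAR_MASS_C / 1e15
    if kind == "mmolCaCO3_to_mg":
        return value * MOLAR_MASS_CACO3
    if kind == "mgCaCO3_to_mol":
        return value / MOLAR_MASS_CACO3 / 1e3
    raise ValueError(f"unknown conversion {kind!r}")
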