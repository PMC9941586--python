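"""Synthetic cruise, compilation, climatology, and trap data with known truth.

Every input the pipeline consumes can be generated here with a
machine-readable ground-truth record, so the full analysis is testable
without any external download.  The defaults emulate the study
conditions of a late-summer subtropical-to-subpolar North Pacific
transect: five main stations from ~23N to ~50N, total living CaCO3
standing stocks rising from ~700 mg m-2 in the oligotrophic subtropics
to ~3800 mg m-2 in the subpolar gyre, coccolithophores carrying ~80% of
the stock (pteropods 15%, foraminifera 4%, heteropods 1%),
chlorophyll-following Gaussian coccolithophore depth profiles that
shoal polewards, lognormal shell-size and biomass distributions with
~7% zeros in the biomass compilation, and a low-subtropical /
high-subpolar surface PIC field with an August maximum.

All generators are bit-reproducible given (seed, config); every
recovery test reads truth only from the emitted truth record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .biomass import (
    DEFAULT_ALLOMETRY,
    DEFAULT_CHAINS,
    DEFAULT_COCCOLITH_TABLE,
    FilterCount,
    ForamWeighing,
    ShellRecord,
    pteropod_heteropod_caco3,
)
from .constants import rng_for
from .stocks import DepthProfile, TowSample, fluorescence_lower_bound, integrate_profile

#: family mix within each zooplankton taxon (mass-weighted)
PTEROPOD_FAMILY_MIX = {"Limacinidae": 0.7, "Cavoliniidae": 0.2, "Cymbuliidae": 0.1}
HETEROPOD_FAMILY_MIX = {"Atlantidae": 0.8, "Carinidae": 0.2}

#: lognormal shell-length parameters (mu, sigma of log length in mm)
DEFAULT_SHELL_LOGNORMAL = {
    "Limacinidae": (math.log(1.0), 0.5),
    "Cavoliniidae": (math.log(1.5), 0.4),
    "Cymbuliidae": (math.log(2.0), 0.4),
    "Atlantidae": (math.log(1.5), 0.4),
    "Carinidae": (math.log(1.5), 0.4),
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic transect."""

    seed: int = 0
    n_stations: int = 5
    latitudes: tuple = (22.75, 30.0, 37.5, 44.0, 50.1)
    longitude: float = -155.0
    #: total living CaCO3 standing stock per station, mg m-2
    total_stocks: tuple = (700.0, 850.0, 1700.0, 2600.0, 3800.0)
    #: taxon shares of the total stock (coccolithophore, pteropod,
    #: foraminifera, heteropod)
    shares: tuple = (0.80, 0.15, 0.04, 0.01)
    #: loose-coccolith stock as a fraction of the coccosphere stock
    loose_coccolith_ratio: float = 0.4
    shell_lognormal: dict = field(default_factory=lambda: dict(DEFAULT_SHELL_LOGNORMAL))
    #: coccolithophore profile: peak depth shoals polewards
    cocco_peak_depth: tuple = (120.0, 30.0)  # subtropical, subpolar end, m
    cocco_width: float = 30.0  # Gaussian width, m
    #: tow geometry: max depth deepens equatorwards, oblique path length
    tow_depth: tuple = (300.0, 150.0)  # subtropical, subpolar end, m
    split_fraction: float = 0.125
    #: biomass compilation (zero-inflated lognormal carbon biomass)
    n_biomass_records: int = 1793
    zero_fraction: float = 0.067
    biomass_median_caco3: float = 0.5  # mg CaCO3 m-3 target median
    biomass_sigma: float = 1.2
    n_planted_outliers: int = 0
    #: PIC climatology: subtropical / subpolar values, mg m-3
    pic_gradient: tuple = (5.0, 80.0)
    low_pic_threshold: float = 10.0
    low_pic_fraction: float = 0.87
    #: fraction of the sphere that is ocean (land drawn as a longitude
    #: sector away from the transect, so the low-PIC fraction is unchanged)
    ocean_fraction: float = 0.71
    grid_step: float = 1.0  # degrees
    seasonal_amplitude: tuple = (0.2, 1.0)  # subtropical, subpolar August excess
    #: trap fluxes
    export_efficiency_true: float = 0.2
    trap_noise_sd: float = 0.0
    trap_aragonite: tuple = (0.30, 0.05)  # subtropical, subpolar end

    def __post_init__(self):
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must be in [0, 1)")
        if abs(sum(self.shares) - 1.0) > 1e-9:
            raise ValueError("taxon shares must sum to 1")
        if len(self.latitudes) < self.n_stations or len(self.total_stocks) < self.n_stations:
            raise ValueError("latitudes and total_stocks must cover n_stations")

    def station_latitudes(self):
        return self.latitudes[: self.n_stations]

    def lat_interp(self, pair: tuple, latitude: float) -> float:
        """Linear interpolation between the transect's end-member values."""
        lat0, lat1 = self.latitudes[0], self.latitudes[self.n_stations - 1]
        if lat1 == lat0:
            return float(pair[0])
        t = np.clip((latitude - lat0) / (lat1 - lat0), 0.0, 1.0)
        return float(pair[0] + t * (pair[1] - pair[0]))


from functools import lru_cache


@lru_cache(maxsize=64)
def expected_individual_caco3(family: str, mu: float, sigma: float, n_quad: int = 4001) -> float:
    """E[CaCO3 per individual] for lognormal shell lengths, by quadrature.

    Midpoint rule on the quantile transform; deterministic and accurate
    to well under 0.1% for the smooth allometric forms.
    """
    u = (np.arange(n_quad) + 0.5) / n_quad
    lengths = np.exp(mu + sigma * stats.norm.ppf(u))
    coeffs, chain = DEFAULT_ALLOMETRY[family], DEFAULT_CHAINS[family]
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        masses = [
            pteropod_heteropod_caco3(ShellRecord(family, L), coeffs, chain) for L in lengths
        ]
    return float(np.mean(masses))


#: family whose strictly monotone power-law fit closes the mass gap
_CLOSING_FAMILY = {"pteropod": "Limacinidae", "heteropod": "Carinidae"}


def _solve_length(family: str, mass: float) -> float:
    """Shell length whose converted CaCO3 equals ``mass`` (power forms)."""
    from scipy.optimize import brentq

    def f(L):
        return pteropod_heteropod_caco3(ShellRecord(family, L)) - mass

    return float(brentq(f, 1e-6, 200.0))


def _fill_shell_sample(taxon, mix, sample_mass_target, cfg, rng):
    """Draw shell records totalling exactly ``sample_mass_target`` mg.

    Per family, floor(target/mean mass) lognormal individuals are drawn;
    the leftover gap (including sub-individual granularity of the
    near-constant heteropod exponential fit) is closed by a single
    individual of the closing family with its length solved from the
    allometric chain.
    """
    records: list[ShellRecord] = []
    realized = 0.0
    if sample_mass_target <= 0:
        return records, realized
    closing = _CLOSING_FAMILY[taxon]
    families = [f for f in mix if f != closing] + [closing]
    remaining = sample_mass_target
    for family in families:
        mu, sigma = cfg.shell_lognormal[family]
        mean_mass = expected_individual_caco3(family, mu, sigma)
        target = mix.get(family, 0.0) * sample_mass_target
        if family == closing:
            target = remaining  # absorb what the other families left
        n = int(target / mean_mass)
        drawn = []
        for L in np.exp(rng.normal(mu, sigma, size=n)):
            rec = ShellRecord(family, float(L))
            m = pteropod_heteropod_caco3(rec)
            if realized + m >= sample_mass_target:
                break
            drawn.append((rec, m))
            realized += m
            remaining -= m
        records.extend(r for r, _ in drawn)
    gap = sample_mass_target - realized
    if gap > 1e-9:
        rec = ShellRecord(closing, _solve_length(closing, gap))
        records.append(rec)
        realized += pteropod_heteropod_caco3(rec)
    return records, realized


@dataclass
class StationSurvey:
    """Generated inputs and truth for one station."""

    station: str
    latitude: float
    tow: TowSample
    filter_counts: list
    fluorescence: DepthProfile
    truth: dict


def _bottle_depths(max_depth: float) -> np.ndarray:
    depths = np.array([5, 15, 25, 40, 55, 75, 100, 125, 150, 175, 200, 225, 250], dtype=float)
    return depths[depths <= max_depth]


def gen_station_survey(cfg: GeneratorConfig, station_index: int) -> StationSurvey:
    """One station's tow, filter counts, and fluorescence, with truth.

    Individual counts are drawn so that running the biomass and
    standing-stock stages recovers the configured per-taxon areal
    stocks in expectation (Poisson count noise only).
    """
    lat = cfg.station_latitudes()[station_index]
    name = f"St{station_index + 1}"
    rng = rng_for(cfg.seed, f"survey:{name}")
    total = cfg.total_stocks[station_index]
    targets = dict(zip(("coccolithophore", "pteropod", "foraminifera", "heteropod"), cfg.shares))
    targets = {k: v * total for k, v in targets.items()}

    max_depth = cfg.lat_interp(cfg.tow_depth, lat)
    distance = float(rng.uniform(2.0, 3.0)) * max_depth
    volume = math.pi * 0.25**2 * distance
    split = cfg.split_fraction

    # --- zooplankton: lognormal shell lists filled to the target sample
    # mass, closed exactly by one solved-length individual of the last
    # (power-law) family, so the realized areal stock equals the target
    shell_records: list[ShellRecord] = []
    realized = {}
    for taxon, mix in (("pteropod", PTEROPOD_FAMILY_MIX), ("heteropod", HETEROPOD_FAMILY_MIX)):
        sample_mass_target = targets[taxon] * volume * split / max_depth
        records, realized_mass = _fill_shell_sample(taxon, mix, sample_mass_target, cfg, rng)
        shell_records.extend(records)
        realized[taxon] = realized_mass / split / volume * max_depth

    # --- foraminifera: split-scaled weighings reproduce the target exactly
    sample_weight = targets["foraminifera"] * volume * split / max_depth
    foram_weighings = [
        ForamWeighing("lt125", 0.3 * sample_weight, max(1, int(0.3 * sample_weight / 0.005)), split),
        ForamWeighing("ge125", 0.7 * sample_weight, max(1, int(0.7 * sample_weight / 0.02)), split),
    ]
    realized["foraminifera"] = targets["foraminifera"]

    tow = TowSample(
        station=name, latitude=lat, flow_distance=distance, max_depth=max_depth,
        split_fraction=split, shell_records=shell_records, foram_weighings=foram_weighings,
    )

    # --- coccolithophores: Gaussian profile scaled so the truncated
    # trapezoid integral equals the target stock
    z0 = cfg.lat_interp(cfg.cocco_peak_depth, lat)
    w = cfg.cocco_width
    depths = _bottle_depths(max(200.0, min(250.0, z0 + 3.5 * w)))
    fluor_depths = np.arange(2.0, max(z0 + 4 * w, depths[-1]) + 1, 2.0)
    fluor = np.exp(-((fluor_depths - z0) ** 2) / (2 * w**2))
    lower = fluorescence_lower_bound(fluor_depths, fluor)
    unit_vals = np.exp(-((depths - z0) ** 2) / (2 * w**2))
    unit_integral = integrate_profile(DepthProfile(depths, unit_vals, lower_bound=lower))
    peak = targets["coccolithophore"] / unit_integral  # mg m-3 at the profile peak

    species = "Emiliania huxleyi"
    lps = DEFAULT_COCCOLITH_TABLE.coccoliths_per_sphere[species]
    mass_pg = DEFAULT_COCCOLITH_TABLE.coccolith_mass_pg[species]
    filter_counts = []
    for z, uv in zip(depths, unit_vals):
        conc = peak * uv  # mg m-3 coccosphere calcite
        cells_per_l = conc / (lps * mass_pg * 1e-6)
        liths_per_l = cfg.loose_coccolith_ratio * conc / (mass_pg * 1e-6)
        F, A, V = 1000.0, float(rng.uniform(0.35, 3.14)), float(rng.uniform(2.1, 6.0))
        filter_counts.append(
            FilterCount(
                depth=float(z), effective_filtration_area=F, counted_area=A,
                filtered_volume=V,
                coccosphere_counts={species: int(rng.poisson(cells_per_l * A * V / F))},
                loose_coccolith_counts={species: int(rng.poisson(liths_per_l * A * V / F))},
            )
        )
    realized["coccolithophore"] = targets["coccolithophore"]

    truth = {
        "station": name,
        "latitude": lat,
        "target_stocks": targets,
        "realized_stocks": realized,
        "loose_coccolith_stock": cfg.loose_coccolith_ratio * targets["coccolithophore"],
        "tow_volume_m3": volume,
        "max_depth_m": max_depth,
        "cocco_peak_depth_m": z0,
        "fluorescence_lower_bound_m": lower,
    }
    return StationSurvey(
        station=name, latitude=lat, tow=tow, filter_counts=filter_counts,
        fluorescence=DepthProfile(fluor_depths, fluor, station=name), truth=truth,
    )


def gen_survey(cfg: GeneratorConfig) -> list[StationSurvey]:
    return [gen_station_survey(cfg, i) for i in range(cfg.n_stations)]


def gen_maredat_like(cfg: GeneratorConfig):
    """Zero-inflated lognormal carbon-biomass compilation with truth.

    The lognormal median is set so that the CaCO3 biomass at the
    midpoint PIC:POC ratio matches ``biomass_median_caco3``; optional
    outliers are planted far beyond the 3-sigma cut.  Returns
    (DataFrame with lat/lon/depth/carbon_biomass/month, truth dict).
    """
    import pandas as pd

    rng = rng_for(cfg.seed, "maredat")
    n = cfg.n_biomass_records
    r_mid = (0.20 + 0.56) / 2.0
    fpic_mid = r_mid / (1 + r_mid)
    carbon_median = cfg.biomass_median_caco3 / (fpic_mid * 8.33)
    values = np.exp(rng.normal(math.log(carbon_median), cfg.biomass_sigma, size=n))
    zeros = rng.random(n) < cfg.zero_fraction
    values[zeros] = 0.0
    outlier_value = values.mean() + 8.0 * values.std(ddof=1)
    if cfg.n_planted_outliers:
        idx = rng.choice(n, size=cfg.n_planted_outliers, replace=False)
        values[idx] = outlier_value

    df = pd.DataFrame(
        {
            "latitude": rng.uniform(20, 60, size=n),
            "longitude": rng.uniform(-180, -120, size=n),
            "depth": rng.uniform(0, 250, size=n),
            "carbon_biomass": values,
            "month": rng.integers(1, 13, size=n),
        }
    )
    # analytic marginal medians: zero inflation shifts the lognormal
    # median to its (0.5 - z)/(1 - z) quantile; the CaCO3 transform uses
    # the mean PIC fraction over the flat PIC:POC prior,
    # E[r/(1+r)] = 1 - ln((1+hi)/(1+lo))/(hi-lo)
    z = cfg.zero_fraction
    carbon_median_marginal = carbon_median * math.exp(
        cfg.biomass_sigma * stats.norm.ppf((0.5 - z) / (1.0 - z))
    )
    lo, hi = 0.20, 0.56
    fpic_mean = 1.0 - math.log((1 + hi) / (1 + lo)) / (hi - lo)
    truth = {
        "carbon_median": carbon_median,
        "caco3_median": cfg.biomass_median_caco3,
        "carbon_median_marginal": carbon_median_marginal,
        "caco3_median_marginal": carbon_median_marginal * fpic_mean * 8.33,
        "fpic_mean": fpic_mean,
        "zero_fraction": cfg.zero_fraction,
        "n_records": n,
        "n_zeros": int(zeros.sum()),
        "n_planted_outliers": cfg.n_planted_outliers,
        "planted_outlier_value": float(outlier_value),
        "realized_skewness": float(stats.skew(values)),
    }
    return df, truth


#: subpolar Northeast-Pacific bloom patch (lat range, lon range): keeps a
#: high-PIC regime over the transect's northern stations while most of the
#: ocean stays in the low band
BLOOM_PATCH = ((45.0, 60.0), (-180.0, -130.0))


def gen_pic_climatology(cfg: GeneratorConfig):
    """Monthly global PIC grid with a known low-PIC area fraction.

    Surface PIC is a two-regime field: the configured subtropical value
    equatorwards of a latitude cut, the subpolar value polewards and
    inside a fixed Northeast-Pacific bloom patch covering the northern
    end of the transect.  The latitude cut is chosen (by exact
    area-weighted search over cell edges) so that the realized area
    fraction below the low-PIC threshold is as close as possible to
    ``low_pic_fraction``.  Monthly values are
    base x (1 + a cos(2 pi (month-8)/12)), so the annual mean is
    exactly the base field and the August/annual bias factor is
    exactly 1 + a.  Returns (PICGrid, truth dict).
    """
    from .globalize import PICGrid

    step = cfg.grid_step
    lats = np.arange(-90 + step / 2, 90, step)
    lons = np.arange(-180 + step / 2, 180, step)
    (plat0, plat1), (plon0, plon1) = BLOOM_PATCH
    in_patch = (
        (lats[:, None] >= plat0) & (lats[:, None] < plat1)
        & (lons[None, :] >= plon0) & (lons[None, :] < plon1)
    )
    # land: a longitude sector starting at 40E, away from both the
    # transect and the bloom patch; uniform over latitude so the low-PIC
    # area fraction is unaffected
    land_width = (1.0 - cfg.ocean_fraction) * 360.0
    land = (lons[None, :] >= 40.0) & (lons[None, :] < 40.0 + land_width)
    ocean = np.broadcast_to(~land, (lats.size, lons.size))
    # exact area weights per cell (same spherical formula the integrator uses)
    band = np.sin(np.radians(lats + step / 2)) - np.sin(np.radians(lats - step / 2))
    weights = np.broadcast_to(
        (band[:, None] / band.sum()) / lons.size, (lats.size, lons.size)
    ).copy()
    weights[~ocean] = 0.0
    weights = weights / weights.sum()

    def low_fraction(cut_deg: float) -> tuple[float, np.ndarray]:
        high = (np.abs(lats)[:, None] > cut_deg) | in_patch
        return float(weights[~high].sum()), high

    edges = np.arange(0.0, 90.0 + step, step)
    fracs = [low_fraction(e)[0] for e in edges]
    cut = float(edges[int(np.argmin(np.abs(np.array(fracs) - cfg.low_pic_fraction)))])
    realized_fraction, high_region = low_fraction(cut)

    low, high = cfg.pic_gradient
    base = np.where(high_region, high, low)
    amp = np.where(high_region, cfg.seasonal_amplitude[1], cfg.seasonal_amplitude[0])
    months = np.arange(1, 13)
    season = 1.0 + amp[None, :, :] * np.cos(2 * np.pi * (months[:, None, None] - 8) / 12.0)
    values = base[None, :, :] * season
    values = np.where(ocean[None, :, :], values, np.nan)

    grid = PICGrid(lats, lons, values, ocean_mask=ocean.copy())
    truth = {
        "lat_cut_deg": cut,
        "low_pic_fraction": realized_fraction,
        "low_value": low,
        "high_value": high,
        "august_bias_low": 1.0 + cfg.seasonal_amplitude[0],
        "august_bias_high": 1.0 + cfg.seasonal_amplitude[1],
    }
    return grid, truth


def gen_trap_fluxes(cfg: GeneratorConfig, production_truth: dict):
    """Trap fluxes consistent with a configured export efficiency.

    ``production_truth`` maps station -> total daily production
    (mg m-2 d-1); flux = production x efficiency x (1 + noise), at 100 m
    and 200 m, with the trap aragonite fraction decreasing polewards.
    Returns (list of TrapFlux, truth dict).
    """
    from .export import TrapFlux

    rng = rng_for(cfg.seed, "traps")
    lats = cfg.station_latitudes()
    traps, truth_flux = [], {}
    for i, (station, production) in enumerate(production_truth.items()):
        lat = lats[i] if i < len(lats) else lats[-1]
        arag = cfg.lat_interp(cfg.trap_aragonite, lat)
        for depth in (100.0, 200.0):
            noise = rng.normal(0.0, cfg.trap_noise_sd) if cfg.trap_noise_sd > 0 else 0.0
            flux = production * cfg.export_efficiency_true * (1.0 + noise)
            traps.append(
                TrapFlux(station=station, depth=depth, caco3_flux=max(0.0, flux),
                         flux_unit="mg m-2 d-1", aragonite_fraction=arag)
            )
        truth_flux[station] = production * cfg.export_efficiency_true
    truth = {
        "export_efficiency": cfg.export_efficiency_true,
        "noiseless_flux_mg_m2_d": truth_flux,
    }
    return traps, truth


def survey_truth_record(cfg: GeneratorConfig, surveys: list[StationSurvey]) -> dict:
    """Combined machine-readable truth for a generated survey."""
    return {
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items() if not isinstance(v, dict)},
        "stations": {s.station: s.truth for s in surveys},
    }
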