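"""Daily and seasonally corrected annual CaCO3 production per taxon.

Production follows from the steady-state assumption: the living stock
divided by the taxon's turnover time (typical lifespan).  Turnover is
only known as a range, so it is propagated with a flat (uniform) prior
via Monte Carlo; coccolithophore turnover is sampled on the cell
division rate and inverted.  A snapshot daily rate is annualized by
x365 and divided by a seasonal bias factor (satellite PIC for
coccolithophores, chlorophyll for foraminifera, a latitude-interpolated
zooplankton seasonality for pteropods/heteropods).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    COCCO_DIVISION_RATE,
    DEFAULT_PIC_POC_RANGES,
    DEFAULT_TURNOVER_DAYS,
    MOLAR_MASS_CACO3,
    ZOOPLANKTON_BIAS_ANCHORS,
    rng_for,
)
from .skewed import density_mode
from .stocks import StandingStock

PERCENTILES = (2.5, 16.0, 32.0, 50.0, 68.0, 84.0, 97.5)


@dataclass(frozen=True)
class TaxonParams:
    """Flat-prior parameter ranges for one taxon.

    ``turnover_range`` is in days; coccolithophores instead carry a
    ``division_rate_range`` in divisions per day, from which turnover is
    1/rate.
    """

    taxon: str
    turnover_range: tuple[float, float] | None = None
    division_rate_range: tuple[float, float] | None = None
    pic_poc_range: tuple[float, float] | None = None

    def __post_init__(self):
        for name in ("turnover_range", "division_rate_range", "pic_poc_range"):
            rng = getattr(self, name)
            if rng is not None and not 0 < rng[0] < rng[1]:
                raise ValueError(f"{self.taxon}: {name} must satisfy 0 < min < max")
        if self.turnover_range is None and self.division_rate_range is None:
            raise ValueError(f"{self.taxon}: a turnover or division-rate range is required")


def default_taxon_params(taxon: str, foram_alt: bool = False) -> TaxonParams:
    """Published defaults: pteropods/heteropods 5-16 d, foraminifera
    14-28 d (10-30 d with ``foram_alt``), coccolithophores 0.1-1.5
    divisions per day."""
    if taxon == "coccolithophore":
        return TaxonParams(
            taxon, division_rate_range=COCCO_DIVISION_RATE,
            pic_poc_range=DEFAULT_PIC_POC_RANGES[taxon],
        )
    if taxon not in DEFAULT_TURNOVER_DAYS:
        raise KeyError(f"no default turnover range for taxon {taxon!r}")
    rng = (10.0, 30.0) if (foram_alt and taxon == "foraminifera") else DEFAULT_TURNOVER_DAYS[taxon]
    return TaxonParams(taxon, turnover_range=rng, pic_poc_range=DEFAULT_PIC_POC_RANGES[taxon])


def draw_turnover(params: TaxonParams, n: int, seed: int | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Flat-prior turnover samples, days.

    Uniform on the turnover range; for coccolithophores uniform on the
    division rate, then tau = 1/rate.  Reproducible given a seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for reproducibility")
        rng = rng_for(seed, f"turnover:{params.taxon}")
    if params.division_rate_range is not None:
        return 1.0 / rng.uniform(*params.division_rate_range, size=n)
    return rng.uniform(*params.turnover_range, size=n)


def expected_daily_production(areal_stock: float, turnover_range: tuple[float, float]) -> float:
    """Closed-form mean of stock/tau under tau ~ U(a, b): S ln(b/a)/(b-a)."""
    a, b = turnover_range
    return areal_stock * np.log(b / a) / (b - a)


@dataclass
class ProductionDistribution:
    """Monte-Carlo sample of one taxon's production at one station."""

    taxon: str
    station: str
    samples: np.ndarray  # mg m-2 d-1, or mol m-2 yr-1 after annualization
    seed: int | None = None
    units: str = "mg m-2 d-1"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_draws(self) -> int:
        return int(self.samples.size)

    def percentile(self, q) -> np.ndarray:
        return np.percentile(self.samples, q)

    def summary(self) -> dict:
        pct = self.percentile(PERCENTILES)
        out = {f"p{p:g}": float(v) for p, v in zip(PERCENTILES, pct)}
        out["mode"] = density_mode(self.samples)
        out["mean"] = float(self.samples.mean())
        return out

    def ci(self, level: int = 68) -> tuple[float, float]:
        if level == 68:
            return tuple(self.percentile([16, 84]))
        if level == 95:
            return tuple(self.percentile([2.5, 97.5]))
        raise ValueError("supported CI levels are 68 and 95")


def production_distribution(
    stock: StandingStock, turnover_samples: np.ndarray,
    seed: int | None = None,
) -> ProductionDistribution:
    """Daily production draws: areal stock / turnover, elementwise."""
    if stock.areal < 0:
        raise ValueError("standing stock must be >= 0")
    samples = stock.areal / np.asarray(turnover_samples, dtype=float)
    return ProductionDistribution(stock.taxon, stock.station, samples, seed=seed)


@dataclass(frozen=True)
class SeasonalBias:
    """Snapshot-to-annual correction: annual = daily x 365 / factor."""

    taxon: str
    factor: float
    source: str

    def __post_init__(self):
        if not self.factor > 0:
            raise ValueError("seasonal bias factor must be > 0")


def seasonal_bias(
    taxon: str,
    august_value: float | None = None,
    annual_mean_value: float | None = None,
    latitude: float | None = None,
) -> SeasonalBias:
    """Seasonal bias factor for one taxon at one site.

    Coccolithophores: August satellite PIC / annual-mean PIC.
    Foraminifera: August chlorophyll / annual-mean chlorophyll.
    Pteropods/heteropods: zooplankton summer/annual ratio interpolated
    linearly in latitude between the subtropical (1.2) and subpolar
    (2.0) time-series anchors, clamped outside.
    """
    if taxon in ("pteropod", "heteropod"):
        if latitude is None:
            raise ValueError(f"{taxon}: latitude required for the zooplankton bias")
        (lat0, f0), (lat1, f1) = ZOOPLANKTON_BIAS_ANCHORS
        t = np.clip((latitude - lat0) / (lat1 - lat0), 0.0, 1.0)
        return SeasonalBias(taxon, float(f0 + t * (f1 - f0)), "zooplankton_latitude")
    source = {"coccolithophore": "satellite_PIC", "foraminifera": "satellite_chlorophyll"}.get(taxon)
    if source is None:
        raise ValueError(f"no seasonal bias rule for taxon {taxon!r}")
    if august_value is None or annual_mean_value is None:
        raise ValueError(f"{taxon}: August and annual-mean climatology values required")
    if annual_mean_value <= 0:
        raise ValueError("annual-mean climatology value must be > 0")
    return SeasonalBias(taxon, august_value / annual_mean_value, source)


#: mg CaCO3 m-2 d-1 -> mol CaCO3 m-2 yr-1
MG_DAY_TO_MOL_YEAR = 365.0 / (MOLAR_MASS_CACO3 * 1000.0)


def annualize(daily: ProductionDistribution, bias: SeasonalBias) -> ProductionDistribution:
    """Annual production, mol CaCO3 m-2 yr-1: daily x 365 / bias factor.

    The full Monte-Carlo distribution is annualized (not just its
    median), preserving the skewed shape of the flat-prior propagation.
    """
    samples = daily.samples * MG_DAY_TO_MOL_YEAR / bias.factor
    return ProductionDistribution(
        daily.taxon, daily.station, samples, seed=daily.seed, units="mol m-2 yr-1"
    )


def station_production(
    stocks: dict[str, StandingStock],
    params: dict[str, TaxonParams] | None = None,
    n_draws: int = 10000,
    seed: int = 0,
) -> dict[str, ProductionDistribution]:
    """Matched Monte-Carlo production draws for all taxa at one station.

    One turnover draw per taxon per iteration with a shared iteration
    index, so that per-draw share distributions are coherent.
    """
    out = {}
    for taxon, stock in stocks.items():
        p = params[taxon] if params else default_taxon_params(taxon)
        tau = draw_turnover(p, n_draws, seed=seed)
        out[taxon] = production_distribution(stock, tau, seed=seed)
    return out


@dataclass
class TaxonShares:
    """Per-draw percentage shares of total production (or stock)."""

    shares: dict  # taxon -> np.ndarray of per-draw shares, %
    aragonite: np.ndarray  # per-draw aragonite share, %

    def summary(self) -> dict:
        out = {}
        for taxon, s in self.shares.items():
            lo, med, hi = np.percentile(s, [2.5, 50, 97.5])
            out[taxon] = {"median": float(med), "ci95": (float(lo), float(hi))}
        lo, med, hi = np.percentile(self.aragonite, [2.5, 50, 97.5])
        out["aragonite"] = {"median": float(med), "ci95": (float(lo), float(hi))}
        return out


def taxon_fractions(per_taxon: dict[str, ProductionDistribution]) -> TaxonShares:
    """Percentage shares per matched Monte-Carlo draw, plus the mineral split.

    Shares sum to 100% on every draw; the aragonite share is the
    pteropod + heteropod fraction.  A draw set with zero total has
    undefined shares and is rejected.
    """
    if not per_taxon:
        raise ValueError("no taxa supplied")
    n = {d.n_draws for d in per_taxon.values()}
    if len(n) != 1:
        raise ValueError("all taxa must share the same number of matched draws")
    mat = np.vstack([d.samples for d in per_taxon.values()])
    total = mat.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("total production is zero on some draws; shares undefined")
    shares = {t: 100.0 * mat[i] / total for i, t in enumerate(per_taxon)}
    aragonite = sum(
        (shares[t] for t in ("pteropod", "heteropod") if t in shares),
        np.zeros_like(total),
    )
    return TaxonShares(shares=shares, aragonite=aragonite)
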