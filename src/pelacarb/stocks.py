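"""Volumetric and depth-integrated CaCO3 standing stocks per station.

Net tows are treated as column-integrating samplers: the volumetric
concentration (total CaCO3 in the sample over the filtered volume) times
the maximum tow depth gives the areal stock.  Niskin-bottle profiles are
trapezoid-integrated from the first sampled depth down to the depth
where fluorescence falls to 1% of its peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .biomass import (
    ForamWeighing,
    ShellRecord,
    foraminifera_caco3,
    pteropod_heteropod_caco3,
)
from .constants import MINERAL_BY_TAXON


@dataclass
class TowSample:
    """One oblique net tow: counts, geometry, and split metadata."""

    station: str
    latitude: float
    flow_distance: float  # m, from the flowmeter
    max_depth: float  # m
    split_fraction: float = 1.0
    net_diameter: float = 0.5  # m
    shell_records: list[ShellRecord] = field(default_factory=list)
    foram_weighings: list[ForamWeighing] = field(default_factory=list)

    def __post_init__(self):
        if self.flow_distance is None or not self.flow_distance > 0:
            raise ValueError(f"station {self.station}: flowmeter distance required (> 0)")
        if not 0 < self.split_fraction <= 1:
            raise ValueError(f"station {self.station}: split fraction must be in (0, 1]")
        if not self.max_depth > 0:
            raise ValueError(f"station {self.station}: max tow depth must be > 0")


def tow_volume(tow: TowSample) -> float:
    """Filtered water volume, m3: net mouth area times flowmeter distance."""
    return math.pi * (tow.net_diameter / 2.0) ** 2 * tow.flow_distance


@dataclass(frozen=True)
class StandingStock:
    """Per-station, per-taxon CaCO3 inventory."""

    station: str
    taxon: str
    areal: float  # mg CaCO3 m-2
    volumetric: float  # mg CaCO3 m-3
    mineral: str = ""

    def __post_init__(self):
        if self.areal < 0 or self.volumetric < 0:
            raise ValueError("standing stock must be >= 0")
        expected = MINERAL_BY_TAXON.get(self.taxon)
        mineral = self.mineral or expected
        if expected is not None and mineral != expected:
            raise ValueError(f"{self.taxon} stock must be {expected}, got {mineral!r}")
        object.__setattr__(self, "mineral", mineral or "calcite")


def tow_standing_stock(
    tow: TowSample,
    taxon: str,
    allometry: dict | None = None,
    chains: dict | None = None,
) -> StandingStock:
    """Standing stock of one zooplankton taxon from a tow.

    volumetric = sum(count/split x CaCO3 per individual) / tow volume;
    areal = volumetric x max tow depth.  An empty tow is a valid zero
    stock.  ``taxon`` selects which records are summed: shell records
    for pteropods/heteropods (by family), weighings for foraminifera.
    """
    from .biomass import DEFAULT_ALLOMETRY, DEFAULT_CHAINS, HETEROPOD_FAMILIES

    volume = tow_volume(tow)
    if taxon == "foraminifera":
        total = foraminifera_caco3(tow.foram_weighings)
    elif taxon in ("pteropod", "heteropod"):
        families = (
            HETEROPOD_FAMILIES if taxon == "heteropod" else ("Cavoliniidae", "Cymbuliidae", "Limacinidae")
        )
        allometry = allometry or DEFAULT_ALLOMETRY
        chains = chains or DEFAULT_CHAINS
        total = 0.0
        for rec in tow.shell_records:
            if rec.family not in families:
                continue
            per_ind = pteropod_heteropod_caco3(rec, allometry[rec.family], chains[rec.family])
            total += rec.count / tow.split_fraction * per_ind
    else:
        raise ValueError(f"tow stocks are defined for zooplankton taxa, not {taxon!r}")
    volumetric = total / volume
    return StandingStock(tow.station, taxon, areal=volumetric * tow.max_depth, volumetric=volumetric)


@dataclass
class DepthProfile:
    """Discrete vertical profile of a concentration, mg m-3 at depths in m.

    ``lower_bound`` is the depth where fluorescence falls to 1% of its
    peak; the integral is truncated there (and never extrapolated above
    the first sample).
    """

    depths: np.ndarray
    values: np.ndarray
    lower_bound: float = math.inf
    station: str = ""

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.shape != self.values.shape:
            raise ValueError("depths and values must have the same length")
        if not np.all(np.diff(self.depths) > 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("profile values must be >= 0")


def integrate_profile(profile: DepthProfile) -> float:
    """Trapezoidal depth integral, mg m-2, over [first depth, lower bound].

    The profile is never extrapolated: integration starts at the first
    sampled depth and stops at min(deepest sample, lower_bound), with
    linear interpolation when the bound falls between samples.
    """
    if profile.depths.size < 2:
        raise ValueError(
            f"station {profile.station or '?'}: at least two depths are "
            "required to integrate a profile"
        )
    z, v = profile.depths, profile.values
    zmax = min(z[-1], profile.lower_bound)
    if zmax <= z[0]:
        return 0.0
    if zmax < z[-1]:
        v_end = float(np.interp(zmax, z, v))
        keep = z < zmax
        z = np.append(z[keep], zmax)
        v = np.append(v[keep], v_end)
    return float(np.trapezoid(v, z))


def fluorescence_lower_bound(depths, fluorescence, fraction: float = 0.01) -> float:
    """Shallowest depth below the fluorescence maximum where the signal
    falls to ``fraction`` of its peak, linearly interpolated.

    Returns +inf when the profile never decays that far (integration is
    then truncated at the deepest sample).
    """
    z = np.asarray(depths, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    ipk = int(np.argmax(f))
    target = fraction * f[ipk]
    for i in range(ipk, z.size - 1):
        if f[i + 1] <= target:
            if f[i] == f[i + 1]:
                return float(z[i + 1])
            frac = (f[i] - target) / (f[i] - f[i + 1])
            return float(z[i] + frac * (z[i + 1] - z[i]))
    return math.inf
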