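"""Production versus sediment-trap export: efficiency, mineralogy, residence.

Comparisons are made at matched stations only.  Daily trap fluxes are
annualized by x365 when compared with annual production; the floating
traps are 72-hour snapshots, so no seasonal weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .production import ProductionDistribution, taxon_fractions


@dataclass(frozen=True)
class TrapFlux:
    """Sediment-trap CaCO3 flux at one station and depth."""

    station: str
    depth: float  # m
    caco3_flux: float
    flux_unit: str = "mg m-2 d-1"  # or "mol m-2 yr-1"
    aragonite_fraction: float | None = None  # from XRD mineralogy

    def __post_init__(self):
        if self.caco3_flux < 0:
            raise ValueError("flux must be >= 0")
        if self.flux_unit not in ("mg m-2 d-1", "mol m-2 yr-1"):
            raise ValueError(f"unknown flux unit {self.flux_unit!r}")
        if self.aragonite_fraction is not None and not 0 <= self.aragonite_fraction <= 1:
            raise ValueError("aragonite fraction must be in [0, 1]")

    def annual_mol(self) -> float:
        """Flux in mol CaCO3 m-2 yr-1 (daily mg fluxes annualized x365)."""
        if self.flux_unit == "mol m-2 yr-1":
            return self.caco3_flux
        from .production import MG_DAY_TO_MOL_YEAR

        return self.caco3_flux * MG_DAY_TO_MOL_YEAR


@dataclass(frozen=True)
class ExportEfficiency:
    exported_percent: float  # trap/production x 100
    remineralised_percent: float
    production_to_export_ratio: float


def export_efficiency(production_annual: float, trap_annual: float) -> ExportEfficiency:
    """Fraction of production exported past the trap depth.

    Both arguments in mol CaCO3 m-2 yr-1.  Zero production leaves the
    efficiency undefined.
    """
    if production_annual <= 0:
        raise ValueError("export efficiency undefined for zero production")
    frac = trap_annual / production_annual
    return ExportEfficiency(
        exported_percent=100.0 * frac,
        remineralised_percent=100.0 * (1.0 - frac),
        production_to_export_ratio=production_annual / trap_annual if trap_annual > 0 else float("inf"),
    )


@dataclass
class AragoniteComparison:
    produced_median: float  # fraction in [0, 1]
    produced_ci95: tuple[float, float]
    exported: float | None  # trap mineralogy, passed through


def aragonite_fractions(
    production_by_taxon: dict[str, ProductionDistribution], trap: TrapFlux | None = None
) -> AragoniteComparison:
    """Aragonite fraction of production (pteropod + heteropod share per
    matched MC draw, with 95% CI) versus the trap mineralogy fraction."""
    shares = taxon_fractions(production_by_taxon)
    lo, med, hi = np.percentile(shares.aragonite, [2.5, 50, 97.5]) / 100.0
    return AragoniteComparison(
        produced_median=float(med),
        produced_ci95=(float(lo), float(hi)),
        exported=None if trap is None else trap.aragonite_fraction,
    )


def coccolith_residence_time(
    loose_stock: float, coccosphere_production
) -> np.ndarray | float:
    """Residence time of loose coccoliths in the production layer, days.

    loose-coccolith standing stock (mg m-2) over whole-coccosphere
    production (mg m-2 d-1); propagated elementwise over MC draws when
    an array or ProductionDistribution is given.
    """
    if isinstance(coccosphere_production, ProductionDistribution):
        coccosphere_production = coccosphere_production.samples
    prod = np.asarray(coccosphere_production, dtype=float)
    if np.any(prod <= 0):
        raise ValueError("residence time undefined for zero production")
    out = loose_stock / prod
    return float(out) if out.ndim == 0 else out
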