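"""Per-individual and per-litre CaCO3 from raw plankton measurements.

Pteropod and heteropod shell lengths enter family-specific allometric
fits and a wet-weight -> dry-weight -> POC -> PIC -> CaCO3 conversion
chain; coccolithophore microscopy counts are converted to cell
concentrations and calcite mass via per-species coccolith tables;
picked foraminifera are weighed directly (test weight taken as pure
CaCO3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .constants import (
    CACO3_PER_PIC,
    DW_TO_POC,
    HETEROPOD_PIC_POC,
    MOLAR_MASS_C,
    MOLAR_MASS_CACO3,
    PTEROPOD_PIC_POC,
    WW_TO_DW,
)

PTEROPOD_FAMILIES = ("Cavoliniidae", "Cymbuliidae", "Limacinidae")
HETEROPOD_FAMILIES = ("Atlantidae", "Carinidae")
FAMILIES = PTEROPOD_FAMILIES + HETEROPOD_FAMILIES

ALLOMETRIC_FORMS = ("power_WW", "power_DW", "linear_DW", "exponential_CaCO3")


@dataclass(frozen=True)
class ShellRecord:
    """One measured shell-length bin of a net-tow sample."""

    family: str
    length: float  # shell length, mm
    count: int = 1  # individuals at this length

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not self.length > 0:
            raise ValueError(f"shell length must be > 0 mm, got {self.length}")
        if int(self.count) != self.count or self.count < 1:
            raise ValueError(f"count must be an integer >= 1, got {self.count}")


@dataclass(frozen=True)
class CarbonChainParams:
    """Factors of the WW -> DW -> POC -> PIC -> CaCO3 conversion chain."""

    ww_to_dw: float = WW_TO_DW
    dw_to_poc: float = DW_TO_POC
    pic_poc_ratio: float = PTEROPOD_PIC_POC
    caco3_per_pic: float = CACO3_PER_PIC

    def __post_init__(self):
        for name in ("ww_to_dw", "dw_to_poc", "pic_poc_ratio", "caco3_per_pic"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        molar = MOLAR_MASS_CACO3 / MOLAR_MASS_C
        if abs(self.caco3_per_pic - molar) >= 0.005:
            raise ValueError(
                f"caco3_per_pic must equal M(CaCO3)/M(C) = {molar:.2f} to 2 decimals"
            )

    @property
    def caco3_per_ww(self) -> float:
        """Constant mg CaCO3 per mg wet weight implied by the chain."""
        return self.ww_to_dw * self.dw_to_poc * self.pic_poc_ratio * self.caco3_per_pic


#: chain with the heteropod PIC:POC midpoint (Carinidae enters at WW)
HETEROPOD_CHAIN = CarbonChainParams(pic_poc_ratio=HETEROPOD_PIC_POC)


@dataclass(frozen=True)
class AllometricCoeffs:
    """Family-specific length -> mass fit.

    ``length_scale`` multiplies the shell length before the fit is
    evaluated (default 1.0: lengths in mm, as printed); it exists
    because the heteropod exponential ash-weight fit is near-constant
    over realistic mm lengths and the intended unit may differ.
    """

    family: str
    form: str
    a: float
    b: float = 0.0
    c: float = 0.0  # offset, linear form only
    length_scale: float = 1.0

    def __post_init__(self):
        if self.form not in ALLOMETRIC_FORMS:
            raise ValueError(f"unknown allometric form {self.form!r}")
        if self.form.startswith("power") and not self.a > 0:
            raise ValueError("power-law coefficient a must be > 0")


#: published fits: Cavoliniidae WW=0.2152 L^2.293, Carinidae WW=0.0888 L^2.161,
#: Limacinidae DW=0.1365 L^1.501, Cymbuliidae DW=0.0392 L - 0.003,
#: Atlantidae CaCO3=0.769 e^(0.0023 L) (direct ash-weight fit, no chain)
DEFAULT_ALLOMETRY = {
    "Cavoliniidae": AllometricCoeffs("Cavoliniidae", "power_WW", 0.2152, 2.293),
    "Carinidae": AllometricCoeffs("Carinidae", "power_WW", 0.0888, 2.161),
    "Limacinidae": AllometricCoeffs("Limacinidae", "power_DW", 0.1365, 1.501),
    "Cymbuliidae": AllometricCoeffs("Cymbuliidae", "linear_DW", 0.0392, c=-0.003),
    "Atlantidae": AllometricCoeffs("Atlantidae", "exponential_CaCO3", 0.769, 0.0023),
}

DEFAULT_CHAINS = {
    "Cavoliniidae": CarbonChainParams(),
    "Cymbuliidae": CarbonChainParams(),
    "Limacinidae": CarbonChainParams(),
    "Carinidae": HETEROPOD_CHAIN,
    "Atlantidae": HETEROPOD_CHAIN,  # unused: exponential fit bypasses the chain
}


def pteropod_heteropod_caco3(
    record: ShellRecord,
    coeffs: AllometricCoeffs | None = None,
    chain: CarbonChainParams | None = None,
) -> float:
    """CaCO3 mass of one individual, mg, from its shell length.

    Power-law WW families run the full chain (DW = WW x 0.28,
    POC = DW x 0.25, PIC = POC x PIC:POC, CaCO3 = PIC x 8.33); DW-fit
    families enter the chain at DW; the Atlantidae exponential fit
    returns CaCO3 directly.  A negative linear-DW value (tiny
    Cymbuliidae juveniles) is clamped to zero with a warning.
    """
    coeffs = coeffs if coeffs is not None else DEFAULT_ALLOMETRY[record.family]
    if coeffs.family != record.family:
        raise ValueError(
            f"coefficients are for {coeffs.family}, record is {record.family}"
        )
    chain = chain if chain is not None else DEFAULT_CHAINS[record.family]
    length = record.length * coeffs.length_scale

    if coeffs.form == "exponential_CaCO3":
        return coeffs.a * math.exp(coeffs.b * length)
    if coeffs.form == "power_WW":
        ww = coeffs.a * length**coeffs.b
        dw = ww * chain.ww_to_dw
    elif coeffs.form == "power_DW":
        dw = coeffs.a * length**coeffs.b
    else:  # linear_DW
        dw = coeffs.a * length + coeffs.c
        if dw < 0:
            warnings.warn(
                f"{record.family} linear DW fit negative at L={record.length} mm; "
                "clamped to 0",
                stacklevel=2,
            )
            return 0.0
    poc = dw * chain.dw_to_poc
    pic = poc * chain.pic_poc_ratio
    return pic * chain.caco3_per_pic


@dataclass(frozen=True)
class FilterCount:
    """Coccolithophore microscopy counts for one Niskin bottle depth."""

    depth: float  # m
    effective_filtration_area: float  # F, mm2
    counted_area: float  # A, mm2
    filtered_volume: float  # V, L
    coccosphere_counts: dict = field(default_factory=dict)  # species -> count C
    loose_coccolith_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.counted_area > 0 or not self.filtered_volume > 0:
            raise ValueError("counted area and filtered volume must be > 0")
        if self.effective_filtration_area < self.counted_area:
            raise ValueError("effective filtration area must be >= counted area")
        for table in (self.coccosphere_counts, self.loose_coccolith_counts):
            for sp, c in table.items():
                if c < 0:
                    raise ValueError(f"negative count for species {sp!r}")


def coccolithophore_cell_concentration(
    fc: FilterCount, species: str, mode: str = "coccosphere"
) -> float:
    """Cells (or loose coccoliths) per litre from filter counts: F*C/(A*V).

    A species absent from the count table contributes zero.
    """
    table = fc.coccosphere_counts if mode == "coccosphere" else fc.loose_coccolith_counts
    count = table.get(species, 0)
    return (
        fc.effective_filtration_area * count / (fc.counted_area * fc.filtered_volume)
    )


@dataclass(frozen=True)
class CoccolithMassTable:
    """Per-species coccoliths per coccosphere and coccolith calcite mass (pg).

    The per-species values come from the microscopy literature and ship
    as editable configuration, not code.
    """

    coccoliths_per_sphere: dict
    coccolith_mass_pg: dict

    def __post_init__(self):
        for name, table in (
            ("coccoliths_per_sphere", self.coccoliths_per_sphere),
            ("coccolith_mass_pg", self.coccolith_mass_pg),
        ):
            for sp, v in table.items():
                if not v > 0:
                    raise ValueError(f"{name}[{sp!r}] must be > 0")

    def require(self, species: str) -> tuple[float, float]:
        if species not in self.coccoliths_per_sphere or species not in self.coccolith_mass_pg:
            raise KeyError(
                f"species {species!r} missing from the coccolith mass table; "
                "add coccoliths_per_sphere and coccolith_mass_pg entries"
            )
        return self.coccoliths_per_sphere[species], self.coccolith_mass_pg[species]


#: placeholder defaults in the literature's typical range, editable via config
DEFAULT_COCCOLITH_TABLE = CoccolithMassTable(
    coccoliths_per_sphere={"Emiliania huxleyi": 20, "Gephyrocapsa oceanica": 15},
    coccolith_mass_pg={"Emiliania huxleyi": 2.5, "Gephyrocapsa oceanica": 9.0},
)

#: pg per litre -> mg per cubic metre: x1e3 L/m3 x 1e-9 mg/pg
_PG_PER_L_TO_MG_PER_M3 = 1e3 * 1e-9


def coccolithophore_caco3(
    concentration: float,
    species: str,
    table: CoccolithMassTable = DEFAULT_COCCOLITH_TABLE,
    mode: str = "coccosphere",
) -> float:
    """Calcite concentration, mg CaCO3 m-3, from a cell or coccolith count.

    ``coccosphere`` mode multiplies cells/L by coccoliths per sphere and
    coccolith mass; ``loose_coccolith`` mode takes coccoliths/L directly.
    """
    if mode not in ("coccosphere", "loose_coccolith"):
        raise ValueError(f"unknown mode {mode!r}")
    liths_per_sphere, mass_pg = table.require(species)
    per_unit = mass_pg * (liths_per_sphere if mode == "coccosphere" else 1.0)
    return concentration * per_unit * _PG_PER_L_TO_MG_PER_M3


@dataclass(frozen=True)
class ForamWeighing:
    """One picked-and-weighed foraminiferal size fraction of a tow split."""

    size_class: str  # "lt125" or "ge125" (um sieve classes)
    total_weight: float  # mg
    count: int
    split_fraction: float  # fraction of the tow analysed, (0, 1]

    def __post_init__(self):
        if self.size_class not in ("lt125", "ge125"):
            raise ValueError(f"unknown size class {self.size_class!r}")
        if self.total_weight < 0 or self.count < 0:
            raise ValueError("weight and count must be >= 0")
        if self.total_weight > 0 and self.count == 0:
            raise ValueError("nonzero weight with zero count")
        if not 0 < self.split_fraction <= 1:
            raise ValueError("split fraction must be in (0, 1]")


def foraminifera_caco3(weighings: list[ForamWeighing]) -> float:
    """Whole-tow foraminiferal CaCO3, mg: sum of split-scaled test weights.

    Test weight is taken as pure CaCO3 (organic matter negligible).
    """
    return sum(w.total_weight / w.split_fraction for w in weighings)
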