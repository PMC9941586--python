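"""Physical constants and default taxon parameters.

All masses are carried internally in mg CaCO3; conversions to moles or
Pg C happen only at reporting boundaries.
"""

from __future__ import annotations

import hashlib

import numpy as np

#: molar mass of carbon, g mol-1
MOLAR_MASS_C = 12.011
#: molar mass of calcium carbonate, g mol-1
MOLAR_MASS_CACO3 = 100.09
#: mg CaCO3 per mg particulate inorganic carbon, M(CaCO3)/M(C) to 2 decimals
CACO3_PER_PIC = 8.33

#: wet weight -> dry weight factor for pteropods/heteropods
WW_TO_DW = 0.28
#: dry weight -> particulate organic carbon factor
DW_TO_POC = 0.25
#: PIC:POC carbon partition for pteropods (0.27:0.73 of total carbon)
PTEROPOD_PIC_POC = 0.27 / 0.73
#: heteropod PIC:POC midpoint of the 0.28-0.45 range
HETEROPOD_PIC_POC = 0.365

#: mean Earth radius, m (spherical approximation)
EARTH_RADIUS_M = 6_371_000.0

#: zooplankton seasonal-bias anchors: (latitude deg N, summer/annual ratio)
#: subtropical anchor from the ALOHA time series, subpolar from Station PAPA
ZOOPLANKTON_BIAS_ANCHORS = ((22.75, 1.2), (50.1, 2.0))

#: flat-prior turnover times, days (zooplankton) or division rates, d-1
#: (coccolithophores); see TaxonParams in production.py
DEFAULT_TURNOVER_DAYS = {
    "pteropod": (5.0, 16.0),
    "heteropod": (5.0, 16.0),
    "foraminifera": (14.0, 28.0),
}
#: alternative foraminiferal range stated alongside the default
FORAM_TURNOVER_ALT = (10.0, 30.0)
#: coccolithophore cell division rate range, divisions per day
COCCO_DIVISION_RATE = (0.1, 1.5)

#: PIC:POC ratio ranges per taxon (dimensionless carbon ratios)
DEFAULT_PIC_POC_RANGES = {
    "coccolithophore": (0.19, 2.08),
    "pteropod": (0.20, 0.56),
    "heteropod": (0.28, 0.45),
    "foraminifera": (3.0, 6.0),
}

TAXA = ("coccolithophore", "foraminifera", "pteropod", "heteropod")
ARAGONITE_TAXA = frozenset({"pteropod", "heteropod"})

MINERAL_BY_TAXON = {
    "coccolithophore": "calcite",
    "loose_coccolith": "calcite",
    "foraminifera": "calcite",
    "pteropod": "aragonite",
    "heteropod": "aragonite",
}


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, stage name).

    Adding a stage never perturbs the draws of another stage, and the
    mapping is stable across processes (hash-based, not `hash()`).
    """
    key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
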