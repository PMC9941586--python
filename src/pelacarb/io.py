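"""Delimited-text I/O and schema validation for the pipeline's tables.

All tables are plain CSV (CRLF or LF); unknown columns are ignored with
a warning and a missing required column fails fast naming the file and
column.  Taxon constants and the coccolith mass table load from YAML.
"""

from __future__ import annotations

import json
import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomass import CoccolithMassTable, FilterCount, ForamWeighing, ShellRecord
from .export import TrapFlux
from .production import TaxonParams
from .skewed import BiomassRecord
from .stocks import StandingStock, TowSample

SHELL_COLUMNS = ("station", "family", "length_mm", "count")
TOW_COLUMNS = ("station", "latitude", "flow_distance_m", "max_depth_m", "split_fraction")
FILTER_COLUMNS = ("station", "depth_m", "F_mm2", "A_mm2", "V_L", "species", "mode", "count")
FORAM_COLUMNS = ("station", "size_class", "total_weight_mg", "count", "split_fraction")
MAREDAT_COLUMNS = ("latitude", "longitude", "depth_m", "mg_C_m3", "month")
TRAP_COLUMNS = ("station", "depth_m", "flux_value", "flux_unit", "aragonite_fraction")
STATION_COLUMNS = ("station", "annual_production", "satellite_pic")


def _read_checked(path, required, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{name} table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} in {name} table")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}")
    return df[list(required)]


def read_tows(tow_path, shell_path=None, foram_path=None) -> dict[str, TowSample]:
    """Tow metadata plus optional shell-record and foram-weighing tables."""
    meta = _read_checked(tow_path, TOW_COLUMNS, "tow")
    tows = {}
    for row in meta.itertuples(index=False):
        tows[str(row.station)] = TowSample(
            station=str(row.station), latitude=float(row.latitude),
            flow_distance=float(row.flow_distance_m), max_depth=float(row.max_depth_m),
            split_fraction=float(row.split_fraction),
        )
    if shell_path is not None:
        shells = _read_checked(shell_path, SHELL_COLUMNS, "shell record")
        for i, row in enumerate(shells.itertuples(index=False)):
            try:
                rec = ShellRecord(str(row.family), float(row.length_mm), int(row.count))
            except ValueError as e:
                raise ValueError(f"{shell_path}: row {i + 2}: {e}") from e
            if str(row.station) not in tows:
                raise ValueError(f"{shell_path}: row {i + 2}: unknown station {row.station!r}")
            tows[str(row.station)].shell_records.append(rec)
    if foram_path is not None:
        forams = _read_checked(foram_path, FORAM_COLUMNS, "foram weighing")
        for i, row in enumerate(forams.itertuples(index=False)):
            try:
                w = ForamWeighing(
                    str(row.size_class), float(row.total_weight_mg), int(row.count),
                    float(row.split_fraction),
                )
            except ValueError as e:
                raise ValueError(f"{foram_path}: row {i + 2}: {e}") from e
            tows[str(row.station)].foram_weighings.append(w)
    return tows


def read_filter_counts(path) -> dict[str, list[FilterCount]]:
    """Per-station lists of FilterCount, one object per (station, depth)."""
    df = _read_checked(path, FILTER_COLUMNS, "filter count")
    out: dict[str, list[FilterCount]] = {}
    for (station, depth), grp in df.groupby(["station", "depth_m"], sort=True):
        first = grp.iloc[0]
        spheres = {
            str(r.species): int(r.count)
            for r in grp.itertuples(index=False) if str(r.mode) == "coccosphere"
        }
        loose = {
            str(r.species): int(r.count)
            for r in grp.itertuples(index=False) if str(r.mode) == "loose_coccolith"
        }
        fc = FilterCount(
            depth=float(depth), effective_filtration_area=float(first.F_mm2),
            counted_area=float(first.A_mm2), filtered_volume=float(first.V_L),
            coccosphere_counts=spheres, loose_coccolith_counts=loose,
        )
        out.setdefault(str(station), []).append(fc)
    for counts in out.values():
        counts.sort(key=lambda fc: fc.depth)
    return out


def read_biomass_records(path) -> list[BiomassRecord]:
    df = _read_checked(path, MAREDAT_COLUMNS, "biomass")
    return [
        BiomassRecord(
            latitude=float(r.latitude), longitude=float(r.longitude),
            depth=float(r.depth_m), carbon_biomass=float(r.mg_C_m3), month=int(r.month),
        )
        for r in df.itertuples(index=False)
    ]


def read_traps(path) -> list[TrapFlux]:
    df = _read_checked(path, TRAP_COLUMNS, "trap flux")
    return [
        TrapFlux(
            station=str(r.station), depth=float(r.depth_m), caco3_flux=float(r.flux_value),
            flux_unit=str(r.flux_unit),
            aragonite_fraction=None if pd.isna(r.aragonite_fraction) else float(r.aragonite_fraction),
        )
        for r in df.itertuples(index=False)
    ]


def read_station_points(path):
    from .globalize import StationPoint

    df = _read_checked(path, STATION_COLUMNS, "station point")
    return [
        StationPoint(str(r.station), float(r.annual_production), float(r.satellite_pic))
        for r in df.itertuples(index=False)
    ]


def read_grid_csv(path):
    """Wide-CSV grid: columns lat, lon, then one value column per month
    (m1..m12) or a single 'annual' column."""
    from .globalize import PICGrid

    df = pd.read_csv(path)
    for col in ("lat", "lon"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}' in grid table")
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    pivot = df.set_index(["lat", "lon"]).sort_index()
    month_cols = [c for c in df.columns if c.startswith("m") and c[1:].isdigit()]
    if month_cols:
        month_cols = sorted(month_cols, key=lambda c: int(c[1:]))
        values = np.stack(
            [pivot[c].to_numpy().reshape(lats.size, lons.size) for c in month_cols]
        )
    elif "annual" in df.columns:
        values = pivot["annual"].to_numpy().reshape(lats.size, lons.size)
    else:
        raise ValueError(f"{path}: grid table needs monthly columns m1..m12 or 'annual'")
    return PICGrid(lats, lons, values)


def read_grid(path):
    """Grid from CSV or NetCDF (by extension; NetCDF honors a mg/mol unit
    attribute on the PIC variable)."""
    path = Path(path)
    if path.suffix.lower() in (".nc", ".nc4", ".cdf"):
        return _read_grid_netcdf(path)
    return read_grid_csv(path)


def _read_grid_netcdf(path):
    import xarray as xr

    from .constants import MOLAR_MASS_CACO3
    from .globalize import PICGrid

    ds = xr.open_dataset(path)
    var = ds["pic"] if "pic" in ds else ds[list(ds.data_vars)[0]]
    values = var.to_numpy()
    unit = str(var.attrs.get("units", "mg m-3"))
    if "mol" in unit and "mmol" not in unit:
        values = values * MOLAR_MASS_CACO3 * 1e3
    elif "mmol" in unit:
        values = values * MOLAR_MASS_CACO3
    return PICGrid(ds["lat"].to_numpy(), ds["lon"].to_numpy(), values)


def read_taxon_params(path) -> dict[str, TaxonParams]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for taxon, spec in raw.items():
        out[taxon] = TaxonParams(
            taxon,
            turnover_range=tuple(spec["turnover_range"]) if "turnover_range" in spec else None,
            division_rate_range=tuple(spec["division_rate_range"]) if "division_rate_range" in spec else None,
            pic_poc_range=tuple(spec["pic_poc_range"]) if "pic_poc_range" in spec else None,
        )
    return out


def read_coccolith_table(path) -> CoccolithMassTable:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return CoccolithMassTable(
        coccoliths_per_sphere={sp: v["coccoliths_per_sphere"] for sp, v in raw.items()},
        coccolith_mass_pg={sp: v["coccolith_mass_pg"] for sp, v in raw.items()},
    )


def write_stocks(stocks: list[StandingStock], path) -> None:
    pd.DataFrame(
        [
            {"station": s.station, "taxon": s.taxon, "mineral": s.mineral,
             "volumetric_mg_m3": s.volumetric, "areal_mg_m2": s.areal}
            for s in stocks
        ]
    ).to_csv(path, index=False)


def read_stocks(path) -> list[StandingStock]:
    df = _read_checked(
        path, ("station", "taxon", "mineral", "volumetric_mg_m3", "areal_mg_m2"), "standing stock"
    )
    return [
        StandingStock(str(r.station), str(r.taxon), areal=float(r.areal_mg_m2),
                      volumetric=float(r.volumetric_mg_m3), mineral=str(r.mineral))
        for r in df.itertuples(index=False)
    ]


def write_bundle(cfg, outdir) -> dict:
    """Write a full synthetic input bundle + truth.json into a directory.

    Emits tows.csv, shells.csv, forams.csv, filters.csv, fluorescence.csv,
    maredat.csv, pic_grid.csv, traps.csv, and truth.json; returns the
    truth record.
    """
    from . import synthetic
    from .production import expected_daily_production
    from .constants import DEFAULT_TURNOVER_DAYS, COCCO_DIVISION_RATE

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    surveys = synthetic.gen_survey(cfg)

    pd.DataFrame(
        [
            {"station": s.station, "latitude": s.latitude,
             "flow_distance_m": s.tow.flow_distance, "max_depth_m": s.tow.max_depth,
             "split_fraction": s.tow.split_fraction}
            for s in surveys
        ]
    ).to_csv(outdir / "tows.csv", index=False)
    pd.DataFrame(
        [
            {"station": s.station, "family": r.family, "length_mm": r.length, "count": r.count}
            for s in surveys for r in s.tow.shell_records
        ]
    ).to_csv(outdir / "shells.csv", index=False)
    pd.DataFrame(
        [
            {"station": s.station, "size_class": w.size_class, "total_weight_mg": w.total_weight,
             "count": w.count, "split_fraction": w.split_fraction}
            for s in surveys for w in s.tow.foram_weighings
        ]
    ).to_csv(outdir / "forams.csv", index=False)
    rows = []
    for s in surveys:
        for fc in s.filter_counts:
            for mode, table in (("coccosphere", fc.coccosphere_counts),
                                ("loose_coccolith", fc.loose_coccolith_counts)):
                for sp, c in table.items():
                    rows.append({"station": s.station, "depth_m": fc.depth,
                                 "F_mm2": fc.effective_filtration_area, "A_mm2": fc.counted_area,
                                 "V_L": fc.filtered_volume, "species": sp, "mode": mode, "count": c})
    pd.DataFrame(rows).to_csv(outdir / "filters.csv", index=False)
    pd.DataFrame(
        [
            {"station": s.station, "depth_m": z, "fluorescence": f}
            for s in surveys for z, f in zip(s.fluorescence.depths, s.fluorescence.values)
        ]
    ).to_csv(outdir / "fluorescence.csv", index=False)

    maredat, maredat_truth = synthetic.gen_maredat_like(cfg)
    maredat.rename(columns={"depth": "depth_m", "carbon_biomass": "mg_C_m3"}).to_csv(
        outdir / "maredat.csv", index=False
    )

    grid, grid_truth = synthetic.gen_pic_climatology(cfg)
    _write_grid_csv(grid, outdir / "pic_grid.csv")

    # total daily production truth at turnover midpoints (see methods note)
    tau_mid = {
        "coccolithophore": 1.0 / np.mean(COCCO_DIVISION_RATE),
        **{t: float(np.mean(r)) for t, r in DEFAULT_TURNOVER_DAYS.items()},
    }
    production_by_taxon = {
        s.station: {t: v / tau_mid[t] for t, v in s.truth["target_stocks"].items()}
        for s in surveys
    }
    production_truth = {st: sum(v.values()) for st, v in production_by_taxon.items()}
    production_shares = {
        st: {t: 100.0 * v / production_truth[st] for t, v in taxa.items()}
        for st, taxa in production_by_taxon.items()
    }
    traps, trap_truth = synthetic.gen_trap_fluxes(cfg, production_truth)
    pd.DataFrame(
        [
            {"station": t.station, "depth_m": t.depth, "flux_value": t.caco3_flux,
             "flux_unit": t.flux_unit, "aragonite_fraction": t.aragonite_fraction}
            for t in traps
        ]
    ).to_csv(outdir / "traps.csv", index=False)

    truth = synthetic.survey_truth_record(cfg, surveys)
    truth["maredat"] = maredat_truth
    truth["pic_grid"] = grid_truth
    truth["traps"] = trap_truth
    truth["production_daily_mid_tau"] = production_truth
    truth["production_daily_by_taxon_mid_tau"] = production_by_taxon
    truth["production_shares_mid_tau_pct"] = production_shares
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
    return truth


def _write_grid_csv(grid, path) -> None:
    lat, lon = np.meshgrid(grid.latitudes, grid.longitudes, indexing="ij")
    data = {"lat": lat.ravel(), "lon": lon.ravel()}
    if grid.monthly:
        for m in range(12):
            data[f"m{m + 1}"] = grid.values[m].ravel()
    else:
        data["annual"] = grid.values.ravel()
    pd.DataFrame(data).to_csv(path, index=False)


def manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(json.dumps(manifest, sort_keys=True, default=str).encode()).hexdigest()[:16]
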