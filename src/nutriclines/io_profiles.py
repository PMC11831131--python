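"""Reading, validation and writing of bottle-cast tables and monthly climatologies.

The canonical cast table is a flat CSV with one row per bottle::

    cast_id, date, latitude, longitude, depth_m,
    nitrate_umol_kg, phosphate_umol_kg, temperature_c, salinity_psu, qc_flag

Empty cells are missing values.  Heterogeneous archive exports (GO-SHIP
exchange dumps, GLODAP merged products, WOD extracts) are mapped onto this
schema through a :class:`ColumnMapping` rather than format-specific parsers.

Climatologies are monthly gridded fields on integer-degree bins, carrying
either a mean nutricline depth per (site, month, nutrient) or a mean
concentration profile on a standard depth axis.  Two on-disk dialects are
supported: a long-format CSV (canonical) and NetCDF with dims
``(lat, lon, month[, depth])``.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BottleSample",
    "Cast",
    "ColumnMapping",
    "IngestReport",
    "MonthlyClimatology",
    "read_casts",
    "write_casts",
    "read_climatology",
    "write_climatology",
    "write_climatology_netcdf",
]

CANONICAL_COLUMNS = (
    "cast_id",
    "date",
    "latitude",
    "longitude",
    "depth_m",
    "nitrate_umol_kg",
    "phosphate_umol_kg",
    "temperature_c",
    "salinity_psu",
    "qc_flag",
)

#: nominal seawater density used for µmol L⁻¹ → µmol kg⁻¹ conversion
NOMINAL_DENSITY_KG_L = 1.025

QC_GOOD = "good"
QC_QUESTIONABLE = "questionable"
QC_BAD = "bad"


@dataclass(frozen=True)
class BottleSample:
    """A single bottle measurement.  Missing values are ``nan``."""

    depth: float
    nitrate: float = np.nan
    phosphate: float = np.nan
    temperature: float = np.nan
    salinity: float = np.nan
    qc_flag: str = QC_GOOD


@dataclass
class Cast:
    """One station occupation: location, date and depth-ordered bottle arrays.

    Samples are stored as parallel numpy arrays sorted strictly increasing by
    depth (duplicate depths are averaged at ingestion).  ``samples`` exposes
    the same data as :class:`BottleSample` objects.
    """

    cast_id: str
    latitude: float
    longitude: float
    date: dt.date
    depth: np.ndarray
    nitrate: np.ndarray
    phosphate: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        n = self.depth.size
        if n == 0:
            raise ValueError(f"cast {self.cast_id!r} has no samples")
        for name in ("nitrate", "phosphate", "temperature", "salinity"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"cast {self.cast_id!r}: {name} length mismatch")
            setattr(self, name, arr)
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError(f"cast {self.cast_id!r}: depths not strictly increasing")
        if np.any(self.depth < 0):
            raise ValueError(f"cast {self.cast_id!r}: negative depth")

    @property
    def n_samples(self) -> int:
        return int(self.depth.size)

    @property
    def samples(self) -> list[BottleSample]:
        return [
            BottleSample(
                depth=float(self.depth[i]),
                nitrate=float(self.nitrate[i]),
                phosphate=float(self.phosphate[i]),
                temperature=float(self.temperature[i]),
                salinity=float(self.salinity[i]),
            )
            for i in range(self.n_samples)
        ]

    def values_for(self, nutrient: str) -> np.ndarray:
        if nutrient not in ("nitrate", "phosphate"):
            raise ValueError(f"unknown nutrient {nutrient!r}")
        return getattr(self, nutrient)


@dataclass
class ColumnMapping:
    """Dialect descriptor mapping an input table onto the canonical schema.

    ``columns`` maps canonical names to source column names (identity by
    default).  ``concentration_unit`` may be ``"umol_kg"`` (canonical) or
    ``"umol_l"``, the latter converted by a fixed nominal density of
    1.025 kg L⁻¹.  If ``pressure_column`` is given, depth is derived from
    pressure through ``pressure_to_depth`` (default 1 dbar ≈ 1 m).
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    concentration_unit: str = "umol_kg"
    pressure_column: str | None = None
    pressure_to_depth: Callable[[np.ndarray], np.ndarray] = staticmethod(lambda p: p)
    include_questionable: bool = True

    def source_name(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


@dataclass
class IngestReport:
    """Structured accounting of what ingestion kept, dropped and repaired.

    ``dropped`` categories partition the removed rows, so
    ``kept_rows + sum(dropped.values()) == input_rows`` always holds.
    ``modified`` counts in-place repairs on retained rows (e.g. negative
    concentrations set missing) and does not affect row conservation.
    """

    input_rows: int = 0
    kept_rows: int = 0
    n_casts: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    modified: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input_rows": self.input_rows,
            "kept_rows": self.kept_rows,
            "n_casts": self.n_casts,
            "dropped": dict(self.dropped),
            "modified": dict(self.modified),
        }


def _normalize_longitude(lon: np.ndarray) -> np.ndarray:
    """Wrap longitudes into [−180, 180); exact no-op on in-range values."""
    lon = np.asarray(lon, dtype=float)
    return np.where((lon >= -180.0) & (lon < 180.0), lon, ((lon + 180.0) % 360.0) - 180.0)


def read_casts(
    path, format_spec: ColumnMapping | None = None
) -> tuple[list[Cast], IngestReport]:
    """Read a bottle-cast table, validating rows against the canonical schema.

    Rows failing validation are dropped and counted per rule in the returned
    :class:`IngestReport`; samples flagged ``bad`` are excluded, negative
    concentrations become missing.  Duplicate depths within a cast are
    averaged.

    Raises
    ------
    ValueError
        If a required column cannot be mapped (the message lists the missing
        columns).
    """
    spec = format_spec or ColumnMapping()
    raw = pd.read_csv(
        path,
        dtype={spec.source_name("cast_id"): str},
        skipinitialspace=True,
        float_precision="round_trip",
    )

    rename = {spec.source_name(c): c for c in CANONICAL_COLUMNS if spec.source_name(c) in raw.columns}
    if spec.pressure_column is not None and spec.pressure_column in raw.columns:
        rename[spec.pressure_column] = "_pressure_dbar"
    df = raw.rename(columns=rename)

    required = ["cast_id", "date", "latitude", "longitude"]
    if spec.pressure_column is None:
        required.append("depth_m")
    elif "_pressure_dbar" not in df.columns:
        required.append(spec.pressure_column)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"input table is missing required columns: {missing}; "
            f"present columns: {list(raw.columns)}"
        )

    report = IngestReport(input_rows=len(df))
    drops = Counter()
    mods = Counter()

    if spec.pressure_column is not None:
        pressure = pd.to_numeric(df["_pressure_dbar"], errors="coerce")
        df["depth_m"] = np.asarray(spec.pressure_to_depth(pressure.to_numpy(dtype=float)))

    date = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    ok = date.notna()
    drops["invalid_date"] = int((~ok).sum())
    df, date = df[ok], date[ok]

    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    ok = lat.notna() & lon.notna() & (lat >= -90) & (lat <= 90)
    drops["invalid_coordinates"] = int((~ok).sum())
    df, date, lat, lon = df[ok], date[ok], lat[ok], lon[ok]

    depth = pd.to_numeric(df["depth_m"], errors="coerce")
    ok = depth.notna() & (depth >= 0)
    drops["invalid_depth"] = int((~ok).sum())
    df, date, lat, lon, depth = df[ok], date[ok], lat[ok], lon[ok], depth[ok]

    if "qc_flag" in df.columns:
        qc = df["qc_flag"].fillna(QC_GOOD).astype(str).str.strip().str.lower()
        qc = qc.replace({"": QC_GOOD, "nan": QC_GOOD})
    else:
        qc = pd.Series(QC_GOOD, index=df.index)
    bad = qc == QC_BAD
    drops["qc_bad"] = int(bad.sum())
    keep = ~bad
    if not spec.include_questionable:
        questionable = qc == QC_QUESTIONABLE
        drops["qc_questionable"] = int((questionable & keep).sum())
        keep &= ~questionable
    df, date, lat, lon, depth = df[keep], date[keep], lat[keep], lon[keep], depth[keep]

    out = pd.DataFrame(
        {
            "cast_id": df["cast_id"].astype(str),
            "date": date.dt.date.to_numpy(),
            "latitude": lat.to_numpy(dtype=float),
            "longitude": _normalize_longitude(lon.to_numpy(dtype=float)),
            "depth_m": depth.to_numpy(dtype=float),
        },
        index=df.index,
    )
    scale = 1.0 / NOMINAL_DENSITY_KG_L if spec.concentration_unit == "umol_l" else 1.0
    if spec.concentration_unit not in ("umol_kg", "umol_l"):
        raise ValueError(f"unknown concentration unit {spec.concentration_unit!r}")
    for col in ("nitrate_umol_kg", "phosphate_umol_kg", "temperature_c", "salinity_psu"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        else:
            vals = np.full(len(df), np.nan)
        if col in ("nitrate_umol_kg", "phosphate_umol_kg"):
            neg = vals < 0  # below-detection artifacts -> missing, not zero
            mods["negative_concentration"] += int(neg.sum())
            vals = np.where(neg, np.nan, vals * scale)
        out[col] = vals

    casts: list[Cast] = []
    for cast_id, grp in out.groupby("cast_id", sort=True):
        n_dup = len(grp) - grp["depth_m"].nunique()
        if n_dup:
            mods["duplicate_depth_merged"] += n_dup
        if grp["date"].nunique() > 1:
            mods["inconsistent_cast_date"] += 1
        agg = grp.groupby("depth_m", sort=True)[
            ["nitrate_umol_kg", "phosphate_umol_kg", "temperature_c", "salinity_psu"]
        ].mean()
        first = grp.iloc[0]
        casts.append(
            Cast(
                cast_id=str(cast_id),
                latitude=float(first["latitude"]),
                longitude=float(first["longitude"]),
                date=first["date"],
                depth=agg.index.to_numpy(dtype=float),
                nitrate=agg["nitrate_umol_kg"].to_numpy(),
                phosphate=agg["phosphate_umol_kg"].to_numpy(),
                temperature=agg["temperature_c"].to_numpy(),
                salinity=agg["salinity_psu"].to_numpy(),
            )
        )

    report.dropped = {k: v for k, v in drops.items() if v}
    report.modified = {k: v for k, v in mods.items() if v}
    report.kept_rows = report.input_rows - sum(report.dropped.values())
    report.n_casts = len(casts)
    return casts, report


def write_casts(casts: Iterable[Cast], path) -> None:
    """Write casts to the canonical CSV schema (one row per bottle)."""
    rows = []
    for cast in casts:
        for i in range(cast.n_samples):
            rows.append(
                (
                    cast.cast_id,
                    cast.date.isoformat(),
                    cast.latitude,
                    cast.longitude,
                    cast.depth[i],
                    cast.nitrate[i],
                    cast.phosphate[i],
                    cast.temperature[i],
                    cast.salinity[i],
                    QC_GOOD,
                )
            )
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Monthly climatology
# ---------------------------------------------------------------------------


class MonthlyClimatology:
    """Monthly gridded climatology on integer-degree (lat, lon) bins.

    Holds a nutricline-depth table and/or a concentration-profile table, both
    tidy DataFrames:

    * depths: ``lat_bin, lon_bin, month, nutrient, nutricline_depth_m``
    * profiles: ``lat_bin, lon_bin, month, nutrient, depth_m,
      concentration_umol_kg`` with a strictly increasing depth axis per cell

    Lookups return ``None`` for absent or all-missing cells, never zero.
    """

    def __init__(self, depths: pd.DataFrame | None = None, profiles: pd.DataFrame | None = None):
        if depths is None and profiles is None:
            raise ValueError("climatology needs a depth table or a profile table")
        for tab, name in ((depths, "depths"), (profiles, "profiles")):
            if tab is not None:
                months = tab["month"].to_numpy()
                if len(tab) and (months.min() < 1 or months.max() > 12):
                    raise ValueError(f"{name} table has months outside 1..12")
        self._depths = depths.reset_index(drop=True) if depths is not None else None
        self._profiles = profiles.reset_index(drop=True) if profiles is not None else None
        self._depth_index: dict | None = None
        self._profile_index: dict | None = None

    @property
    def depth_table(self) -> pd.DataFrame | None:
        return self._depths

    @property
    def profile_table(self) -> pd.DataFrame | None:
        return self._profiles

    @property
    def nutrients(self) -> tuple[str, ...]:
        nuts: list[str] = []
        for tab in (self._depths, self._profiles):
            if tab is not None:
                nuts.extend(tab["nutrient"].unique())
        return tuple(dict.fromkeys(nuts))

    def _build_depth_index(self) -> dict:
        if self._depth_index is None:
            self._depth_index = {}
            if self._depths is not None:
                for row in self._depths.itertuples(index=False):
                    key = (int(row.lat_bin), int(row.lon_bin), int(row.month), row.nutrient)
                    self._depth_index[key] = float(row.nutricline_depth_m)
        return self._depth_index

    def nutricline_depth(self, lat_bin: int, lon_bin: int, month: int, nutrient: str) -> float | None:
        val = self._build_depth_index().get((int(lat_bin), int(lon_bin), int(month), nutrient))
        if val is None or np.isnan(val):
            return None
        return val

    def profile(
        self, lat_bin: int, lon_bin: int, month: int, nutrient: str
    ) -> tuple[np.ndarray, np.ndarray] | None:
        if self._profile_index is None:
            self._profile_index = {}
            if self._profiles is not None:
                grp = self._profiles.groupby(["lat_bin", "lon_bin", "month", "nutrient"], sort=False)
                for key, sub in grp:
                    sub = sub.sort_values("depth_m")
                    z = sub["depth_m"].to_numpy(dtype=float)
                    if np.any(np.diff(z) <= 0):
                        raise ValueError(f"profile depth axis not strictly increasing at {key}")
                    self._profile_index[(int(key[0]), int(key[1]), int(key[2]), key[3])] = (
                        z,
                        sub["concentration_umol_kg"].to_numpy(dtype=float),
                    )
        got = self._profile_index.get((int(lat_bin), int(lon_bin), int(month), nutrient))
        if got is None or np.all(np.isnan(got[1])):
            return None
        return got


def write_climatology(clim: MonthlyClimatology, path) -> None:
    """Write a climatology as a single long-format CSV.

    Depth rows carry ``kind='depth'`` and ``nutricline_depth_m``; profile rows
    carry ``kind='profile'`` with ``depth_m`` and ``concentration_umol_kg``.
    """
    parts = []
    if clim.depth_table is not None:
        d = clim.depth_table.copy()
        d["kind"] = "depth"
        parts.append(d)
    if clim.profile_table is not None:
        p = clim.profile_table.copy()
        p["kind"] = "profile"
        parts.append(p)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def write_climatology_netcdf(clim: MonthlyClimatology, path) -> None:
    """Write the climatology to NetCDF with dims (lat, lon, month[, depth])."""
    import xarray as xr

    data_vars = {}
    coords: dict = {}
    if clim.depth_table is not None:
        d = clim.depth_table
        da = d.set_index(["lat_bin", "lon_bin", "month", "nutrient"])["nutricline_depth_m"]
        arr = da.to_xarray().rename({"lat_bin": "lat", "lon_bin": "lon"})
        for nut in d["nutrient"].unique():
            data_vars[f"{nut}_nutricline_depth_m"] = arr.sel(nutrient=nut, drop=True)
    if clim.profile_table is not None:
        p = clim.profile_table
        da = p.set_index(["lat_bin", "lon_bin", "month", "nutrient", "depth_m"])[
            "concentration_umol_kg"
        ]
        arr = da.to_xarray().rename({"lat_bin": "lat", "lon_bin": "lon", "depth_m": "depth"})
        for nut in p["nutrient"].unique():
            data_vars[f"{nut}_concentration_umol_kg"] = arr.sel(nutrient=nut, drop=True)
    xr.Dataset(data_vars, coords=coords).to_netcdf(path, engine="scipy")


def _climatology_from_netcdf(path) -> MonthlyClimatology:
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    if "month" not in ds.dims:
        raise ValueError(f"climatology {path} has no 'month' axis")
    depth_frames, profile_frames = [], []
    for var in ds.data_vars:
        if var.endswith("_nutricline_depth_m"):
            nut = var[: -len("_nutricline_depth_m")]
            df = ds[var].to_dataframe().reset_index().rename(
                columns={"lat": "lat_bin", "lon": "lon_bin", var: "nutricline_depth_m"}
            )
            df["nutrient"] = nut
            depth_frames.append(df.dropna(subset=["nutricline_depth_m"]))
        elif var.endswith("_concentration_umol_kg"):
            nut = var[: -len("_concentration_umol_kg")]
            df = ds[var].to_dataframe().reset_index().rename(
                columns={"lat": "lat_bin", "lon": "lon_bin", "depth": "depth_m", var: "concentration_umol_kg"}
            )
            df["nutrient"] = nut
            profile_frames.append(df.dropna(subset=["concentration_umol_kg"]))
    return MonthlyClimatology(
        depths=pd.concat(depth_frames, ignore_index=True) if depth_frames else None,
        profiles=pd.concat(profile_frames, ignore_index=True) if profile_frames else None,
    )


def read_climatology(path) -> MonthlyClimatology:
    """Read a climatology from long-format CSV or NetCDF (by extension)."""
    if str(path).endswith((".nc", ".cdf", ".netcdf")):
        return _climatology_from_netcdf(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "month" not in df.columns:
        raise ValueError(f"climatology {path} has no 'month' column")
    if "kind" in df.columns:
        depth_rows = df[df["kind"] == "depth"]
        profile_rows = df[df["kind"] == "profile"]
    else:
        has_depth = "nutricline_depth_m" in df.columns
        depth_rows = df[df["nutricline_depth_m"].notna()] if has_depth else df.iloc[0:0]
        profile_rows = df[df["depth_m"].notna()] if "depth_m" in df.columns else df.iloc[0:0]
    depths = (
        depth_rows[["lat_bin", "lon_bin", "month", "nutrient", "nutricline_depth_m"]]
        if len(depth_rows)
        else None
    )
    profiles = (
        profile_rows[["lat_bin", "lon_bin", "month", "nutrient", "depth_m", "concentration_umol_kg"]]
        if len(profile_rows)
        else None
    )
    return MonthlyClimatology(depths=depths, profiles=profiles)
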