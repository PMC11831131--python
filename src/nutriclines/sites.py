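"""1°-site assignment, annual averaging and trend-eligibility filters.

Cast coordinates are rounded to the nearest integer degree
(half-away-from-zero; longitude 180 wraps to −180), and nutricline depths are
averaged per (site, nutrient, calendar year).  Temporal trends are then fit
only to annual means deeper than 50 m at sites between 45°S and 45°N, which
keeps the analysis in nutrient-limited waters and away from mixed-layer
variability.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Site",
    "assign_site",
    "assign_sites",
    "annual_average",
    "filter_trend_eligible",
    "DEFAULT_MIN_DEPTH",
    "DEFAULT_LAT_RANGE",
]

DEFAULT_MIN_DEPTH = 50.0
DEFAULT_LAT_RANGE = (-45.0, 45.0)

Site = tuple[int, int]  # (lat_bin, lon_bin), integer degrees


def _round_half_away(x):
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def assign_site(latitude: float, longitude: float) -> Site:
    """Round coordinates to the nearest integer degree.

    Rounding is half-away-from-zero on each coordinate; longitude is first
    normalized to [−180, 180) and a rounded value of 180 wraps to −180, so
    every valid coordinate maps to exactly one site with
    lat_bin ∈ [−90, 90] and lon_bin ∈ [−180, 179].
    """
    if not (-90.0 <= latitude <= 90.0) or not np.isfinite(longitude):
        raise ValueError(f"invalid coordinates ({latitude}, {longitude})")
    lon = longitude if -180.0 <= longitude < 180.0 else ((longitude + 180.0) % 360.0) - 180.0
    lat_bin = int(_round_half_away(latitude))
    lon_bin = int(_round_half_away(lon))
    if lon_bin == 180:
        lon_bin = -180
    return lat_bin, lon_bin


def assign_sites(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized site assignment; adds ``lat_bin``/``lon_bin`` columns."""
    lat = frame["latitude"].to_numpy(dtype=float)
    if np.any((lat < -90) | (lat > 90)) or np.any(~np.isfinite(frame["longitude"].to_numpy(dtype=float))):
        raise ValueError("coordinates out of range")
    raw_lon = frame["longitude"].to_numpy(dtype=float)
    lon = np.where((raw_lon >= -180.0) & (raw_lon < 180.0), raw_lon, ((raw_lon + 180.0) % 360.0) - 180.0)
    out = frame.copy()
    out["lat_bin"] = _round_half_away(lat).astype(int)
    lon_bin = _round_half_away(lon).astype(int)
    out["lon_bin"] = np.where(lon_bin == 180, -180, lon_bin)
    return out


def annual_average(
    records: pd.DataFrame, value_cols: Sequence[str] = ("depth",)
) -> pd.DataFrame:
    """Annually averaged nutricline depths per (site, nutrient, year).

    Records with undefined depth (status ``never_reached`` /
    ``insufficient_data``) are excluded before averaging.  Returns one row
    per site × nutrient × calendar year with ``mean_<col>`` for each value
    column and ``n_casts``.  Grouping also splits by ``threshold`` when the
    column is present, so multi-threshold record frames never pool.
    """
    df = records
    if "lat_bin" not in df.columns:
        df = assign_sites(df)
    df = df[df["depth"].notna()]
    keys = ["lat_bin", "lon_bin", "nutrient", "year"]
    if "threshold" in df.columns:
        keys.insert(2, "threshold")
    agg = {f"mean_{c}": (c, "mean") for c in value_cols}
    out = df.groupby(keys, sort=True).agg(n_casts=("depth", "size"), **agg).reset_index()
    return out


def filter_trend_eligible(
    series: pd.DataFrame,
    min_depth: float = DEFAULT_MIN_DEPTH,
    lat_range: tuple[float, float] = DEFAULT_LAT_RANGE,
    depth_col: str = "mean_depth",
) -> pd.DataFrame:
    """Apply the trend-eligibility filters to annual site series.

    Drops annual points whose mean depth is not strictly deeper than
    ``min_depth`` and whole series at sites outside ``lat_range``
    (inclusive bounds).
    """
    keep = series[depth_col] > min_depth
    keep &= (series["lat_bin"] >= lat_range[0]) & (series["lat_bin"] <= lat_range[1])
    return series[keep].reset_index(drop=True)
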