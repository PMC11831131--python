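"""Global and site-specific nutricline trends with robustness statistics.

The central quantities are the site-specific temporal trends of annually
averaged nutricline depth — T_NO3 for the nitracline and T_PO4 for the
phosphacline, in m y⁻¹ — summarized by their median with a percentile
bootstrap confidence interval over sites.  Around these sit the supporting
analyses: pooled global regressions, seasonal-anomaly correction against a
monthly climatology, the paired Z_NO3 − Z_PO4 residual trend, the signed
orthogonal distance of (T_NO3, T_PO4) from the 1:1 line, density-at-nutricline
trends, nonparametric significance tests, regional medians and the deep-water
concentration-bias diagnostic.

All p-values are two-sided and reported per analysis without multiple-testing
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import linear_eos, density_at_depth
from .io_profiles import Cast, MonthlyClimatology
from .sites import (
    DEFAULT_LAT_RANGE,
    DEFAULT_MIN_DEPTH,
    annual_average,
    assign_sites,
)

__all__ = [
    "GlobalFit",
    "MedianTrendSummary",
    "RegionSpec",
    "fit_global_regression",
    "fit_site_trends",
    "median_with_bootstrap_ci",
    "seasonal_anomaly",
    "paired_residual_trend",
    "residual_tpo4",
    "sign_test",
    "kruskal_wallis",
    "density_trends",
    "regional_medians",
    "filter_extreme_trends",
    "deep_anomaly_trend",
]


@dataclass(frozen=True)
class GlobalFit:
    """Pooled OLS fit of depth (or anomaly) on calendar year."""

    slope: float
    slope_se: float
    p_value: float
    n_points: int
    intercept: float


@dataclass(frozen=True)
class MedianTrendSummary:
    """Median of site trends with a percentile bootstrap CI over sites."""

    median: float
    ci_low: float
    ci_high: float
    n_sites: int
    n_bootstrap: int
    seed: int
    quantity: str = ""
    insufficient: bool = False


@dataclass(frozen=True)
class RegionSpec:
    """A named union of (lat, lon) boxes; bounds inclusive."""

    name: str
    boxes: tuple[tuple[tuple[float, float], tuple[float, float]], ...]

    def __post_init__(self) -> None:
        if not self.boxes:
            raise ValueError(f"region {self.name!r} has no boxes")

    def contains(self, lat, lon) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        mask = np.zeros(lat.shape, dtype=bool)
        for (lat_lo, lat_hi), (lon_lo, lon_hi) in self.boxes:
            mask |= (lat >= lat_lo) & (lat <= lat_hi) & (lon >= lon_lo) & (lon <= lon_hi)
        return mask


def fit_global_regression(series: pd.DataFrame, value_col: str = "mean_depth") -> GlobalFit:
    """OLS of annual mean depth on year, pooled over all sites.

    Annual points are unweighted.  Requires at least 3 pooled points.
    Degenerate exact fits (zero residual variance) get p = 1 for a zero slope
    and p = 0 otherwise.
    """
    x = series["year"].to_numpy(dtype=float)
    y = series[value_col].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError(f"global regression needs >= 3 points, got {x.size}")
    if np.ptp(y) == 0.0:
        return GlobalFit(0.0, 0.0, 1.0, x.size, float(y[0]))
    res = stats.linregress(x, y)
    p = res.pvalue
    if res.stderr == 0.0:  # exactly collinear points
        p = 0.0 if res.slope != 0.0 else 1.0
    return GlobalFit(float(res.slope), float(res.stderr), float(p), int(x.size), float(res.intercept))


def fit_site_trends(
    series: pd.DataFrame,
    value_col: str = "mean_depth",
    quantity: str | None = None,
    weight_sqrt_n: bool = False,
) -> pd.DataFrame:
    """Per-site OLS slope of annual mean depth versus calendar year.

    Sites with fewer than two annual points are skipped; the number skipped
    is recorded in ``result.attrs['n_sites_skipped']``.  Slopes are computed
    from the closed-form normal equations with the year centered per site.
    Setting ``weight_sqrt_n`` weights annual points by √n_casts.

    Returns a frame with columns ``lat_bin, lon_bin, [nutrient, threshold,]
    quantity, slope, intercept, n_years``.
    """
    keys = ["lat_bin", "lon_bin"]
    for extra in ("nutrient", "threshold"):
        if extra in series.columns:
            keys.append(extra)
    df = series[keys].copy()
    x = series["year"].to_numpy(dtype=float)
    y = series[value_col].to_numpy(dtype=float)
    w = np.sqrt(series["n_casts"].to_numpy(dtype=float)) if weight_sqrt_n else np.ones_like(x)
    df["_w"] = w
    df["_wx"] = w * x
    df["_wy"] = w * y
    df["_wxx"] = w * x * x
    df["_wxy"] = w * x * y
    g = df.groupby(keys, sort=True)[["_w", "_wx", "_wy", "_wxx", "_wxy"]].sum()
    n_years = df.groupby(keys, sort=True).size()
    sw, sx, sy, sxx, sxy = (g[c].to_numpy() for c in ("_w", "_wx", "_wy", "_wxx", "_wxy"))
    denom = sw * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sw * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / sw
    out = g.reset_index()[keys]
    out["quantity"] = quantity if quantity is not None else out.get("nutrient", "")
    out["slope"] = slope
    out["intercept"] = intercept
    out["n_years"] = n_years.to_numpy()
    kept = (out["n_years"] >= 2) & np.isfinite(out["slope"])
    result = out[kept].reset_index(drop=True)
    result.attrs["n_sites_skipped"] = int((~kept).sum())
    return result


def _slopes_array(trends) -> np.ndarray:
    if isinstance(trends, pd.DataFrame):
        return trends["slope"].to_numpy(dtype=float)
    return np.asarray(trends, dtype=float)


def median_with_bootstrap_ci(
    trends,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    quantity: str = "",
    ci: float = 0.95,
) -> MedianTrendSummary:
    """Median of site trends with a percentile bootstrap CI.

    Sites are resampled with replacement ``n_bootstrap`` times — the site is
    the exchangeable unit — and the CI is the (2.5, 97.5) percentile range of
    the resampled medians.  Reproducible given ``seed``.
    """
    slopes = _slopes_array(trends)
    if slopes.size < 2:
        raise ValueError("median_with_bootstrap_ci needs >= 2 trends")
    rng = np.random.default_rng(seed)
    n = slopes.size
    meds = np.empty(n_bootstrap)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n_bootstrap, chunk):
        stop = min(start + chunk, n_bootstrap)
        idx = rng.integers(0, n, size=(stop - start, n))
        meds[start:stop] = np.median(slopes[idx], axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(meds, [100 * alpha, 100 * (1 - alpha)])
    return MedianTrendSummary(
        median=float(np.median(slopes)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_sites=int(n),
        n_bootstrap=int(n_bootstrap),
        seed=int(seed),
        quantity=quantity,
    )


def seasonal_anomaly(
    records: pd.DataFrame, clim: MonthlyClimatology
) -> tuple[pd.DataFrame, int]:
    """Subtract the monthly climatological nutricline depth from each record.

    Adds a ``depth_anomaly`` column (observed − climatology for that site and
    month) while keeping the raw ``depth`` — downstream, the >50 m
    trend-eligibility filter must keep using raw depths, since anomalies are
    near zero by construction.  Records whose (site, month) is missing from
    the climatology are dropped; the count is returned alongside.
    """
    if clim.depth_table is None:
        raise ValueError("climatology has no nutricline-depth table")
    df = records[records["depth"].notna()]
    if "lat_bin" not in df.columns:
        df = assign_sites(df)
    merged = df.merge(
        clim.depth_table.rename(columns={"nutricline_depth_m": "_clim_depth"}),
        on=["lat_bin", "lon_bin", "month", "nutrient"],
        how="left",
    )
    ok = merged["_clim_depth"].notna()
    n_dropped = int((~ok).sum())
    out = merged[ok].copy()
    out["depth_anomaly"] = out["depth"] - out["_clim_depth"]
    out = out.drop(columns="_clim_depth").reset_index(drop=True)
    return out, n_dropped


def paired_residual_trend(
    records_no3: pd.DataFrame,
    records_po4: pd.DataFrame,
    min_depth: float = DEFAULT_MIN_DEPTH,
    lat_range: tuple[float, float] = DEFAULT_LAT_RANGE,
) -> pd.DataFrame:
    """Site trends of the per-cast paired difference Z_NO3 − Z_PO4.

    Casts are paired by ``cast_id`` and used only where both crossing depths
    are defined and both are strictly deeper than ``min_depth``.  Differences
    are averaged annually per site and fit exactly like depth trends; the
    resulting quantity id is ``"ZNO3_minus_ZPO4"``.  A negative median slope
    means the phosphacline is deepening faster than the nitracline.
    """
    left = records_no3[records_no3["depth"].notna()][
        ["cast_id", "depth", "latitude", "longitude", "year", "month"]
    ].rename(columns={"depth": "z_no3"})
    right = records_po4[records_po4["depth"].notna()][["cast_id", "depth"]].rename(
        columns={"depth": "z_po4"}
    )
    pairs = left.merge(right, on="cast_id", how="inner")
    pairs = pairs[(pairs["z_no3"] > min_depth) & (pairs["z_po4"] > min_depth)]
    pairs = assign_sites(pairs)
    pairs = pairs[(pairs["lat_bin"] >= lat_range[0]) & (pairs["lat_bin"] <= lat_range[1])]
    pairs["depth"] = pairs["z_no3"] - pairs["z_po4"]
    pairs["nutrient"] = "difference"
    series = annual_average(pairs[["lat_bin", "lon_bin", "nutrient", "year", "depth"]])
    return fit_site_trends(series, quantity="ZNO3_minus_ZPO4")


def residual_tpo4(t_no3, t_po4):
    """Signed orthogonal distance of (T_NO3, T_PO4) from the T_PO4 = T_NO3 line.

    Equals (T_PO4 − T_NO3)/√2; positive when the phosphacline deepens faster
    than the nitracline.  Antisymmetric under swapping the arguments and zero
    on the diagonal.
    """
    return (np.asarray(t_po4, dtype=float) - np.asarray(t_no3, dtype=float)) / np.sqrt(2.0)


def sign_test(trends) -> float:
    """Exact two-sided binomial sign test on positive vs negative slopes.

    Zero slopes are dropped.  Returns ``nan`` when no nonzero slopes remain
    (the test is undefined).
    """
    slopes = _slopes_array(trends)
    pos = int(np.count_nonzero(slopes > 0))
    neg = int(np.count_nonzero(slopes < 0))
    n = pos + neg
    if n == 0:
        warnings.warn("sign test undefined: all slopes are zero")
        return float("nan")
    return float(stats.binomtest(pos, n, 0.5, alternative="two-sided").pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal–Wallis rank test with tie correction and χ² p-value.

    Each group must contain at least two values.  When every value across all
    groups is identical there is trivially no group effect: (H, p) = (0, 1).
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def density_trends(
    casts: Sequence[Cast],
    records: pd.DataFrame,
    eos: Callable = linear_eos,
    min_depth: float = DEFAULT_MIN_DEPTH,
    lat_range: tuple[float, float] = DEFAULT_LAT_RANGE,
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> dict[str, tuple[MedianTrendSummary | None, int]]:
    """Median trends of water density at the nutricline depth, per nutrient.

    For every record with a defined crossing depth passing the standard
    eligibility filters, T and S are interpolated to the crossing and
    converted to a density anomaly by ``eos``; the density values then run
    through the same annual-average / site-trend / bootstrap-median machinery
    (quantity id ``density_at_Z<NUTRIENT>``).  Returns per nutrient a
    ``(summary, n_missing_density)`` pair, with ``summary=None`` when fewer
    than two sites yield trends.
    """
    cast_by_id = {c.cast_id: c for c in casts}
    out: dict[str, tuple[MedianTrendSummary | None, int]] = {}
    eligible = records[records["depth"].notna() & (records["depth"] > min_depth)]
    eligible = assign_sites(eligible)
    eligible = eligible[
        (eligible["lat_bin"] >= lat_range[0]) & (eligible["lat_bin"] <= lat_range[1])
    ]
    for nutrient, sub in eligible.groupby("nutrient"):
        dens = np.array(
            [
                density_at_depth(cast_by_id[cid], z, eos=eos)
                for cid, z in zip(sub["cast_id"], sub["depth"])
            ]
        )
        n_missing = int(np.isnan(dens).sum())
        vals = sub.copy()
        vals["depth"] = dens  # reuse the depth pipeline on density values
        vals = vals[np.isfinite(dens)]
        quantity = f"density_at_Z{'NO3' if nutrient == 'nitrate' else 'PO4'}"
        if len(vals) == 0:
            out[nutrient] = (None, n_missing)
            continue
        series = annual_average(vals[["lat_bin", "lon_bin", "nutrient", "year", "depth"]])
        trend_tab = fit_site_trends(series, quantity=quantity)
        if len(trend_tab) < 2:
            out[nutrient] = (None, n_missing)
        else:
            out[nutrient] = (
                median_with_bootstrap_ci(trend_tab, n_bootstrap=n_bootstrap, seed=seed, quantity=quantity),
                n_missing,
            )
    return out


def regional_medians(
    trends: pd.DataFrame,
    regions: Sequence[RegionSpec],
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> dict[str, MedianTrendSummary]:
    """Bootstrap median trend per region (hemispheres, basins, gyres...).

    Regions with fewer than two member sites are flagged ``insufficient``
    with an undefined median rather than a fabricated number.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(len(regions)) % (2**31)
    out: dict[str, MedianTrendSummary] = {}
    for region, sub_seed in zip(regions, child_seeds):
        mask = region.contains(trends["lat_bin"], trends["lon_bin"])
        sub = trends[mask]
        if len(sub) < 2:
            out[region.name] = MedianTrendSummary(
                median=float("nan"),
                ci_low=float("nan"),
                ci_high=float("nan"),
                n_sites=int(len(sub)),
                n_bootstrap=0,
                seed=int(sub_seed),
                quantity=region.name,
                insufficient=True,
            )
        else:
            out[region.name] = median_with_bootstrap_ci(
                sub, n_bootstrap=n_bootstrap, seed=int(sub_seed), quantity=region.name
            )
    return out


def filter_extreme_trends(
    trends: pd.DataFrame, bounds: tuple[float, float]
) -> tuple[pd.DataFrame, int]:
    """Drop site trends outside ``bounds`` (m y⁻¹); returns (kept, n_removed).

    Used to exclude slopes beyond what high-resolution time series suggest is
    physically feasible.
    """
    lo, hi = bounds
    keep = (trends["slope"] >= lo) & (trends["slope"] <= hi)
    return trends[keep].reset_index(drop=True), int((~keep).sum())


def deep_anomaly_trend(
    casts: Sequence[Cast],
    clim: MonthlyClimatology,
    min_depth: float = 1000.0,
    nutrients: Sequence[str] = ("nitrate", "phosphate"),
) -> dict[str, GlobalFit | None]:
    """Temporal trend of deep-water concentration anomalies (bias diagnostic).

    Below ``min_depth`` nutrient concentrations should be climatologically
    stable, so a systematic trend in (observed − climatology) there indicates
    drifting measurement methods rather than real change.  Per cast, observed
    concentrations are interpolated onto the climatology's standard depths
    below ``min_depth`` (within the sampled range), the climatological profile
    is subtracted, and the pooled anomalies are regressed on decimal year.
    Returns ``None`` for a nutrient with fewer than 3 anomaly points.
    """
    if clim.profile_table is None:
        raise ValueError("deep_anomaly_trend needs a concentration-profile climatology")
    from .sites import assign_site

    results: dict[str, GlobalFit | None] = {}
    for nutrient in nutrients:
        years: list[float] = []
        anoms: list[float] = []
        for cast in casts:
            vals = cast.values_for(nutrient)
            good = ~np.isnan(vals)
            z_obs, v_obs = cast.depth[good], vals[good]
            if z_obs.size < 2 or z_obs.max() <= min_depth:
                continue
            site = assign_site(cast.latitude, cast.longitude)
            prof = clim.profile(site[0], site[1], cast.date.month, nutrient)
            if prof is None:
                continue
            z_clim, c_clim = prof
            sel = (z_clim > min_depth) & (z_clim >= z_obs.min()) & (z_clim <= z_obs.max())
            sel &= ~np.isnan(c_clim)
            if not sel.any():
                continue
            interp = np.interp(z_clim[sel], z_obs, v_obs)
            t = cast.date.year + (cast.date.month - 0.5) / 12.0
            for a in interp - c_clim[sel]:
                years.append(t)
                anoms.append(float(a))
        if len(anoms) < 3:
            results[nutrient] = None
            continue
        x = np.asarray(years)
        y = np.asarray(anoms)
        if np.ptp(y) == 0.0:
            results[nutrient] = GlobalFit(0.0, 0.0, 1.0, y.size, float(y[0]))
            continue
        res = stats.linregress(x, y)
        results[nutrient] = GlobalFit(
            float(res.slope), float(res.stderr), float(res.pvalue), int(y.size), float(res.intercept)
        )
    return results
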