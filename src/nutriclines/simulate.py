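"""Synthetic cruise-archive generator with analytically known ground truth.

Emulates the statistical structure the trend analysis assumes in a real
multi-decadal archive: sparse, irregularly timed station occupations at
1°-degree sites, a seasonal cycle in nutricline depth, site-level long-term
linear depth trends drawn from a configurable normal distribution,
bottle-level analytical noise, and coupled nitrate/phosphate profiles whose
crossing depths can diverge over time.

For site *s*, nutrient *n*, decimal year *t* and month *m*, the true crossing
depth is

    Z_s,n(t, m) = Z0_s + A · cos(2π (m − φ)/12) + b_s,n · (t − t₀)

with b drawn per site per nutrient.  The concentration profile of each cast
is a logistic saturating curve positioned so that it crosses the generating
threshold exactly at Z — giving the oracle a closed form — and phosphate is
nitrate/16 whenever the two crossing depths coincide (strict Redfield
coupling), diverging smoothly as the crossing depths separate.

The ground truth (every Z and every b) is emitted as a sidecar table keyed by
cast id so that tests never re-derive it from generator internals.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import REDFIELD_N_TO_P
from .io_profiles import Cast, MonthlyClimatology
from .nulls import ErrorModel, TrendDistribution

__all__ = [
    "TwoLayerTS",
    "SyntheticWorldConfig",
    "generate_archive",
    "generate_climatology",
    "schedule_from_casts",
]

# 15 m resolution through the nutricline zone (26 levels total, the scale of
# a modern rosette cast); with the default 50 m transition width this keeps
# the piecewise-linear crossing within 0.5 m of the analytic crossing.
DEFAULT_BOTTLE_DEPTHS = tuple(float(z) for z in range(0, 256, 15)) + (
    300.0, 400.0, 500.0, 700.0, 1000.0, 1250.0, 1500.0, 1750.0, 2000.0,
)


@dataclass(frozen=True)
class TwoLayerTS:
    """Two-layer temperature/salinity column with a smooth logistic interface.

    With ``pycnocline_follows_nutricline`` the interface sits at each cast's
    true nitracline depth, locking the nutricline to a fixed isopycnal (the
    density at the crossing is then time-invariant); otherwise the interface
    is fixed at ``interface_depth`` and a migrating nutricline crosses into
    different density layers.
    """

    t_surface: float = 22.0
    t_deep: float = 4.0
    s_surface: float = 35.5
    s_deep: float = 34.6
    interface_depth: float = 120.0
    interface_width: float = 30.0
    pycnocline_follows_nutricline: bool = False


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Study conditions for a synthetic cruise archive.

    Defaults describe a five-decade (1972–2022) archive of tropical /
    subtropical sampling at real cruise-archive density — about 0.07 casts
    per site-year, i.e. a typical 1° site is occupied in only a handful of
    distinct years — with a 20 m seasonal nutricline cycle and site trends
    drawn from the distributions that reproduce observed global trend
    statistics: nitracline N(−0.63, 1.5²) m y⁻¹, phosphacline
    N(+0.20, 1.0²) m y⁻¹.
    """

    n_sites: int = 100
    lat_range: tuple[float, float] = (-40.0, 40.0)
    lon_range: tuple[float, float] = (-180.0, 179.0)
    years: tuple[int, int] = (1972, 2022)
    casts_per_site_year: float = 0.07
    month_weights: tuple[float, ...] | None = None
    baseline_depth_range: tuple[float, float] = (70.0, 200.0)
    seasonal_amplitude: float = 20.0
    seasonal_phase: float = 8.0  # month of deepest nutricline
    trend_dist_no3: TrendDistribution = TrendDistribution(-0.63, 1.5)
    trend_dist_po4: TrendDistribution = TrendDistribution(0.20, 1.0)
    redfield_coupled: bool = False
    deep_concentration: float = 35.0  # deep nitrate, µmol kg⁻¹
    transition_width: float = 50.0
    threshold: float = 3.0  # nitrate threshold anchoring the profiles
    bottle_depths: tuple[float, ...] = DEFAULT_BOTTLE_DEPTHS
    noise: ErrorModel = ErrorModel(nitrate_sd=0.1, phosphate_sd=0.01)
    deep_drift: float = 0.0  # µmol kg⁻¹ y⁻¹ added below 1000 m
    ts: TwoLayerTS = TwoLayerTS()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.casts_per_site_year <= 0:
            raise ValueError("counts must be positive")
        if self.years[1] - self.years[0] < 1:
            raise ValueError("year span must cover at least 2 years")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")
        if not 0 < self.threshold < self.deep_concentration:
            raise ValueError("threshold must lie strictly between 0 and deep_concentration")

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.years[0] + self.years[1]) + 0.5


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _concentration(z, crossing, c_deep, threshold, width):
    """Logistic profile C(z) = C_deep·σ((z−m)/w) with C(crossing) = threshold."""
    m = crossing + width * np.log((c_deep - threshold) / threshold)
    return c_deep * _logistic((np.asarray(z, dtype=float) - m) / width)


def _seasonal(month, amplitude, phase):
    return amplitude * np.cos(2.0 * np.pi * (month - phase) / 12.0)


def _true_depth(cfg, z0, b, year, month):
    t = year + (month - 0.5) / 12.0
    z = z0 + _seasonal(month, cfg.seasonal_amplitude, cfg.seasonal_phase) + b * (t - cfg.t_mid)
    return max(float(z), 10.0)  # keep crossings below the surface


def generate_archive(cfg: SyntheticWorldConfig) -> tuple[list[Cast], pd.DataFrame]:
    """Generate a cruise archive and its ground-truth sidecar table.

    Returns ``(casts, truth)`` where ``truth`` has one row per cast with the
    analytic crossing depths (``z_no3_true``, ``z_po4_true``), the drawn
    site trends (``b_no3``, ``b_po4``) and the site baseline ``z0``.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lat_lo, lat_hi = cfg.lat_range
    lon_lo, lon_hi = cfg.lon_range
    lat_bins = np.arange(int(np.ceil(lat_lo)), int(np.floor(lat_hi)) + 1)
    lon_bins = np.arange(int(np.ceil(lon_lo)), int(np.floor(lon_hi)) + 1)
    grid = np.array([(la, lo) for la in lat_bins for lo in lon_bins])
    if cfg.n_sites > len(grid):
        raise ValueError(f"n_sites={cfg.n_sites} exceeds {len(grid)} grid cells")
    sites = grid[rng.choice(len(grid), size=cfg.n_sites, replace=False)]

    z0 = rng.uniform(*cfg.baseline_depth_range, size=cfg.n_sites)
    b_no3 = rng.normal(cfg.trend_dist_no3.mean, cfg.trend_dist_no3.sd, cfg.n_sites)
    if cfg.redfield_coupled:
        b_po4 = b_no3.copy()
    else:
        b_po4 = rng.normal(cfg.trend_dist_po4.mean, cfg.trend_dist_po4.sd, cfg.n_sites)

    months = np.arange(1, 13)
    weights = np.asarray(cfg.month_weights, dtype=float) if cfg.month_weights else np.ones(12)
    weights = weights / weights.sum()
    depths = np.asarray(cfg.bottle_depths, dtype=float)
    p_threshold = cfg.threshold / REDFIELD_N_TO_P
    deep = depths > 1000.0

    casts: list[Cast] = []
    truth_rows = []
    years = np.arange(cfg.years[0], cfg.years[1] + 1)
    cast_counter = 0
    for s in range(cfg.n_sites):
        lat_bin, lon_bin = int(sites[s, 0]), int(sites[s, 1])
        n_per_year = rng.poisson(cfg.casts_per_site_year, size=years.size)
        for year, n_casts in zip(years, n_per_year):
            for _ in range(int(n_casts)):
                month = int(rng.choice(months, p=weights))
                day = int(rng.integers(1, 29))
                lat = lat_bin + rng.uniform(-0.49, 0.49)
                lon = lon_bin + rng.uniform(-0.49, 0.49)
                t = year + (month - 0.5) / 12.0

                z_no3 = _true_depth(cfg, z0[s], b_no3[s], year, month)
                z_po4 = z_no3 if cfg.redfield_coupled else _true_depth(cfg, z0[s], b_po4[s], year, month)

                nit = _concentration(depths, z_no3, cfg.deep_concentration, cfg.threshold, cfg.transition_width)
                pho = _concentration(
                    depths, z_po4, cfg.deep_concentration / REDFIELD_N_TO_P, p_threshold, cfg.transition_width
                )
                if cfg.deep_drift != 0.0:
                    drift = cfg.deep_drift * (t - cfg.t_mid)
                    nit = nit + np.where(deep, drift, 0.0)
                    pho = pho + np.where(deep, drift, 0.0)
                if cfg.noise.nitrate_sd > 0:
                    nit = nit + rng.normal(0.0, cfg.noise.nitrate_sd, depths.size)
                if cfg.noise.phosphate_sd > 0:
                    pho = pho + rng.normal(0.0, cfg.noise.phosphate_sd, depths.size)
                nit = np.maximum(nit, 0.0)
                pho = np.maximum(pho, 0.0)

                zi = z_no3 if cfg.ts.pycnocline_follows_nutricline else cfg.ts.interface_depth
                frac = _logistic(-(depths - zi) / cfg.ts.interface_width)
                temp = cfg.ts.t_deep + (cfg.ts.t_surface - cfg.ts.t_deep) * frac
                sal = cfg.ts.s_deep + (cfg.ts.s_surface - cfg.ts.s_deep) * frac

                cast_id = f"syn-{cast_counter:07d}"
                cast_counter += 1
                casts.append(
                    Cast(
                        cast_id=cast_id,
                        latitude=float(lat),
                        longitude=float(lon),
                        date=dt.date(int(year), month, day),
                        depth=depths.copy(),
                        nitrate=nit,
                        phosphate=pho,
                        temperature=temp,
                        salinity=sal,
                    )
                )
                truth_rows.append(
                    (cast_id, lat_bin, lon_bin, int(year), month, t, z0[s], b_no3[s], b_po4[s], z_no3, z_po4)
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "cast_id", "lat_bin", "lon_bin", "year", "month", "t",
            "z0", "b_no3", "b_po4", "z_no3_true", "z_po4_true",
        ],
    )
    return casts, truth


def generate_climatology(
    cfg: SyntheticWorldConfig, include_profiles: bool = True
) -> MonthlyClimatology:
    """Analytic monthly climatology of the synthetic world at its trend-free baseline.

    Per (site, month): mean nutricline depth Z0_s + A·cos(2π(m − φ)/12) for
    both nutrients (b = 0, t = t₀), plus — unless disabled — the matching
    concentration profiles on the bottle-depth axis.  Sites and baselines are
    re-drawn from ``cfg.seed`` with the exact streams the archive generator
    uses, so the climatology matches the archive site for site.
    """
    rng = np.random.default_rng(cfg.seed)
    lat_lo, lat_hi = cfg.lat_range
    lon_lo, lon_hi = cfg.lon_range
    lat_bins = np.arange(int(np.ceil(lat_lo)), int(np.floor(lat_hi)) + 1)
    lon_bins = np.arange(int(np.ceil(lon_lo)), int(np.floor(lon_hi)) + 1)
    grid = np.array([(la, lo) for la in lat_bins for lo in lon_bins])
    sites = grid[rng.choice(len(grid), size=cfg.n_sites, replace=False)]
    z0 = rng.uniform(*cfg.baseline_depth_range, size=cfg.n_sites)

    depths = np.asarray(cfg.bottle_depths, dtype=float)
    p_threshold = cfg.threshold / REDFIELD_N_TO_P
    depth_rows, profile_rows = [], []
    for s in range(cfg.n_sites):
        lat_bin, lon_bin = int(sites[s, 0]), int(sites[s, 1])
        for month in range(1, 13):
            z = max(float(z0[s] + _seasonal(month, cfg.seasonal_amplitude, cfg.seasonal_phase)), 10.0)
            for nutrient in ("nitrate", "phosphate"):
                depth_rows.append((lat_bin, lon_bin, month, nutrient, z))
            if include_profiles:
                nit = _concentration(depths, z, cfg.deep_concentration, cfg.threshold, cfg.transition_width)
                pho = _concentration(
                    depths, z, cfg.deep_concentration / REDFIELD_N_TO_P, p_threshold, cfg.transition_width
                )
                for d, cn, cp in zip(depths, nit, pho):
                    profile_rows.append((lat_bin, lon_bin, month, "nitrate", d, cn))
                    profile_rows.append((lat_bin, lon_bin, month, "phosphate", d, cp))

    depths_tab = pd.DataFrame(
        depth_rows, columns=["lat_bin", "lon_bin", "month", "nutrient", "nutricline_depth_m"]
    )
    profiles_tab = (
        pd.DataFrame(
            profile_rows,
            columns=["lat_bin", "lon_bin", "month", "nutrient", "depth_m", "concentration_umol_kg"],
        )
        if include_profiles
        else None
    )
    return MonthlyClimatology(depths=depths_tab, profiles=profiles_tab)


def schedule_from_casts(casts: Sequence[Cast]) -> pd.DataFrame:
    """Sampling schedule (site, year, month) of an archive, for replay simulations."""
    from .sites import assign_site

    rows = []
    for cast in casts:
        lat_bin, lon_bin = assign_site(cast.latitude, cast.longitude)
        rows.append((lat_bin, lon_bin, cast.date.year, cast.date.month))
    return pd.DataFrame(rows, columns=["lat_bin", "lon_bin", "year", "month"])
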