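"""Threshold-crossing nutricline depths and density at depth.

The nutricline depth of a cast is the shallowest depth at which the
piecewise-linearly interpolated nutrient concentration reaches a threshold
chosen to be well above detection limits.  The canonical thresholds are
[NO₃⁻] = 3 µmol kg⁻¹ for the nitracline and, in Redfield proportion (N:P =
16:1), [PO₄³⁻] = 3/16 µmol kg⁻¹ for the phosphacline; 1 and 5 µmol kg⁻¹
Redfield-paired variants probe threshold sensitivity.

Profiles are scanned from the shallowest sample downward and only the first
crossing counts: the nutricline marks the top of the nutrient-replete layer,
so deeper re-crossings of non-monotonic profiles are ignored.  A cast whose
shallowest sample already meets the threshold is ``surface_saturated``; one
that never reaches it is ``never_reached``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io_profiles import Cast

__all__ = [
    "NUTRIENTS",
    "REDFIELD_N_TO_P",
    "STATUS_CROSSED",
    "STATUS_SURFACE_SATURATED",
    "STATUS_NEVER_REACHED",
    "STATUS_INSUFFICIENT_DATA",
    "ThresholdSpec",
    "ProfileQC",
    "NutriclineRecord",
    "compute_nutricline",
    "compute_all",
    "records_to_frame",
    "linear_eos",
    "density_at_depth",
]

NUTRIENTS = ("nitrate", "phosphate")
REDFIELD_N_TO_P = 16.0

STATUS_CROSSED = "crossed"
STATUS_SURFACE_SATURATED = "surface_saturated"
STATUS_NEVER_REACHED = "never_reached"
STATUS_INSUFFICIENT_DATA = "insufficient_data"


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-nutrient threshold concentrations (µmol kg⁻¹), both > 0."""

    nitrate_threshold: float = 3.0
    phosphate_threshold: float = 3.0 / REDFIELD_N_TO_P

    def __post_init__(self) -> None:
        if self.nitrate_threshold <= 0 or self.phosphate_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def redfield(cls, nitrate_threshold: float) -> "ThresholdSpec":
        """Redfield-paired spec: phosphate threshold = nitrate threshold / 16."""
        return cls(nitrate_threshold, nitrate_threshold / REDFIELD_N_TO_P)

    def threshold_for(self, nutrient: str) -> float:
        if nutrient == "nitrate":
            return self.nitrate_threshold
        if nutrient == "phosphate":
            return self.phosphate_threshold
        raise ValueError(f"unknown nutrient {nutrient!r}")


@dataclass(frozen=True)
class ProfileQC:
    """Cast-eligibility window ensuring the crossing is actually resolved.

    A cast qualifies for a nutrient only if it has at least ``min_samples``
    non-missing values inside ``depth_window`` and its deepest non-missing
    sample is at or below ``min_deepest``.  This guards against spurious
    shallow crossings on truncated casts.
    """

    min_samples: int = 3
    depth_window: tuple[float, float] = (0.0, 500.0)
    min_deepest: float = 200.0

    def passes(self, depths: np.ndarray) -> bool:
        lo, hi = self.depth_window
        in_window = int(np.count_nonzero((depths >= lo) & (depths <= hi)))
        return in_window >= self.min_samples and depths.size > 0 and depths.max() >= self.min_deepest


DEFAULT_QC = ProfileQC()


@dataclass(frozen=True)
class NutriclineRecord:
    """Per-cast, per-nutrient crossing depth with provenance.

    ``depth`` is defined (finite) iff ``status`` is ``crossed`` or
    ``surface_saturated``.
    """

    cast_id: str
    nutrient: str
    threshold: float
    depth: float
    status: str
    latitude: float
    longitude: float
    year: int
    month: int


def _first_crossing(depths: np.ndarray, values: np.ndarray, threshold: float) -> tuple[float, str]:
    """First downward threshold crossing of a piecewise-linear profile.

    ``depths``/``values`` must be the non-missing samples, sorted by depth.
    """
    if values[0] >= threshold:
        return float(depths[0]), STATUS_SURFACE_SATURATED
    above = values >= threshold
    if not above.any():
        return np.nan, STATUS_NEVER_REACHED
    j = int(np.argmax(above))  # first sample at/above threshold; j >= 1 here
    z0, z1 = depths[j - 1], depths[j]
    v0, v1 = values[j - 1], values[j]
    depth = z0 + (threshold - v0) * (z1 - z0) / (v1 - v0)
    return float(depth), STATUS_CROSSED


def compute_nutricline(
    cast: Cast,
    nutrient: str,
    spec: ThresholdSpec | None = None,
    qc: ProfileQC | None = None,
) -> NutriclineRecord:
    """Compute the threshold-crossing nutricline depth for one cast.

    Missing samples are skipped, so interpolation brackets the crossing with
    the nearest non-missing neighbors.  With ``qc`` given, casts failing the
    eligibility window get status ``insufficient_data``.  An empty or
    single-sample profile is ``insufficient_data``, never an exception.
    """
    spec = spec or ThresholdSpec()
    threshold = spec.threshold_for(nutrient)
    values = cast.values_for(nutrient)
    good = ~np.isnan(values)
    depths = cast.depth[good]
    vals = values[good]

    year, month = cast.date.year, cast.date.month
    if depths.size < 2 or (qc is not None and not qc.passes(depths)):
        depth, status = np.nan, STATUS_INSUFFICIENT_DATA
    else:
        depth, status = _first_crossing(depths, vals, threshold)
    return NutriclineRecord(
        cast_id=cast.cast_id,
        nutrient=nutrient,
        threshold=threshold,
        depth=depth,
        status=status,
        latitude=cast.latitude,
        longitude=cast.longitude,
        year=year,
        month=month,
    )


def records_to_frame(records: Iterable[NutriclineRecord]) -> pd.DataFrame:
    """Tidy DataFrame of nutricline records (one row per cast × nutrient × spec)."""
    recs = list(records)
    return pd.DataFrame(
        {
            "cast_id": [r.cast_id for r in recs],
            "nutrient": [r.nutrient for r in recs],
            "threshold": [r.threshold for r in recs],
            "depth": [r.depth for r in recs],
            "status": [r.status for r in recs],
            "latitude": [r.latitude for r in recs],
            "longitude": [r.longitude for r in recs],
            "year": [r.year for r in recs],
            "month": [r.month for r in recs],
        }
    )


def compute_all(
    casts: Sequence[Cast],
    specs: ThresholdSpec | Sequence[ThresholdSpec] | None = None,
    nutrients: Sequence[str] = NUTRIENTS,
    qc: ProfileQC | None = DEFAULT_QC,
) -> pd.DataFrame:
    """Nutricline records for every (cast, nutrient, threshold spec).

    Applies the default :class:`ProfileQC` eligibility window; pass
    ``qc=None`` to disable it.  Deterministic given inputs.
    """
    if specs is None:
        specs = [ThresholdSpec()]
    elif isinstance(specs, ThresholdSpec):
        specs = [specs]
    if len(casts) == 0 or len(specs) == 0:
        raise ValueError("compute_all requires non-empty casts and specs")
    records = [
        compute_nutricline(cast, nutrient, spec, qc=qc)
        for cast in casts
        for nutrient in nutrients
        for spec in specs
    ]
    return records_to_frame(records)


# ---------------------------------------------------------------------------
# Density at depth
# ---------------------------------------------------------------------------


def linear_eos(
    temperature: float | np.ndarray,
    salinity: float | np.ndarray,
    rho0: float = 1025.0,
    alpha: float = 2.0e-4,
    beta: float = 7.6e-4,
    t_ref: float = 10.0,
    s_ref: float = 35.0,
):
    """Linear equation of state, returned as a density anomaly σ (kg m⁻³).

    ρ = ρ₀·(1 − α(T − T₀) + β(S − S₀)); σ = ρ − 1000.  A TEOS-10
    implementation (e.g. ``gsw.sigma0``) can be plugged in wherever an
    ``eos`` callable is accepted.
    """
    rho = rho0 * (1.0 - alpha * (temperature - t_ref) + beta * (salinity - s_ref))
    return rho - 1000.0


def density_at_depth(
    cast: Cast,
    depth: float,
    eos: Callable = linear_eos,
) -> float:
    """Potential density anomaly at ``depth`` from interpolated T and S.

    T and S are linearly interpolated (independently, skipping missing
    samples) to ``depth`` and passed to ``eos``.  Returns ``nan`` when the
    depth is not bracketed by non-missing T and S samples — no extrapolation.
    """
    if np.isnan(depth):
        return np.nan
    out: dict[str, float] = {}
    for name in ("temperature", "salinity"):
        vals = getattr(cast, name)
        good = ~np.isnan(vals)
        z, v = cast.depth[good], vals[good]
        if z.size < 2 or depth < z[0] or depth > z[-1]:
            return np.nan
        out[name] = float(np.interp(depth, z, v))
    return float(eos(out["temperature"], out["salinity"]))
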