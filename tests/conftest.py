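import datetime as dt

import numpy as np
import pytest

from nutriclines import Cast
from nutriclines.core import (
    STATUS_CROSSED,
    STATUS_NEVER_REACHED,
    STATUS_SURFACE_SATURATED,
)


def make_cast(
    depths,
    nitrate=None,
    phosphate=None,
    temperature=None,
    salinity=None,
    cast_id="c1",
    lat=10.0,
    lon=20.0,
    date=dt.date(2000, 6, 15),
):
    """Build a Cast from plain lists; omitted fields are all-missing."""
    depths = np.asarray(depths, dtype=float)
    n = depths.size

    def arr(x):
        return np.full(n, np.nan) if x is None else np.asarray(x, dtype=float)

    return Cast(
        cast_id=cast_id,
        latitude=lat,
        longitude=lon,
        date=date,
        depth=depths,
        nitrate=arr(nitrate),
        phosphate=arr(phosphate),
        temperature=arr(temperature),
        salinity=arr(salinity),
    )


def brute_force_crossing(depths, values, threshold, dz=0.01):
    """Independent dense-grid oracle for the first threshold crossing.

    Evaluates the piecewise-linear profile on a `dz`-spaced grid and returns
    the first grid depth whose value reaches the threshold.
    """
    depths = np.asarray(depths, dtype=float)
    values = np.asarray(values, dtype=float)
    good = ~np.isnan(values)
    depths, values = depths[good], values[good]
    if values[0] >= threshold:
        return float(depths[0]), STATUS_SURFACE_SATURATED
    grid = np.arange(depths[0], depths[-1] + dz / 2, dz)
    prof = np.interp(grid, depths, values)
    above = prof >= threshold
    if not above.any():
        return np.nan, STATUS_NEVER_REACHED
    return float(grid[np.argmax(above)]), STATUS_CROSSED


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_profile(rng, allow_saturated=True):
    """Random depth profile exercising all crossing statuses."""
    n = int(rng.integers(3, 12))
    depths = np.sort(rng.uniform(0, 600, n))
    depths += np.arange(n) * 1e-3  # enforce strictly increasing
    base = rng.uniform(0, 4)
    rise = np.cumsum(rng.uniform(0, 6, n))
    noise = rng.normal(0, rng.uniform(0, 1.5), n)
    values = np.maximum(base + rise + noise, 0.0)
    if not allow_saturated and values[0] >= 3.0:
        values[0] = rng.uniform(0, 2.9)
    return depths, values
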