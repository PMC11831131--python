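# nutriclines

Nutricline-depth extraction and temporal trend analysis for hydrographic
bottle-cast archives.

Nitrate and phosphate are usually below detection limits in the surface
ocean, so their long-term change cannot be read off surface measurements.
Both nutrients increase with depth, and the depth at which each first
reaches a well-detected concentration — the **nitracline** Z<sub>NO3</sub>
and **phosphacline** Z<sub>PO4</sub> — proxies upper-ocean nutrient
availability: a deepening nutricline means a more nutrient-depleted upper
ocean. This package turns multi-decadal archives of ship-based bottle casts
(GO-SHIP / GLODAP / WOD-style tables) into nutricline depth records and
asks whether those depths are trending, for whom the answer matters:
observational biogeochemists and ecologists who need trend estimates that
survive the severe irregularities of cruise sampling.

## Method

For each cast, the nutricline depth is the first downward crossing of a
threshold concentration by the piecewise-linearly interpolated profile —
canonically [NO₃⁻] = 3 µmol kg⁻¹ and, in Redfield proportion (N:P = 16),
[PO₄³⁻] = 3/16 µmol kg⁻¹ (1 and 5 µmol kg⁻¹ Redfield-paired variants probe
threshold sensitivity). Cast coordinates are rounded to the nearest degree;
depths are averaged per (1° site, calendar year); trends use only annual
means deeper than 50 m between 45°S and 45°N. Each site with ≥ 2 years gets
an OLS slope T<sub>NO3</sub> or T<sub>PO4</sub> (m y⁻¹), and the global
summary is the median slope with a 10,000-sample percentile bootstrap CI
over sites.

Because cruise sampling is irregular in space, season and decade, the
package ships the corresponding robustness battery:

- **Scrambled-year null (MToRP)** — permute each site's sampling years,
  refit, and build the null distribution of median trends;
- **Measurement-error injection** — add zero-mean Gaussian error
  (0.8 / 0.1 µmol kg⁻¹ for nitrate / phosphate) to every bottle and rerun;
- **Climatology replay** — impose the actual sampling schedule on a
  trend-free monthly climatology, optionally with artificial site trends,
  and match (mean, sd) of the imposed trend distribution to observed
  statistics by grid search;
- **Paired residual trend** — site trends of the per-cast difference
  Z<sub>NO3</sub> − Z<sub>PO4</sub>;
- **Residual T<sub>PO4</sub>** — signed orthogonal distance
  (T<sub>PO4</sub> − T<sub>NO3</sub>)/√2 from the 1:1 trend line;
- **Density-at-nutricline trends** and a **deep-water (>1000 m)
  concentration-anomaly diagnostic** for measurement-method drift;
- sign and Kruskal–Wallis tests, regional medians, extreme-trend exclusion.

A synthetic cruise-archive generator (`nutriclines.simulate`) produces
archives with known per-site trends, seasonal cycles, realistic sampling
sparsity and bottle noise — plus the matching trend-free climatology — so
every stage is testable end-to-end without downloads.

## Worked example

```python
from nutriclines import (
    SyntheticWorldConfig, TrendDistribution, generate_archive,
    compute_all, annual_average, filter_trend_eligible,
    fit_site_trends, median_with_bootstrap_ci, scramble_years,
)

world = SyntheticWorldConfig(
    n_sites=400,
    casts_per_site_year=1.0,
    seed=42,
    trend_dist_no3=TrendDistribution(0.0, 1.0),   # stable nitracline
    trend_dist_po4=TrendDistribution(0.35, 1.0),  # deepening phosphacline
)
casts, truth = generate_archive(world)
print(f"{len(casts)} casts at {world.n_sites} sites, {world.years[0]}-{world.years[1]}")

records = compute_all(casts)  # Z_NO3 and Z_PO4 per cast at 3 / (3/16) umol/kg
series = filter_trend_eligible(annual_average(records))  # >50 m, 45S-45N

label = {"nitrate": "T_NO3", "phosphate": "T_PO4"}
for nutrient, sub in series.groupby("nutrient"):
    trends = fit_site_trends(sub)
    med = median_with_bootstrap_ci(trends, n_bootstrap=10_000, seed=1)
    null = scramble_years(sub, n_randomizations=2_000, seed=1)
    print(f"median {label[nutrient]} = {med.median:+.2f} m/y "
          f"[{med.ci_low:+.2f}, {med.ci_high:+.2f}] (n={med.n_sites} sites), "
          f"scrambled-year p = {null.p_value:.2g}")
```

prints

```
20260 casts at 400 sites, 1972-2022
median T_NO3 = +0.06 m/y [-0.05, +0.15] (n=400 sites), scrambled-year p = 0.0005
median T_PO4 = +0.28 m/y [+0.14, +0.43] (n=400 sites), scrambled-year p = 0.0005
```

The phosphacline median recovers the imposed +0.35 m y⁻¹ deepening to
within its bootstrap CI, while the nitracline — generated with no trend —
comes out slightly positive: the "> 50 m" eligibility filter censors sites
that shoal into the mixed layer, a small but real selection effect of the
method that the scrambled-year null (which has no such secular structure)
flags as significant. The paired and residual statistics in
`nutriclines.trends` quantify the difference between the two nutrients'
trends directly.

A `nutriclines` command-line interface runs the same stages
(`simulate`, `nutricline`, `aggregate`, `trends`, `nulls`, `report`) from a
YAML config, writing flat CSV/JSON artifacts and a run manifest.

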