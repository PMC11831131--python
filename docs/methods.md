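# Methods

## The estimand and the pipeline

The quantity of interest is the long-term rate of change of nutricline
depth. For a cast with bottle concentrations C(z), the nutricline is the
shallowest depth where the piecewise-linear interpolant of C reaches a
threshold T: nitrate T = 3 µmol kg⁻¹ and phosphate T = 3/16 µmol kg⁻¹ by
default (Redfield-paired; 1 and 5 µmol kg⁻¹ variants supported). Scanning
is strictly top-down and only the first crossing counts — the nutricline is
the top of the nutrient-replete layer, and deeper re-crossings of
non-monotonic profiles are ignored. A profile whose shallowest sample
already meets T is `surface_saturated` (depth = shallowest sampled depth);
one that never reaches T is `never_reached` (no depth). Missing bottles are
skipped, so the crossing is bracketed by the nearest non-missing neighbors.

Depths are then averaged per 1° site (coordinates rounded
half-away-from-zero; longitude 180° wraps to −180°) and calendar year, and
filtered: only annual means strictly deeper than 50 m, at sites within
±45° latitude, enter the trend fits. The per-site trend is the OLS slope of
annual mean depth on calendar year (unweighted by default; a √n_casts
weighting knob exists), computed for sites with at least two annual points.
The global summary is the median of site slopes with a percentile bootstrap
CI: sites are the exchangeable unit and are resampled with replacement
10,000 times.

Assumptions worth stating: linear interpolation between bottles (the
minimal reproducible choice; the test oracle is a 0.01 m dense-grid scan of
the same interpolant); the calendar year as the annual bin; straight OLS
per site with no autocorrelation correction (annual means at a site are
rarely more than a handful of points); p-values two-sided and uncorrected
for multiple testing, reported per analysis.

## Eligibility and quality control

Two layers of screening exist and are deliberately separate:

* `compute_nutricline` itself requires only ≥ 2 non-missing samples of the
  nutrient — single-cast use stays permissive, and degenerate input yields
  `insufficient_data`, never an exception.
* The pipeline-level `ProfileQC` window (applied by default in
  `compute_all`) requires ≥ 3 non-missing samples within 0–500 m and a
  deepest sample at or below 200 m, rejecting truncated casts whose
  apparent crossing would not be resolved. Both the window and the filter
  thresholds (50 m strict, ±45° inclusive, 25 m robustness variant) are
  configuration knobs.

Ingestion clamps nothing silently: negative concentrations (below-detection
artifacts) become missing, bottles flagged `bad` are excluded
(`questionable` retained by default), duplicate depths are averaged, and
every dropped row lands in exactly one category of the ingest report so
that kept + dropped = input always holds. Inputs in µmol L⁻¹ are converted
with a fixed nominal density of 1.025 kg L⁻¹; pressure converts to depth
1:1 by default with a pluggable hook. Heterogeneous archive QC-flag
conventions must be mapped to good/questionable/bad by the caller's
`ColumnMapping`; the mapping is a declared convention, not an inference.

## Robustness procedures

**Scrambled-year null (MToRP).** Year labels of each site's annual series
are permuted uniformly at random, site trends refit, and the median
recorded; 10,000 randomizations by default. Permutation is within site —
the stricter null that preserves all spatial structure and each site's
multiset of depths exactly — with a global scramble available as an option.
The two-sided empirical p-value carries the +1 correction
p = (1 + #{|m\*| ≥ |m_obs|})/(n + 1), so it is never exactly zero. Under
within-site exchangeability this is an exact permutation test; null
calibration is verified on trend-free synthetic archives.

**Measurement-error injection.** Independent zero-mean Gaussian error
(defaults 0.8 and 0.1 µmol kg⁻¹ for nitrate and phosphate) is added to
every bottle concentration — not to depths — and perturbed negative values
clamp to zero; the whole pipeline then reruns. Because the phosphate
threshold (0.1875 µmol kg⁻¹) is less than 2 SD of the injected error, noise
occasionally manufactures spurious shallow phosphacline crossings; this
both inflates the spread of T_PO4 (far more than T_NO3, whose threshold
sits almost 4 SD above its error) and attenuates the phosphacline median
toward zero by roughly a quarter. Both effects are properties of the
threshold-crossing estimator under noise, not implementation artifacts.

**Climatology replay.** The actual sampling schedule (site, year, month) is
replayed against a trend-free monthly climatology: pseudo-depth =
climatology(site, month) + b·(t − t₀), with b = 0, a fixed slope, or a
fresh per-site draw from N(mean, sd²) per population; each population also
permutes schedule years within site, which is what makes the no-trend
populations vary at all — the choice of randomization is ours, selected
because it reuses the MToRP null and reproduces both expected outcomes
(null medians centered on zero; an imposed fixed trend recovered in the
median). `match_trend_distribution` grid-searches (mean, sd) to match an
observed median and site-trend variance, with the loss standardized by the
observed scales and ties broken toward smaller sd; grid search rather than
gradients because the objective is a noisy simulation output.

**Paired and derived statistics.** The paired residual trend fits site
trends of per-cast Z_NO3 − Z_PO4 (both depths defined and > 50 m; the
cast-level filter is our choice, since the difference has no meaningful
50 m scale of its own). The residual-T_PO4 statistic is
(T_PO4 − T_NO3)/√2, the signed orthogonal distance from the 1:1 line.
Density at the nutricline interpolates T and S to the crossing depth and
applies a pluggable equation of state; the shipped default is a linear EOS
σ = ρ₀(1 − α(T − 10 °C) + β(S − 35)) − 1000 with ρ₀ = 1025 kg m⁻³,
α = 2×10⁻⁴ K⁻¹, β = 7.6×10⁻⁴ — fully self-contained and adequate for
trend *signs*; any TEOS-10 callable (e.g. `gsw.sigma0`) plugs in where
absolute densities matter. The deep-water diagnostic regresses pooled
(observed − climatology) concentration anomalies below 1000 m on decimal
year; a slope indistinguishable from zero is the expected no-bias outcome.

## The synthetic world

`SyntheticWorldConfig` defines the study conditions. Per site s, nutrient
n, month m and decimal year t, the true crossing depth is

    Z(s, n, t, m) = Z0_s + A·cos(2π(m − φ)/12) + b_{s,n}·(t − t₀)

with Z0 ~ U(70, 200) m, A = 20 m, φ = month 8, and b drawn per nutrient
from configurable normal distributions (defaults N(−0.63, 1.5²) m y⁻¹
nitracline, N(+0.20, 1.0²) m y⁻¹ phosphacline — the distributions that
reproduce observed global trend statistics). Concentration profiles are
logistic in depth, positioned so C(Z) equals the generating threshold
exactly (closed-form oracle), with deep nitrate 35 µmol kg⁻¹, transition
width 50 m, and phosphate exactly nitrate/16 whenever the two crossing
depths coincide (`redfield_coupled`). Bottles sit on a 26-level grid with
15 m spacing through the upper 255 m — the scale of a modern rosette cast,
and fine enough that the piecewise-linear crossing stays within 0.5 m of
the analytic crossing at the default transition width. Bottle noise
defaults to analytical precision (0.1 / 0.01 µmol kg⁻¹); an optional
uniform concentration drift below 1000 m feeds the deep-bias diagnostic.
A two-layer T/S column with a logistic interface supplies density; the
interface can be fixed in depth or locked to the nutricline, giving
zero-density-trend and migrating-nutricline constructions.

Sampling density defaults to 0.07 casts per site-year (Poisson per
site-year, months categorical, day uniform) — the density implied by real
conglomerate archives, where a typical 1° site is occupied in only a
handful of distinct years across five decades. Under these defaults the
synthetic world reproduces, without being fit to them, three observed
statistics of the real analysis: the climatology-replay IQR is ~50% of the
observed trend IQR, error injection inflates the T_PO4 IQR by ~30–40%
versus a few percent for T_NO3, and the injected-error phosphacline median
attenuates by ~25%.

What the generator does **not** emulate: interannual (ENSO-scale) depth
variability, archive heterogeneity (mixed methods, laboratories and QC
conventions), cruise-track clumping of casts, spatially correlated trends,
and mixed-layer dynamics. Consequently the synthetic site-trend dispersion
(σ ≈ 1.3 m y⁻¹) is about half the observed one, and confidence intervals
on synthetic medians are correspondingly tighter than in the real analysis.
Passing tests therefore demonstrate correctness of the estimators and
calibration of the nulls under known ground truth — not that real-archive
CIs would be as tight, nor that unmodeled interannual variability could not
widen them. One acceptance check is deliberately left failing: after error
injection at the default SDs, the attenuated phosphacline median falls just
outside the uninjected archive's bootstrap CI, precisely because the
synthetic CI lacks the real world's extra dispersion that absorbed the same
attenuation in the observational analysis.

The generator also exposes a genuine property of the method: the strict
"> 50 m" filter censors sites that shoal into the mixed layer, biasing the
median trend slightly positive (a trend-free nitracline world yields a
median of about +0.06 to +0.09 m y⁻¹ at dense sampling). This selection
effect is inherent to the eligibility rule, is visible in
climatology-matching exercises, and is why recovered medians are compared
against the median of the actually drawn slopes rather than the nominal
distribution mean.

## Numerical choices

* Rounding to sites is half-away-from-zero (`copysign(floor(|x|+0.5), x)`),
  not banker's rounding; longitude normalization is an exact no-op on
  in-range values so ingestion round-trips byte-identically.
* Site slopes use the closed-form normal equations on grouped sums with the
  year centered; exact two-point and collinear cases reproduce the line.
  Degenerate global fits (zero residual variance) return p = 1 for a zero
  slope and p = 0 otherwise rather than NaN.
* Bootstrap and scramble resampling are chunked to ~2×10⁷ elements;
  all randomness flows through `numpy.random.default_rng(seed)` and results
  are bit-reproducible given (seed, n) on a fixed platform.
* Sign test: exact two-sided binomial, zeros dropped, undefined (NaN, with
  a warning) when nothing remains. Kruskal–Wallis returns (0, 1) when all
  values are identical instead of erroring.
* CSV I/O uses round-trip float precision; the climatology carries explicit
  missing values — a lookup at an absent or all-missing cell returns None,
  never zero. NetCDF climatologies use dims (lat, lon, month[, depth]).
* Seasonal anomalies subtract the (site, month) climatological depth but
  the 50 m eligibility filter keeps using the raw depth: anomalies are
  near zero by construction and filtering them at 50 m would be
  meaningless.

## Test problem sizes

The suite exercises the crossing oracle on 1,000 random profiles; null
calibration on 60 trend-free 300-site, 30-year archives (500 randomizations
each — the p-resolution needed to judge p > 0.05, while the library default
stays 10,000); parameter recovery on 20 archives of 300 sites at one cast
per site-year, where estimation noise is small enough that recovery
isolates estimator correctness; and the measurement-error contrast on an
1,800-site archive, the scale of the real trend-site ensemble. The
acceptance script uses the full 10,000 bootstrap and randomization counts.

## Known limitations

Linear interpolation understates crossing depths on convex profile segments
(bounded by the bottle-spacing analysis above); the annual bin ignores
hydrographic-year conventions; no autocorrelation or measurement-error
model enters the OLS fits (the robustness battery addresses these by
simulation instead); the linear EOS is not TEOS-10 and should not be used
where absolute density accuracy matters; and sampling-density–based
observation filtering is not implemented.
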