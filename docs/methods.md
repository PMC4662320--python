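# Methods

`phenosync` implements a pipeline linking satellite-derived vegetation
phenology to the breeding phenology of cavity-nesting tits in a
mixed-deciduous woodland, together with a synthetic-data generator that
produces every input with known ground truth. This note documents the
models, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## Satellite side

**EVI2 series.** Each 240 m pixel is observed up to 16 times per 8-day
period; cloud-flagged looks are discarded and the per-period index value is
the arithmetic mean of EVI2 = 2.5(NIR − Red)/(NIR + 2.4 Red + 1) over the
clear looks. Periods are calendar-anchored at 1 January (46 per year, the
last one 5–6 days long); whether the original processing anchored windows to
the calendar or to a satellite product is not recoverable, so the calendar
convention is fixed here and documented. The "middle day" of days d..d+7 is
taken as d+3; the ambiguity is at most one day and propagates to green-up
dates at well below the method's noise level.

**Green-up extraction.** A cubic penalized regression spline (uniform
B-spline basis, second-order difference penalty) is fitted to each
pixel-year series, with the penalty chosen by generalized cross-validation;
green-up is the integer day, within days 30–250 and the data support, at
which the fitted first derivative is maximal (ties to the earliest day; a
maximum ≤ 0 means "no green-up" and the pixel-year is dropped with a log
entry). The basis has 20 functions by default (~21-day knot spacing). We
initially used 10, but the ~51-day knot spacing quantizes the location of
the derivative peak of a ~40-day logistic rise: the noiseless extraction
error then oscillates by ±4–5 days depending on where the true inflection
falls between knots, and — worse — the oscillation's local slope distorts
within-year contrasts. With 20 basis functions the noiseless error is ≤ 2
days at any inflection and the simulated median absolute error at 75% cloud
is ~1.4 days. The penalty, not the basis size, controls the effective
degrees of freedom, so the larger basis does not overfit. Pixel-years with
fewer than 20 clear periods (of 46) are not fitted; the threshold is a
package choice with no published counterpart. An optional
residual-bootstrap CI (199 replicates, seeded) is available but off by
default; nothing downstream consumes it.

**Nestbox weighting.** A nestbox inherits the bilinear-interpolation
weights of its four nearest pixel centers, each multiplied by the pixel's
woodland fraction and renormalized over pixels with a valid estimate; boxes
with no weighted neighbour fall back to the nearest valid woodland pixel
within 360 m, beyond which they are unassignable and dropped (logged). The
original study used a GIS weighting procedure whose details are in an
unavailable supplement; bilinear × woodland-fraction is the simplest scheme
satisfying the published description and is presented as an interpretation,
not a reconstruction.

## Breeding side

Laying dates are inferred by back-counting one egg per day from a clutch
observation (3 eggs on 3 April → laid 1 April) and kept on a day-of-April
scale (1 = 1 April). Per year and species, only clutches laid within 30
days (inclusive) of the first clutch are retained, excluding repeat
breeding attempts; the boundary and the per-species reference are
configurable. Joins to nestbox covariates and nestbox green-up never drop
records silently: every input row ends up retained, excluded by the
30-day filter, or listed in a rejects table, and the three counts add up
exactly.

## Statistical models

**Within/between-year centering.** Nestbox green-up g is split into the
annual mean (between-year) and the deviation from it (within-year), so
that g = between + within exactly for every record. The mixed model of
laying (or hatch) date has fixed effects {within, between} or additionally
{altitude, woodland-edge distance, oak density within 75 m}, and crossed
random intercepts for year and nestbox (optionally female, which restricts
the data to identified females). The between coefficient is only weakly
identified next to the year intercepts — standard for this decomposition —
while the within coefficient is the quantity of interest. For the annual
between-year predictor two conventions exist (mean over records vs. mean
over woodland pixels); the record mean is used inside the decomposition so
the reconstruction identity holds, and the woodland-pixel mean is used for
annual-level correlations. Both are exposed.

**REML solver.** The crossed-intercepts model is estimated by profiled
REML: for fixed relative standard deviations θ the penalized least-squares
system (mixed-model equations with scaled random effects) is solved by one
dense Cholesky factorization, which also yields the two log-determinants in
the profiled deviance; Nelder-Mead minimizes over log θ, and components
drifting toward zero are polished onto the boundary when that does not
worsen the criterion. Coefficient inference uses the normal approximation
on t = estimate/SE; the original analysis reported MCMC-based p-values,
which we do not reproduce — point estimates and SEs are comparable,
significance machinery is not. The solver is cross-checked against
statsmodels MixedLM (single-factor and crossed variance components) in the
test suite; statsmodels is not used for the production fits because the
single-group variance-component formulation it needs for crossed factors is
an order of magnitude slower at ~10³ nestbox levels.

An algebraic note: the within coefficient is exactly invariant to adding a
constant to all green-up values of one year when the model's covariance
treats year as the only grouping (the centered predictor is orthogonal, in
the V⁻¹ metric, to year-constant columns). With crossed nestbox intercepts
the invariance is approximate (~1e-4 in our simulations) because box
effects couple observations across years. The exactness check in the
validation suite therefore uses the year-grouped fit at common variance
components.

**Synchrony landscape.** Pixel synchrony is the across-year Pearson
correlation between a pixel's annual mean laying date and its green-up
date; attempts are assigned to the pixel containing the nestbox. Pixels
with woodland fraction ≤ 0.5 are excluded; pixels with fewer than 6
year-points (configurable) are flagged rather than mapped, matching the
original exclusion of 3- and 5-point pixels. Habitat regressions are
weighted least squares of pixel r on one species proportion at a time
(compositional proportions are not independent, so no joint model), with
weights equal to the number of breeding attempts behind each r; by default
every woodland pixel with a defined correlation enters, since the original study
describes the regressions as using all >50%-woodland pixels. The species
contrast is a Welch t-test (whether the original analysis pooled variances
is not documented; Welch is the safer default).

**Mantel correlograms.** For each distance class the statistic is the
negated Pearson correlation over site pairs between value dissimilarity
|vᵢ − vⱼ| and the 0/1 class indicator, so positive r means positive
autocorrelation. Distance classes default to equal-count bins (Sturges'
rule on the pair count); p-values come from permuting site labels (999 by
default, seeded; two-sided on |r|), with an exact variant enumerating all
n! permutations for small n used as the test oracle. Laying-date
correlograms use residuals from an intercept-only mixed model with year
(and optionally female) intercepts — "corrected for annual and
female-specific effects". A class whose pairs are all identical in value is
reported as undefined, never silently zero. A progressive Holm correction
across classes is available but off by default.

**Cloud-window scan.** Annual synchrony is the per-year Pearson r between
individual laying dates and nestbox green-up (≥3 pairs). Mean cloud
fraction is computed for every contiguous window of 3–15 8-day periods
within the first 15 periods (91 windows), and annual synchrony is regressed
on each window's mean; windows are ranked by |r| (the reported top models
have negative slopes, so magnitude ordering is the informative one), with a
signed ranking also emitted and ties broken by (start, length). Windows
with cloudiness constant across the usable years are flagged and left
unranked.

## Synthetic-data generator

The generator emulates the study system at its published scale: an 11×11
grid of 240 m pixels (~117-pixel site), 13 years, 1200 nestboxes, ~35%
occupancy per species per year (≈4600 attempts per species over 13 years),
16 potential looks per period with winter cloudiness averaging 79% (→ ~4
clear looks), and a green-up day near 110 with between-year SD 6 d.
Spatial structure (woodland fraction, habitat composition, altitude, the
static green-up field) comes from Gaussian-kernel-smoothed white noise
(bandwidth = `spatial_range`, restandardized), which gives controllable
autocorrelation without any geostatistics dependency. Habitat lives on
120 m quadrant compartments so that pixel composition is a genuine
area-weighted overlay yet decorrelates across pixels when the smoothing
range is zero. Canopy/understory shares fluctuate log-normally around the
woodland-wide means (oak 27%, ash 31%, beech 14%, sycamore 11%; hazel 44%,
hawthorn 33%, elder 7%, field maple 6%).

Laying dates follow
α + b_w·(g − ḡ_y)(1 + γ·oak) + b_b·ḡ_y + b_alt·alt + b_edge·edge +
b_oak·oakdens + year + box + ε, with defaults b_w = 0.02 d/d and
b_b = 0.315 d/d taken from the reported model coefficients (0.019/0.315),
habitat effects 0.028, 0.003, −0.043 likewise, residual SD 4 d, year and
box intercept SDs 2 and 1.5 d. Two defaults deserve justification because
they are calibrated from reported statistics rather than stated directly:

- the pixel-by-year green-up deviation SD is 5 d (against a static spatial
  SD of 3 d), since the original study emphasizes that spatial green-up patterns
  change considerably from year to year;
- the oak coupling gain is γ = 25 on a 0–1 normalized oak-density scale.
  The reported pixel-synchrony spread (r from about −0.3 to +0.85, an oak
  slope of ~0.39) cannot arise from a uniform 0.02 d/d coupling; γ = 25
  means birds at the oak-richest boxes track local green-up at ~0.2–0.5 d/d
  while oak-free boxes barely track it, and reproduces a synchrony spread
  of about −0.5 to +0.85 with mean ~0.44. γ was fixed from this reasoning
  before the recovery experiments were run, and is not adjusted.

The caterpillar half-fall series is γ₀ + 0.8·ḡ_y + noise with noise SD
4.4 d, chosen so the green-up/half-fall correlation sits near the reported
0.74 at n = 13. The laying→hatch link (clutch size ~N(8.5, 1.2) rounded,
13 days of incubation, 1 d noise) is plumbing: nothing in the original study
specifies it, and only the existence of plausible hatch dates matters
downstream. A small rate (2%) of late repeat clutches ~38–50 days after
the year's first clutch exercises the first-brood filter. Observation
looks within a period all carry the period's midpoint date: the
twice-daily look structure is deliberately not modeled beyond counts, and
this makes noiseless period means match the analytic curve exactly, which
the round-trip tests rely on.

**What the generator does not emulate.** Reflectances are a constant red
band with NIR solved from the target EVI2 — no radiative transfer, BRDF,
soil background or atmosphere; cloudiness is site-wide per period rather
than spatially patchy; habitat composition is stationary over years;
female identity affects no phenotype; and the bird model responds to the
truth of its own pixel, linearly. Passing recovery tests therefore shows
the estimators are consistent with their own assumptions at realistic
noise levels — not that those assumptions hold in real satellite or field
data.

## Validation experiment sizes

The experiments behind `scripts/acceptance.py` and the heavier tests use
sizes chosen to finish in minutes on one core while keeping the full study-scale
conditions where they matter: green-up recovery uses 100 pixel-years (5×5
grid × 4 years) at a flat 75% cloud; the within-coefficient recovery runs
the complete satellite chain on 20 full-scale simulated studies; the
oak-slope experiment runs 20 + 20 full-scale studies on truth green-up
(the satellite step is orthogonal to the sign question); Mantel calibration
uses 200 spatially random datasets of 15 sites at 199 permutations plus a
brute-force check at n = 5 (120 permutations); the cloud-degradation curve
averages 50 paired seeds (same truth, different thinning) of 36 pixel-years
per cloud level.

## Known limitations

- The nestbox weighting scheme is an interpretation of a procedure whose
  specification is unavailable; alternatives (buffer area-weighting) would
  differ most for boxes near pixel corners.
- The between-year coefficient is reported but weakly identified next to
  the year random intercept; treat its SE accordingly.
- Coefficient p-values are large-sample normal approximations; for 13
  year-level units they are optimistic.
- The scan over 91 cloud windows is reported without multiplicity
  correction, as in the original design; the ranking, not any single
  p-value, is the meaningful output.
- Green-up extraction at >90% cloud leaves many pixel-years below the
  20-period threshold; the pipeline drops them, which can bias surviving
  pixels toward the less cloudy parts of a year.
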