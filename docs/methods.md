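# Methods

## Scope and model

`landepi` implements, end to end, the analysis design of a
population-based matched case-control study of childhood central
nervous system (CNS) tumours in which residential exposure is derived
from geographic layers: percentage of cultivated land around the home
(the Global Crop Index, GCI), a five-category industrial/urban/rural
environment label, and a census-tract socioeconomic status (SES) value.
Because the registry, census and land-cover data behind such studies
are confidential, the package pairs the analysis chain with a synthetic
landscape and population generator whose statistical structure matches
what the analysis assumes, so every stage is testable and
parameter-recovery experiments can be run at full study scale (714
cases, 4284 controls).

The outcome model, both for generating case labels and for analysis, is
an unconditional logistic regression

    logit P(case) = β₀ + β_g·(GCI/10) + Σ β_q·1[SES quartile q]
                  + Σ β_e·1[environment e] + β_s·1[male] + β_y·(year − ȳ)
                  + u_region,     u_region ~ N(0, σ²)

with rural and quartile Q1 as reference levels. The matching factors
(sex, birth year, region) enter as covariates; conditional logistic
regression is deliberately out of scope. Exponentiated coefficients are
odds ratios (ORs): per 10 percentage points of GCI, per quartile
contrast, per category versus rural. Confidence intervals are Wald,
exp(β̂ ± 1.96·SE), matching the reporting convention being emulated;
profile intervals are not provided.

## Exposure assessment

The GCI of a residence is 100 × area(buffer ∩ crop polygons) /
area(buffer) for a circular buffer of radius 1 km (configurable), with
six crop subcategories (Irrigated, Rice, Vineyards, Fruits, Olives,
Heterogeneous) measured the same way; the subcategory values of a
disjoint land-cover layer sum to the GCI. Numerical choices:

- the circle is a 64-segment polygon and the denominator is the area of
  that polygon, so full containment is exactly 100; the worst-case
  polygonisation error (~0.16 points) is far below the 0.5-point
  accuracy the tests demand;
- values are clamped to [0, 100] to absorb floating-point residue;
- polygons sharing a category are unioned before intersection, so
  malformed overlapping inputs are not double counted;
- a buffer reaching past the landscape extent keeps the full buffer
  area as denominator — missing land counts as non-crop (conservative
  and reproducible);
- an independent Monte-Carlo oracle (uniform sampling in the true disc
  plus point-in-polygon counting) verifies the exact computation; at
  10⁵ samples its standard error is ≤ 0.5 points.

## Environment classification

With d the Euclidean distance to the nearest industrial facility, u
membership of an urban polygon (population ≥ 10 000 by default), D the
industrial distance and a fixed 5 km outer limit: intersection if u and
d ≤ D; industrial if not u and d ≤ D; urban if u and d > D; ring if not
u and D < d ≤ 5 km; rural otherwise. Ties: d ≤ D is exposed, points on
polygon boundaries are inside. The ring exists only outside urban
areas; urban residents stay "urban" regardless of d > D. The D-sweep
refits the full model at each candidate distance (defaults 1, 1.5, 2,
2.5, 3, 4, 5 km) and reports the environment ORs per D; the choice of a
working D (2 km by default) is an input, not an output — no change
point is detected automatically. Sweep rows flag terms whose Wald
machinery is meaningless under (near-)separation, which happens easily
in small simulated studies when a category is nearly empty.

## SES

Each residence inherits the SES value of the census tract containing
it; tracts partition the territory, and boundary points resolve to the
lowest tract index. Quartile cut-points are the 25/50/75
linear-interpolation percentiles of the matched controls (the default
reference, which yields exactly equal control counts per quartile; a
whole-study reference is a config switch), and labels use half-open
intervals [q25, q50) etc., with Q4 closed at the maximum.

## Matching

Each case receives 6 controls (configurable) drawn uniformly without
replacement from pool members sharing its (sex, birth year, region)
stratum, restricted to validly geocoded subjects — equivalent to the
registry practice of redrawing replacements for the ~2% of failed
geocodes. Controls are never reused across cases, so n_controls =
6 × n_cases exactly. Birth-year matching is exact by default; a ±window
is exposed. A stratum with too few eligible controls raises an error
naming the stratum and shortfall; this is a rare random event at the
simulated pool sizes and the acceptance script redraws such a replicate
from a deterministic fallback seed.

## Mixed-model estimation

No maximum-likelihood binomial mixed model is available in the
installed Python stack, so the marginal likelihood is implemented
directly: for each region the random-intercept integral is evaluated by
adaptive Gauss–Hermite quadrature (15 nodes by default) recentred at
the per-region posterior mode found by a one-dimensional Newton
iteration; the Laplace approximation is the one-node special case.
L-BFGS-B maximises over (β, σ) with σ ≥ 0, started from the ordinary
logistic fit; standard errors come from the inverse numerical Hessian
at the optimum. The implementation agrees with `lme4::glmer`
(nAGQ = 15) to ~1e-4 on clustered test data, and with plain logistic
regression to 1e-6 when σ is pinned at 0.

A random intercept over five regions is fragile, and under exact
matching on region the between-region case:control imbalance is zero by
construction, so σ̂ typically collapses to the boundary. When σ̂ falls
below 0.02 the model is refitted with region fixed effects and the
`method` field records `"region_fixed"`. This is the expected route for
matched simulated studies; the `"aghq"` route engages on genuinely
clustered (unmatched) data.

## Synthetic landscape and population

The generator emulates the four layers the analysis consumes, in one
planar metric frame (no geodesy — all distances in the design are local
and metric):

- **Land cover / tracts**: Voronoi tessellations of seeded uniform
  point sets, mirrored across the extent edges so cells partition the
  rectangle exactly (default 400 cells / 250 tracts over 50 × 50 km).
  Cells get i.i.d. category labels (defaults: 50% NonCrop, 20%
  Irrigated, 10% Heterogeneous, 8% Fruits, 5% Vineyards, 5% Olives, 2%
  Rice); cells whose centroid falls under a town are relabelled
  NonCrop, since built-up land replaces cultivated land. Tract SES is
  uniform on the observed census range 0.46–1.57.
- **Towns**: 12 discs with radius 1–6 km; population = area × a
  density around 1500/km², so some towns fall below the 10 000 urban
  threshold.
- **Facilities**: 150 points, 70% scattered normally around towns
  (industry tracks settlement) and 30% uniform; the group attribute is
  free text drawn from a small vocabulary.
- **Population**: a pool of 25 000 residences with density 4× higher
  inside towns than outside, uniform sex, birth years 1996–2011, five
  named regions with equal weights, and 2% flagged as failed geocodes.
  Equal region sizes are a deliberate simplification: real registries
  are heavily unbalanced, but under 6:1 within-region matching the
  region marginal carries no information about the exposure ORs, and
  equal sizes keep small matching strata populated. Region labels are
  independent of location (the territory is shared); per-region
  placement overrides (`crop_free`, `high_ses`) exist for sensitivity
  experiments.
- **Outcomes**: region intercepts are drawn once per region; each valid
  subject gets the logistic case probability above, and exactly
  `n_cases` cases are sampled without replacement with weight
  proportional to that probability (Gumbel top-k), mirroring a registry
  of fixed case count. The default intercept (−6 log-odds) keeps
  probabilities small so that weight-proportional sampling reproduces
  the generating odds ratios to well under 1%. Cases draw subgroup
  labels from the registry multinomial (36% astrocytoma, 24%
  intracranial/intraspinal embryonal tumours, …), independent of
  exposure by default.

Default generating effects are the published full-model point estimates
(GCI 1.22 per 10 points; SES Q2/Q3/Q4 0.97/1.01/1.37; industrial /
intersection / urban 0.96/1.20/0.90), with unreported terms (sex, year,
ring) at the null and region SD 0.25.

**What the generator does not emulate**: real geography and street
networks; spatially clumped agriculture (crop labels are i.i.d. over
cells, so simulated exposure prevalence is far higher than the ~14% of
study children with any crop in their buffer); regional imbalance;
within-tract SES heterogeneity; any relationship between moving and
exposure. Passing tests therefore demonstrate correctness of the
pipeline and calibration of the estimator under the assumed model, not
robustness to the messiness of real registry data.

## Movers and the same-address sensitivity analysis

A configured fraction of cases (default 0.535, i.e. ~332 of 714
non-movers) is flagged as having a diagnosis address different from the
birth address. Two modes exist. In the default `"flag"` mode movers
keep their coordinates: the flag only defines the sensitivity subset,
and the main analysis remains an unbiased recovery experiment — this is
the mode study-scale recovery and calibration runs use. In
`"relocate"` mode movers draw a fresh uniform residence after the
outcome, so their analysed exposure is decoupled from the exposure that
generated their outcome; this reproduces, directionally, the
attenuation of the main-analysis GCI OR relative to the non-mover
subset, and is exercised by a dedicated test. The sensitivity analysis
itself refits every model on non-mover cases plus all controls, and
flags subgroups left without cases.

## Leave-one-region-out

The total-CNS model is refitted excluding each region in turn,
reporting the GCI and SES-Q4 ORs per exclusion. A caveat discovered in
design: with faithful individual matching the case:control ratio is
fixed within every region, so region composition cannot confound the
matched sample and excluding a region built to be crop-free and
affluent does not, in this simulation, reproduce the real study's shift
of the GCI OR toward the null — that observation requires residual
between-region structure the matched design removes. The operation is
provided and tested for exchangeability under homogeneous regions.

## Problem sizes and tolerances

Parameter-recovery runs use the full study scale (pool 25 000, 714
cases, 100 replicates); null-calibration uses a reduced scale (pool
6 000, 120 cases, 25 km extent, 200 replicates), since interval
coverage is scale-invariant. Geometry tests compare exact indices with
the 10⁵-sample oracle to 1 percentage point; the half-plane
configuration is checked to 0.5 points. The mixed-model boundary
threshold is σ̂ < 0.02; IRLS converges to 1e-12 step size; quadrature
uses 15 nodes.

## Known limitations

- Wald intervals misbehave under separation (small subgroups, sparse
  categories); affected sweep rows are flagged, not repaired.
- The region random intercept is estimable only from unmatched designs;
  matched runs always report the fixed-effects route.
- The crop layer's i.i.d. labelling makes the GCI distribution bimodal
  (many 0s and 100s), unlike the long-tailed real index.
- Subgroup analyses at realistic subgroup sizes (31–258 cases) are
  noisy by nature; the package reports them without multiplicity
  adjustment, as in the design being emulated.
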