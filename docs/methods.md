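# Methods

## The estimation problem

Whole-animal size in squamates is conventionally summarized by snout–vent
length (SVL); for skeletons and fossils the usable analogue is precaudal
length (PCL), snout tip to the last presacral centrum, which avoids the
highly variable tail. Fossil monitor lizards are usually represented by a
braincase or isolated dorsal vertebrae, so the package calibrates two
proxies on extant skeletons:

- **BCL** — lateral braincase length, anterior tip of the basipterygoid
  process to the tip of the paroccipital process;
- **DVL** — centrum length of a posterior dorsal vertebra, anterior
  midline lip to the posteromedial condylar lip, excluding the condyle's
  articular surface.

The bundled calibration table holds 21 skeletons of 15 extant *Varanus*
species spanning 174–1478 mm PCL, each with BCL, DVL and PCL.

## The ratio model

For a calibration group the mean ratio is computed as the **ratio of
sums**, r̂ = ΣPCL/Σx, not the arithmetic mean of per-specimen ratios. The
two conventions differ in general (17.68 vs 17.65 for the full-table
PCL/BCL case); the ratio of sums is a proxy-weighted mean of per-specimen
ratios and is the convention under which all of the package's reference
statistics were derived. Dispersion is the sample standard deviation
(n−1 denominator) of the per-specimen ratios.

A fossil element of length L is predicted at L·r̂ with interval half-width
z·s·L/√n (z = 1.96 by default, configurable). This is a
normal-approximation **confidence interval on the group mean ratio**,
rescaled by L — *not* a prediction interval for a new individual, which
would be wider (roughly z·s·L for large n). Both interpretations are
defensible for fossils; the package implements the mean-ratio interval
because that is the form its bundled reference estimates follow, and the
distinction is documented here rather than hidden.

Groups are defined in an editable YAML config (label → specimen ids, or
`all`), because subclade membership is a taxonomic judgement, not a
property of the measurement table. The default config ships four groups:
all specimens; the two *V. komodoensis* skeletons; a six-specimen
Indo-Asian A set (*bengalensis* ×2, *flavescens* ×2, *rudicollis*,
*salvator*); and komodoensis + *gouldii* (the large-bodied comparators
used for the Pleistocene giant).

Numerical notes: estimates scale exactly linearly in L (equivariance is
tested to 1e-12 relative); the mean ratio always lies within the range of
per-specimen ratios (weighted-mean property); a single-specimen group
yields a point estimate with no interval and a warning; a group with no
member carrying the proxy is an error, not a silent skip. Report rendering
uses one decimal below 1000 mm, whole millimetres above, and four
significant figures for half-widths; tests compare unrounded values.

## Trendlines

Ordinary least squares of PCL on each proxy (via statsmodels) provides
slope, intercept and R² as a descriptive check that the proxies track size
tightly (R² ≈ 0.96 for BCL, ≈ 0.96 for DVL on the full table). A two-point
fit is exact and reports R² = 1; proxies with zero spread are rejected as
degenerate. The OLS line is not used for the headline estimates — the
ratio model is — but both are exposed, and the line through the
komodoensis calibration points reproduces those points exactly.

## Size ranking

A fossil PCL estimate is compared directly against maximum reported SVLs
of extant species (PCL and SVL measure the same trunk span, osteologically
vs externally; no conversion factor is applied). Counting is at species
level: subspecies rows collapse onto the species epithet, a species' size
is its maximum over all rows, rows lacking SVL are dropped, and "larger
than" is strict (ties count against the fossil). On the bundled 84-row
size table this yields 49 *Varanus* species with usable SVL; a 664.5 mm
estimate exceeds 43 of them (87.8%). `project_exceptional` multiplies a
species mean by a percent factor, reflecting that the largest wild
individuals of several monitors run 150–225% of their species mean.

## Ancestral areas

Ancestral biogeographic areas are reconstructed under the Fitch criterion:
minimize the number of unordered state changes on a rooted tree. The
implementation is a 0/1-cost dynamic program (the Sankoff recursion with
the Fitch metric): per node and state, the minimal subtree cost; the tree
length is the root minimum. This generalizes exactly to polytomies and to
polymorphic tips (a tip with states {Africa, Asia} contributes cost 0 for
either), where the classical intersection-else-union set rules need ad-hoc
extensions. A top-down pass recovers, per node, the states attainable in
at least one most-parsimonious reconstruction. On strictly binary trees
with singleton tips the per-node argmin sets coincide with classical Fitch
down-pass sets (property-tested against an independent implementation of
the set rules).

Correctness is anchored by `brute_force_min_length`, an exhaustive
enumeration of all internal-node labelings (refused above 12 internal
nodes or 5 states); the dynamic program matches it on every random
instance tested. The bundled example tree is a deliberately stylized
six-leaf summary of varanid biogeography (a North American outgroup, the
African radiation, a widespread Africa+Asia lineage, Asian and
Australasian crown groups); on it the monitor crown node reconstructs with
Asia among its optimal states. It is illustrative only — real analyses
should supply their own tree and area file.

## Synthetic data

`simulate_specimens` draws PCL log-uniformly over a configurable range
(default 174–1478 mm, matching the calibration table's span) and sets
proxy = (PCL/r)·(1+ε) with ε ~ Normal(0, cv). Noise is multiplicative
because the data are scale-free ratios; cv defaults to 0.13, the empirical
coefficient of variation of the bundled table's PCL/BCL ratios. A single
numpy generator seeded from the config drives all draws, so tables are
bit-reproducible. `simulate_fossil` is noiseless (length = PCL/r), making
estimate∘simulate an exact inverse in the noiseless limit — used as a
round-trip test. `simulate_tree_tip_states` grows a random rooted binary
topology by repeated joining and evolves one area character from the root
with a fixed per-branch change probability, recording the realized change
count (an upper bound on parsimony length, asserted over many replicates).

What the generator does **not** emulate: phylogenetic correlation among
specimens (real ratios are similar within clades; simulated specimens are
exchangeable), measurement error on PCL itself, and allometric curvature
(real PCL/proxy ratios may drift with size; simulated ratios are
size-independent). Passing simulation tests therefore certify the
estimator's arithmetic and its sampling behaviour under its own
assumptions, not the biological adequacy of ratio scaling.

Monte-Carlo problem sizes were chosen to give stable estimates at desk
scale: bias at 200 replicates of n=50 (measured |relative bias| < 1% at
cv = 0.05), coverage at 1000 replicates of n=21.

## Known limitations

Two reference checks fail by design rather than being papered over:

1. **The full-table PCL~DVL trendline.** The reference values for this one
   line (slope 39.93, intercept −24.20, R² 0.975) cannot be obtained from
   the 21 bundled calibration rows, which give 38.72 / −11.20 / 0.964. No
   defensible variant reproduces them — excluding up to three rows,
   species-mean aggregation, inverse regression, or appending the fossil
   points — so they appear to derive from additional measured specimens
   that are not in the published calibration table (whose caption mentions
   28 specimens against 21 printed rows). The BCL full-table line and all
   four subgroup lines do reproduce exactly. The package reports the OLS
   fit of the data it actually has.

2. **Interval coverage under wide size ranges.** At the calibration's own
   operating conditions (n=21, cv=0.13, sizes spanning almost an order of
   magnitude) the nominal-95% interval covers a known fossil size in only
   ~90–92% of simulations, short of the 93–97% band expected of a
   well-calibrated interval. The cause is structural: the ratio of sums
   weights specimens by proxy size, so its effective sample size (≈15 for
   a log-uniform 174–1478 mm table) is smaller than n, and s/√n
   understates the true sampling error. With near-equal specimen sizes
   coverage is ≈94–95% (tested). Users wanting calibrated intervals from
   heterogeneous calibration sets should prefer size-stratified groups or
   a weighted variance estimate; the package keeps the simple formula
   because it is the one its reference estimates encode, and documents the
   shortfall instead of silently widening intervals.

Other limitations: no phylogenetically corrected regression (GLS), no
body-mass estimation, no log-transformed allometry — ratio scaling is
assumed linear through the origin; and the ancestral-area stage performs
no tree search or likelihood biogeography (DEC etc.), only parsimony on a
user-supplied topology.
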