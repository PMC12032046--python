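# Methods

This note records the models, defaults and numerical choices behind
`ilqtl`, in the spirit of a statistical methods appendix. Nothing here
states an empirical result the test suite or `scripts/acceptance.py` does
not itself compute.

## Study design the package models

An introgression library (IL): `n_lines = 69` inbred lines carrying donor
segments in a recurrent background, plus the two parents included as
all-recurrent and all-donor genotypes. Phenotyping: a gridded greenhouse
platform with `n_reps = 8` plants per line in each of two watering
treatments (`ww`, `wd`), daily records of fresh shoot biomass, leaf area,
transpired water and visible leaf count; and a seedling paper-roll assay
(root/shoot dry weights, 6 replicates). The analysis chain — segment
calling → trait derivation in thermal time → spatial correction →
heritability/BLUPs → segment-wise association → LD clustering — mirrors
how such libraries are analysed in practice.

## Synthetic genotypes

* Introgression count per line ~ Poisson(3.3); chromosome chosen uniformly
  among 10 chromosomes of 230 Mb; segment length ~ Exponential(mean 39 Mb)
  truncated at the chromosome; start uniform. The length distribution is a
  modelling choice — published libraries report only ranges and means — and
  placement ignores recombination-map nonuniformity.
* Markers: evenly spaced (default 190/chromosome); calls inside a placed
  interval are donor homozygous, elsewhere recurrent; a configurable
  fraction of calls is set missing (default 1%) or heterozygous (default
  0); ILs are treated as inbred.
* `min_qtl_carriers` (default 10) tops up the carrier count at each planted
  QTL position by adding covering intervals to randomly chosen lines. Real
  libraries are constructed so that targeted regions are represented; a
  scan on segments carried by one or two lines is uninformative.
* Called-run counts undercount planted intervals by ~0.3/line at default
  geometry: same-chromosome intervals that overlap merge into one run, and
  intervals shorter than the marker spacing can miss every marker. The
  generator's truth table (`simulate_library_with_truth`) preserves the
  planted intervals for exact accounting.

## Synthetic phenotypes

Daily biomass follows `b(τ) = EV·exp(r₀(τ − τ_on))` before the stress
onset day and `b(τ) = EV + R·(τ − τ_on)` after it, in thermal time τ. Only
the evaluation window (onset → harvest) feeds the derived traits, and there
the trajectory is exactly linear, so a plant's biomass-accumulation trait
equals its planted rate `R` — planted effects are recovered exactly when
variance components are zero.

Per plant and trait, the underlying window parameter is

    mult · (baseline + G_line + GxE_line,trt + σ_spatial·S(row,col) + e_plant) + Δ_QTL

with `mult` the multiplicative wd factor (biomass 0.282, water use 0.456,
from the published population means 3.78/13.41 and 110.75/242.87) applied
to the whole distribution so heritability is preserved across treatments
and rates stay positive; `Δ_QTL` is the sum of planted effects of carried
segments, stated on the scale of their own treatment and therefore added
unscaled. The spatial surface `S` is a standardized random quadratic in
(row, col), shared across traits and scaled by each trait's
`σ_spatial` — smooth enough that the row/column model and the moving
averages are distinguishable.

WUE is not simulated directly: it emerges as `100·R/W` from the biomass
and water channels. Planted WUE effects act through the water channel
(the carrier's water rate is rescaled so WUE shifts by the planted
amount at fixed biomass rate). Water is distributed over days
proportionally to leaf area × thermal-time increment and rescaled so the
window total matches the plant's water-use parameter exactly; hence the
identity `biomass_acc = wue/100 × water_use` holds to machine precision
for every simulated plant.

Default variance components were sized so that entry-mean h² at 8
replicates — including the line variance contributed by the default
planted QTL scenario — falls in the 0.77–0.93 operating band reported for
such platforms (the acceptance script prints the realized range). Seedling
root/shoot components similarly target h² ≈ 0.8. Specific transpiration is
fully emergent (water ÷ leaf area); its absolute scale is not calibrated
to any published mean because water totals and leaf area are both already
constrained.

What the generator does **not** emulate: stomatal/soil-water dynamics,
image-derived measurement error structure, leaf-area allometry beyond
proportionality to biomass, and recombination-based segment sharing
between related lines. Passing tests demonstrate the statistical machinery
under the assumed variance structure, not physiological realism.

## Traits

* Thermal response `f`: linear degree-day above 0 °C, normalized at 20 °C
  (`τ = Σ f(T_i)Δt_i / f(20)`), pluggable via the `response` argument; at
  constant 20 °C every response gives 1 T-day per day. Temperatures are
  validated to 0–45 °C.
* Window endpoints are inputs, interpolated linearly in thermal time;
  water totals interpolate the cumulative curve, which is what makes the
  WUE identity exact.
* WUE is reported per 100 g water: the 0.035–0.056 g/g biomass/water
  ratios then print as the 3.5–5.6 magnitudes used in the field, and QTL
  effects on WUE read as percentage points.
* "Standardized" response traits divide by the treatment population mean
  (`res = (x_ww/μ_ww)/(x_wd/μ_wd)`), keeping the population mean near 1;
  z-scoring was rejected because near-zero denominators would explode the
  ratio.
* Specific transpiration averages per-interval ratios (water over mean
  leaf area per T-day); a ratio-of-totals variant is flag-switchable.

## Spatial correction and heritability

* Outliers: |value − median| > k·σ̂ within line × treatment cells, k = 3.5,
  σ̂ the MAD scaled by 1.4826 and the finite-sample consistency factor
  (b₈ = 1.129 …). Without the small-sample factor the rule flags ~2.2% of
  Gaussian cells of size 8; with it ~1.5%. This stands in for unpublished
  platform-specific outlier rules.
* Row/column model: fixed row and column effects with genotype as random
  intercept (REML via statsmodels MixedLM; OLS on genotype-demeaned values
  as fallback, identical in balanced layouts). Moving averages subtract
  the mean neighbour deviation (population-mean or genotype-mean
  deviations) in a square window of radius 1 (8 neighbours, configurable);
  isolated plants are left uncorrected with a warning. Composite methods
  chain the mixed model with both moving averages in either order. All
  corrections are re-centred so the population mean is preserved exactly.
* Heritability: one-way ANOVA estimators, σ²_e = MS_within,
  σ²_G = max(0, (MS_between − MS_within)/n₀) with n₀ the
  unbalanced-design effective replicate number; h² = σ²_G/(σ²_G + σ²_e/n₀),
  clamped to [0, 1]. The truncation at 0 makes the null estimator biased
  upward (mean ≈ 0.07 at 69×8 while the median sits at ~0); tests check
  the median under the null and the mean under signal.
* Method selection maximizes h², ties broken in the fixed method order, so
  selection is deterministic.
* BLUPs: `μ̂ + w_i(ȳ_i − μ̂)`, `w_i = σ²_G/(σ²_G + σ²_e/r_i)`.

## Association scan and clusters

* The scan runs on line **entry means** of corrected values. In a balanced
  design, BLUP-based and mean-based t statistics are identical (shrinkage
  rescales all lines equally), but shrinkage attenuates effect sizes by
  `w`, which would bias reported effects in trait units; entry means keep
  effects unshrunken, matching how unit-scale QTL effects are reported.
  BLUPs are used for correlations, PCA and Dunnett, as is conventional.
* Pooled-variance two-sample t (df = n−2) by default, Welch behind a flag;
  segments with fewer than 3 carriers (or fewer than 2 non-carriers) are
  skipped and excluded from the multiplicity. Bonferroni multiplicity is
  the number of segments actually tested **per trait**; consequently the
  controlled family is one trait's scan (per-family error ≈ 0.01 at
  α = 0.01), and the probability of some hit across 9 trait families is
  ≈ 1 − 0.99⁹ ≈ 0.086 under the global null — an arithmetic consequence of
  per-trait control, not an inflation of any single family.
* `effect_pct` is relative to the non-carrier mean (a +0.76 effect on a
  3.78 baseline reads +20.1%).
* Stepwise refinement: greedy forward–backward selection on AIC over the
  significant segments of one trait (p-threshold entry/stay criterion
  available); perfectly collinear carrier sets are aliased to one
  representative beforehand. The retained set is always a subset of the
  input.
* Clusters: significant segments are nodes; high-LD edges (Fisher
  p < 0.01) connect them unless the pair shows opposite effect signs on a
  shared significant trait; connected components qualify when their union
  of associated traits has size ≥ 2; components still containing a
  conflicting pair via intermediaries are split greedily in canonical
  (chromosome, start) order, making output independent of input order.
  The cluster span is the union of member spans.
* Unique segments use exact-span identity; carrier status uses containment
  (a line carries a unique segment spanned by one of its own segments).
  Exact-identity carrier assignment is available; containment is the
  default because overlapping long introgressions are what give short
  unique segments multiple carriers.

## Dunnett contrasts

Many-to-one t statistics with the residual variance pooled across all
groups; family-wise adjustment by seeded Monte Carlo evaluation of the
max-|t| null reference (10⁵ draws by default, one shared chi scale per
draw). The Monte Carlo tolerance is ~0.01 in p at default draws; adjusted
p-values are floored at the raw p. On small fixtures the procedure matches
the multivariate-t implementation in scipy to ~3 decimals.

## Coordinates and conventions

Spans are 1-based closed bp; lengths are (end − start)/10⁶ Mb; exported
segment tables state this in their header (deviating from BED half-open).
Segment boundaries sit on the first/last donor-scored SNP (conservative);
midpoint extension toward the flanking recurrent SNPs is available behind
a flag. Up to two consecutive missing calls bridge a run by default. A
single genome-wide Mb↔cM ratio (~39 Mb ≈ 25 cM) is appropriate for
reporting only and is not used in any computation.

## Problem sizes in tests

The test suite simulates at the study scale where the property demands it
(69 lines × 8 replicates for heritability recovery, power and type-I
calibration; ~360–400 unique segments for the null scan) and at reduced
scale (20–30 lines, 4–5 chromosomes) where geometry is irrelevant, keeping
the default run to about a minute. The acceptance script runs the full
default-scale pipeline once.

## Known limitations

* The row/column mixed model treats grid indices as unstructured factors;
  no spline/kriging surface is fitted.
* Fisher LD p-values are exact but the clustering threshold (0.01) is not
  multiplicity-corrected, as is standard for this screening use.
* The stepwise procedure is greedy; it agrees with exhaustive best-subset
  on well-separated fixtures but is not guaranteed optimal.
* Response-trait heritabilities are not computed (the traits are defined
  at line level).
* The Dunnett adjustment assumes homoscedastic groups.
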