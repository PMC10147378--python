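# Methods

This note records the models, conventions, parameter choices and numerical
decisions behind phenokit, and what the synthetic-data generators do and do
not emulate.

## Sholl analysis

**Geometry.** Profiles are computed in 2D: the z coordinate is dropped
before any distance computation. This matches the circle-area (πr²)
normalization of the semi-log density and the maximum-projected confocal
images that tracings are typically made from. The soma centre is the root
node's XY position.

**Crossing convention.** Radii run from one step (default 1 μm) to the
ceiling of the maximal node distance. In `intersections` mode, a straight
segment with endpoint distances d1 ≤ d2 crosses the circle of radius r
once iff d1 < r ≤ d2 (half-open, so a chain of collinear segments crossing
a circle is counted exactly once), and twice when the segment is
re-entrant — its interior minimum distance dips below r ≤ d1. This is the
limit of counting sign changes of (distance − r) along the edge, which is
exactly what the dense-sampling oracle in the test suite does at 0.01 μm
resolution. `branch_points` mode instead bins branch-point nodes into
annuli (r − step, r]; both modes are exposed because counting either
crossings or branch points per radius is common practice, and reports
state the mode used.

**Semi-log fit.** y(r) = log10(N(r)/(πr²)) is fitted by ordinary least
squares; the Sholl regression coefficient is k = −slope. Log base 10 is
used throughout. Radii with N(r) = 0 are dropped before the transform
rather than pseudocounted — a pseudocount would bias the tail, and the
zero radii carry no density information for the fit. Per-neuron fits
require at least 3 points and are flagged `included` only when R² > 0.8
(strict); excluded fits are still reported.

**Pooled genotype fit.** Counts are averaged per radius across all neurons
of a genotype, with neurons shorter than r contributing 0 — the average is
over the full cohort at every radius, not over survivors. Radii whose mean
count falls outside the [10th, 90th] percentile band of the mean-count
distribution (linear-interpolation percentiles, bounds inclusive) are
excluded, and the remaining semi-log points are fitted with no R² gate.
The percentile filter operates on the distribution of per-radius mean
counts; filtering on radii or per-neuron values would be alternatives, and
the bounds are arguments (`pct_low`, `pct_high`) so either end can be
disabled with 0/100.

## Morphometry

A branch point is a node with ≥ 2 children; multifurcations count once.
The soma is never a branch point: its k stems start k primary neurites
instead. Primary neurite length is the geodesic (along-path) distance from
the soma to the first branch point of the stem, or to the tip if the stem
never branches — consistent with terminal neurite length being the
geodesic from a leaf back to its nearest ancestral branch point (or soma).
The alternative reading of "primary neurite length" as the total length of
each soma-rooted subtree is deliberately not the default, since that
quantity is recoverable from total path length and would make the
primary/terminal pair redundant. Growth-cone versus blunt terminal labels
are annotations supplied by the experimenter (classified visually from
actin staining); the package aggregates them into a per-neuron percentage
and does not attempt image-based classification.

## Imaging

Thresholds default to Otsu's method computed within the region of
interest, per channel, and can be overridden with fixed intensities. For
colocalization, qualifying pixels are ROI pixels where **either** channel
exceeds its threshold (union rule); the Pearson coefficient is then the
correlation of paired intensities over those pixels. The union rule keeps
pixels that are bright in exactly one channel — exclusion signal — which a
mutual-threshold rule would discard. Both the rule and the thresholds are
reported alongside the coefficient.

The coefficient is computed from centered dot products. Values within
1e-12 of ±1 are snapped to exactly ±1: mathematically perfect correlation
can land one floating-point ulp inside the interval after the final
quotient, and downstream code treats ±1 as the meaningful "identical /
affine-inverted" statements.

Puncta are maximal 8-connected components (the common Fiji default)
strictly above threshold, with components under `min_area` (default 4 px)
discarded as noise. Punctum size is the equivalent circular diameter
2·√(area/π) in μm, since reported aggregate/lysosome sizes are scalar
diameters without a stated measure. Per-cell assignment places a punctum
in the cell mask containing its centroid pixel; masks must be disjoint and
unassigned puncta are reported, not silently dropped. Size–frequency
fractions use strict > at each cutoff (defaults 5 and 10 μm).

## Organismal assays

**Climbing.** Displacement is position(5 s) − start along the vial axis;
velocity divides by the fixed 5 s interval. Negative values (falls) are
legitimate data. When positions arrive in pixels, calibration uses the
15 cm graduated vial length. Group comparison is an unpaired Welch t-test
(Satterthwaite degrees of freedom) — variances between genotypes are not
assumed equal.

**NMJ boutons.** The input schema gives each bouton either an integer
position on a named branch or a `sprout_of` reference; chains are maximal
runs of consecutive positions. Chain length ≥ 2 → every member is mature;
isolated on-branch boutons and all sprouts are satellites. Equivalently, an
on-branch bouton is mature iff an adjacent position is occupied — the test
suite checks both formulations agree. The package does not infer chains
from images.

**Longevity.** Deaths are scored daily, so lifespans are integers and ties
are the rule; the log-rank (Mantel–Cox) test therefore uses exact
hypergeometric tie handling rather than jitter. Median lifespan is the
Kaplan–Meier product-limit median (smallest t with S(t) ≤ 0.5), which on
an uncensored even-sized cohort is the lower middle order statistic. A
raw sample median would agree in the uncensored case but is biased under
censoring. The rescue criterion is conjunctive and strict: rescue ⇔
(median increase > 5%) AND (log-rank p < 0.05); exactly +5.0% is not a
rescue.

## Synthetic data generators

All generators are pure functions of (parameters, seed); there is no
global random state. They create statistical structure with known ground
truth, not biology.

**Neurons.** Segments grow radially outward in 1 μm steps with angular
jitter. When a target decay k₀ is requested, each live segment's expected
offspring per step at radius r is ρ(r) = ((r+s)/r)²·10^(−k₀·s), realised
as ⌊ρ⌋ children plus a Bernoulli remainder (multifurcations allowed). The
product telescopes so E[N(r)] = stems·(r/s)²·10^(−k₀(r−s)), making the
semi-log density exactly linear with slope −k₀ — a constant
branch/termination probability cannot produce the required r-dependence.
Two details keep the generator's live-segment bookkeeping identical to the
analysis module's crossing counts: angular perturbations are arc-length
limited (s.d. capped at 5° near the soma, shrinking like 1/r), which makes
every segment's distance from the soma strictly increasing, so no segment
is re-entrant; and node radii carry a +1e-6 μm offset so no node sits
exactly on a counting circle, where the half-open crossing convention
would otherwise tie-break on a 1-ulp rounding of √(x²+y²). Defaults
(3 stems, k₀ = 0.08/μm, 40 μm extent) give arbors of order 10²–10³ μm
total path length, comparable to cultured motor neurons at tracing age.
What is *not* emulated: tortuous paths, re-entrant branches, tropism,
soma extent, 3D structure — so passing recovery tests show the estimator
chain is correct, not that real arbors satisfy the exponential model.

**Two-genotype populations.** Group B defaults to twice the decay and 75%
of the radial extent of group A, emulating a reduced-complexity genotype
with an unambiguous ordering of total path length.

**Survival.** Lifespans are Weibull with shape 3 — an ageing-type
(increasing) hazard typical of fly senescence — with the scale set so the
continuous median equals the request, then rounded up to whole days.
Censoring marks the requested fraction of flies at a uniformly drawn day
within their lifespan. Cohort defaults (100 flies/group, control median
20 d at the stress-rearing temperature, 5% censoring) mirror common
longevity-assay cohort sizes.

**Images.** Colocalization pairs are correlated Gaussian fields (mean 120,
s.d. 15, clipped at 0 — a >8σ event, so effectively never) with exact
affine copies at ρ = ±1. Puncta images draw flat-topped disks at
saturating intensity over a dark background with sparse single-pixel
speckles (fraction 10⁻³) standing in for shot noise; speckles are isolated
by construction so Otsu thresholding plus the 4 px minimum area removes
them. Dense Gaussian background noise is deliberately not used: Otsu marks
roughly half of a pure-noise image as foreground, which percolates into
large spurious components and models no real imaging regime of interest
here.

## Numerical and interface choices

- SWC dialect: 7 whitespace columns, single root with parent −1,
  coordinates in μm, comments preserved; write precision 4 decimals
  (0.1 nm — far below optical resolution), round-tripping node-for-node.
- Degenerate inputs raise informative errors rather than returning NaN:
  <3 fit points, all-identical abscissa, zero-variance channels, undefined
  KM median, overlapping cell masks, dangling sprout references.
- ANOVA on groups with zero within-group variance follows the F → ∞,
  p → 0 limit of the underlying statistics library.
- The pipeline report bundle (CSV tables, summary JSON, log) contains no
  timestamps, and floats are printed with a fixed format, so identical
  config and seed reproduce identical bytes.
- Problem sizes in the verification script (200 oracle trees, 10×200
  neurons for decay recovery, 256² image fields, 100-fly cohorts, 40
  null-simulation seeds, 1000 bouton graphs) were chosen to put Monte-Carlo
  error well inside each tolerance while keeping a desk-scale run in tens
  of seconds.

## Known limitations

- 2D Sholl geometry: a 3D distance option would need a 4πr² (sphere)
  normalization to remain a density; the πr² convention is kept for
  comparability with projected-image analyses.
- The percentile filter for the pooled fit assumes the genotype cohort
  shares a radial step; mixed-step studies must resample first.
- Pearson colocalization is sensitive to the thresholding rule; Manders or
  Costes-style analyses are out of scope.
- The rescue criterion inherits the discreteness of daily death scoring:
  with a 20-day control median, the smallest observable increase above 5%
  is 2 days (10%).
- Growth-cone classification, cell segmentation, neurite tracing and
  bouton detection are upstream of this package and are not performed here.
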