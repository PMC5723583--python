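# Methods

This note documents the models, conventions and numerical choices behind
`elevgrad`, and what its synthetic-data tests do and do not establish.

## The banded domain

All analyses run on an `ElevationGrid`: contiguous half-open bands
`[lo, hi)` of fixed width tiling `[domain_lo, domain_lo + n·width)`, with
`n = ceil((domain_hi − domain_lo)/width)`.  When the domain length is not a
multiple of the width the final band extends past `domain_hi` to the next
band boundary: a 600–4,300 m domain at 200 m gives 19 bands ending with
[4,200, 4,400).  The alternative — truncating the last band at 4,300 m —
would change band areas, not memberships, and is not offered; the
convention is flagged here because the source data for such analyses often
quote the domain top rather than the grid top.

A species interval `[lo, hi]` (closed) overlaps a band iff
`lo < band_hi and hi > band_lo`.  Strict inequalities mean a range that
only touches a band boundary is not counted in that band, preventing
double-counting at shared edges.  A degenerate point range (`lo == hi`)
occupies exactly the band containing the point under the half-open rule.
Survey records on a boundary likewise belong to the upper band.

## Richness

Interpolated richness assumes range-through occupancy: a species occupies
every band between its elevational limits.  It therefore dominates observed
(record-based) richness band-by-band, a relation asserted in tests.

## Mid-domain-effect null model

The null model is the fully stochastic continuous bounded-domain model:
every empirical range size `R` is kept and its midpoint redrawn uniformly
on the feasible interval `[L + R/2, U − R/2]`, where `[L, U]` is the grid
span (U = top of the last band).  Per replicate, band richness is recounted
under the same overlap rule as the empirical analysis; the result is the
per-band mean and percentile (2.5/97.5) envelope over replicates,
reproducible from the seed (default 50,000 replicates).

Because midpoints are uniform, the occupancy probability of band `[a, b)`
for a range of size `R` has the closed form

    P = |[a − R/2, b + R/2] ∩ [L + R/2, U − R/2]| / (U − L − R),

with `P = 1` when `R = U − L` (midpoint forced).  The simulator is tested
against this expectation to within 4 Monte-Carlo standard errors on random
configurations; the expectation itself is exercised on hand-computed
cases.  Range sizes are *not* resampled across replicates — the null keeps
the empirical size distribution fixed and randomizes placement only.

The "explanatory power of the MDE" is quantified as the OLS R² of
empirical band richness on the null-model mean, the standard practice when
a single summary is wanted.

## Ancestral elevational ranges

Internal-node midpoints and range sizes are reconstructed independently as
continuous traits by weighted squared-change parsimony: the states
minimising `Σ_edges (x_child − x_parent)²/branch_length` with tips pinned.
These are the joint ML ancestral states under Brownian motion, obtained
exactly by solving the sparse first-order system (each internal state is
the weight-harmonic average of its neighbours).  Properties used as tests:
the solution matches a generic numerical minimiser of the same objective;
internal states lie in the convex hull of tip values; the root equals the
GLS phylogenetic mean computed by explicit covariance inversion.

Zero-length internal branches are collapsed into polytomies before solving
(singular weights otherwise); a zero-length terminal branch is an error
because the tip value would pin its parent.  Reconstructed sizes are
clamped at zero; `log_size=True` reconstructs log-size instead when all tip
sizes are positive.  No uncertainty is attached to node states — the
downstream colonization metrics treat the reconstruction as fixed, a known
limitation of this family of methods.

## Colonization metrics

Given reconstructed intervals at all nodes of an ultrametric tree, the
interval endpoints along an edge are interpolated linearly in time between
parent and child.  For a fixed band both overlap inequalities are linear in
time, so the set of times the lineage overlaps the band is one interval and
the *entry time* (oldest time of overlap) is solved in closed form.  One
colonization event is emitted per (edge, band) first entry; bands inside
the root's interval are seeded with events at root age (without root
seeding the oldest ages would be undefined).  Boundary-touching overlaps do
not count (strict inequalities, consistent with the richness rule).
Re-entries on different edges are separate events; within one edge
convexity forbids re-entry, which is asserted rather than assumed.

Per band the events give: frequency, oldest age, summed age (SAC — the sum
of event ages, blending age and frequency), and average age (NA for empty
bands).  The alternative event-age conventions `child`/`parent` (assigning
the node age instead of the interpolated entry time) are exposed as a
config option because the interpolation choice cannot be pinned down from
published descriptions of this metric family; `interp` is the default as
the only internally consistent reading of "first arrival".

## Diversification rates

The method-of-moments estimators at relative extinction fraction
ε = μ/λ ∈ [0, 1):

* stem, n ≥ 1: `r = ln(n(1−ε)+ε)/t`
* crown, n ≥ 2:
  `r = [ln(n(1−ε²)/2 + 2ε + ((1−ε)/2)·√(n(nε²−8ε+2nε+n))) − ln 2]/t`

with the exact limits `ln(n)/t` and `(ln n − ln 2)/t` at ε = 0 and
monotone non-increase in ε, both property-tested.  The per-clade table
takes user-supplied monophyletic tip sets (crown age = MRCA age, stem age =
its parent's age, absent for the root clade) plus each clade's tip-mean
elevation and reconstructed ancestral (MRCA) midpoint.  When no clade file
is given, all internal-node subtrees of size ≥ 2 are tabulated for
exploration; they are nested and not an independent sample, so regressions
on them are indicative only.

## Rapoport statistics

Stevens' profile: the arithmetic mean range size of the species overlapping
each band (same overlap rule; bands share species, so the points are
autocorrelated by construction).  Cross-species table: one (midpoint, size)
point per species.  Trend tests for both are plain OLS in the stats layer;
no phylogenetic correction is applied to the cross-species regression by
design (the classical form of the test).

## Regression layer

OLS always includes an intercept; degree 2 adds squared terms of each
predictor (used by default for richness~MAT and range-size~AP, the two
relationships expected to be unimodal; every degree is overridable).
Standardization (centering and unit SD) is applied to predictors in
multiple regressions; R², the overall F-test p and fit quality are
invariant to it.  Adjusted R² is the Ezekiel correction
`1 − (1−R²)(n−1)/(n−p−1)`.  VIF screening regresses each predictor on the
others (`VIF = 1/(1−R²)`) and greedily drops the worst offender until all
VIFs fall below the threshold (3 by default); exact collinearity drops the
later column.

Three-set variance partitioning fits the seven submodels {A}, {B}, {C},
{AB}, {AC}, {BC}, {ABC} and decomposes the full-model *adjusted* R² by
inclusion–exclusion into three pure, three pairwise-shared and one
three-way-shared fraction plus residual.  The seven fractions sum to the
full-model adjusted R² identically; raw fractions may be slightly negative
(a well-known property of adjusted R²), so a zero-truncated copy is
reported alongside for display.  In the pipeline the three sets are MAT
(energy), the MDE null mean (geometry) and SAC (evolutionary history) —
SAC is used as the evolutionary predictor because it blends colonization
age and frequency into one band-level quantity.

Bands with no species have NA Stevens means and NA average colonization
age; such rows are dropped (and logged) from the affected regressions but
retained everywhere else.

## Synthetic data: the stated world

Defaults describe one fixed world and are not tuned per analysis:
19 species on a 600–4,300 m domain in 200-m bands; a constant-rate
birth–death tree (λ = 0.2/Myr, μ = 0) conditioned on the tip count;
midpoint and size evolving by independent BM at σ² = 10⁴ m²/Myr from a
root at 2,450 m midpoint and 1,200 m size (drift of ~100 m per √Myr —
enough to spread ranges over the domain on a ~10-Myr tree without pinning
them to its edges); climate with a 6.5 °C/km MAT lapse from 15 °C at the
domain base, increasing diurnal range and seasonality, unimodal annual
precipitation, decreasing dry-quarter precipitation, and upslope-shrinking
drainage areas; surveys uniform within each range.  One master seed feeds
named substreams (tree/traits/climate/survey), so any stage can be
regenerated independently.

Tree conditioning uses the general sampling approach (simulate past the
target tip count and draw a time at which exactly n lineages were extant).
The naive alternative — stopping at the n-th speciation — returns a tree
whose youngest terminal branches have zero length, which the reconstruction
contract rejects; GSA also removes the bias toward too-young trees that
stop-at-birth sampling induces.

BM evolution reflects sizes at zero and clips intervals to the domain at
every node; the recorded "truth" is the post-clipping state, so truth and
emitted tips are consistent by construction.  Clipping makes tip traits
slightly non-Brownian near the domain edges — reconstruction-recovery tests
therefore assert correlation with truth (> 0.7 on 50-tip trees averaged
over 20 seeds), not unbiasedness.

A separate fixed, hand-written stand-in range table of 19 species
(`synthetic_loach_ranges`) embodies the qualitative structure expected of a
plateau stream-fish fauna — unimodal interpolated richness peaking in the
2,200–2,400 m band, broader ranges upslope.  It exists so examples and
headline checks have a deterministic, documented input; it is synthetic and
carries no information about any real survey beyond those stated facts.

## What a green test establishes

Synthetic tests validate internal consistency (simulator vs closed form,
solver vs numerical oracle, event detector vs lattice scan, partition
identity) and parameter recovery under the generator's assumptions.  They
do not validate the assumptions themselves against real faunas: real range
data carry sampling error in the limits, real trees carry topological and
dating uncertainty, and real climate covariates are spatially
autocorrelated in ways the trend+noise generator does not emulate.
Statistical caveat: with 19 bands, a ±2·SE interval on a regression slope
has t(17) coverage ≈ 93.8%, not 95% — recovery rates should be compared to
the t-based nominal level, not the Gaussian one.

## Determinism and tolerances

Every stochastic routine takes an explicit seed; reports serialize with
sorted keys and are byte-identical across runs of the same inputs.
Ultrametricity is declared at relative tolerance 1e-6 on root-to-tip
depths.  The colonization lattice oracle uses a time step of 1e-4 of the
root age and matches entry times to 1e-3 of it.  The ancestral solver is
exact up to the linear-algebra solve (no iteration); the MDE simulator's
chunked evaluation is bit-independent of the chunk size.
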