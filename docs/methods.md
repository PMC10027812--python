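# Methods

`qisipop` builds an integral synthetic population for small census
geographies from four public-release-style inputs — a weighted individual
microdata sample, a household-grouped (hierarchical) microdata sample,
per-area aggregate profiles and a geographic hierarchy — plus a projection
table of future person counts by province, scenario, year, sex and age
group. The pipeline has four sequential stages: base-year synthesis,
scenario projection, household assignment and household typing, followed by
validation metrics.

## Base synthesis: IPF + quasirandom integer sampling (QISI)

Seven attributes are synthesized jointly: age group (18 five-year bands,
85+ open), sex, highest degree (3), labour force status (3), household-size
category (5), income band (4) and the primary-maintainer flag (2) — a
7-axis contingency table of 12 960 cells.

**Seed.** The weighted microdata records of the province are summed into
the table. Cells unobserved in the sample receive a smoothing value ε
(default 10⁻⁶ × the smallest positive cell weight) so that a marginal
demanding a combination absent from the sample does not make fitting
infeasible; ε = 0 disables smoothing and restricts the synthesis support to
observed combinations (giving a realism fraction of exactly 1, at the cost
of possible infeasibility when the sample misses an age-sex cell that the
area's aggregates require).

**Marginals.** Per area, target vectors are read from the aggregate
profile: total population N, households H (as the maintainer margin
(N−H, H)), sex, age group, the age-group × sex joint, household size,
degree, labour status and income band. Profile rows for degree, labour
status and income cover ages 15+ only, so the 0–14 population is added to
"no degree", "not in labour force" and the lowest income band. Household
counts by size are converted to persons by size (size × count, 5 for the
open category). A variable wholly missing from an area's profile is imputed
as N × the province-level distribution (taken from the weighted seed).

**Matching.** Published counts are randomly rounded and so do not sum to
N. Each vector is adjusted to sum to N by allocating ±1 increments along
the province distribution using largest-remainder apportionment — the
minimal total change, never driving an entry negative, idempotent on
already-matched input. The age × sex joint is then reconciled to the
matched age and sex vectors (a 2-D fit followed by a margin-preserving
integerisation), so the eight constraints are mutually consistent. Where
rounding makes the raw joint disagree with the raw single-axis vectors, the
single-axis vectors win; this is the declared tie-break. Households
exceeding N after rounding are capped at N and logged.

**IPF.** Iterative proportional fitting scales the seed against each
constraint in a fixed declared order (the age × sex joint first, then
degree, labour status, household size, income, maintainer, then age and sex
last), to an L∞ marginal residual ≤ 10⁻⁹ (at most 1000 sweeps). Structural
zeros conflicting with positive targets raise a convergence error carrying
the residual. The fit preserves the seed's odds ratios wherever
unconstrained.

**Integer sampling.** Individuals are drawn one at a time from the fitted
table. An integer quota per constraint category is decremented at each
draw, cells with any exhausted quota are excluded, and the table is
refitted to the remaining quotas with a couple of IPF sweeps per draw
(running to convergence over the last few dozen persons, where a stale
table could otherwise steer the draw into an infeasible corner). Every
constrained marginal of the drawn population therefore equals its integer
target exactly, with no separate integerisation step; the random stream
only decides *which* feasible table is realised, and the expected cell
counts track the fractional table. A dead end (possible in principle with
ε = 0) raises a sampling error and the area is retried, continuing the
area's random stream.

Randomness is derived per area from (master seed, area code), so chunked
execution and merging reproduce a single run exactly.

## Projection by resampling

For a (scenario, year, province) slice of the projection table, the signed
difference between the target and base count is computed per (sex, age
group) cell; targets are rounded to whole persons and the file's 5-year
bands above 85 are aggregated into the open band. Cells grow by duplicating
uniformly-with-replacement sampled members (full attribute copies, fresh
indices above the current maximum) and shrink by uniform deletion without
replacement. Counts match targets exactly; the within-cell distribution of
unconstrained attributes (and of areas — growth accrues to areas in
proportion to their base population) is unchanged in expectation. Projected
years are independent: each starts from the base population. Household
identifiers, exact ages and household types are reset because households
are re-assigned per projected year. Attributes themselves (income,
qualification) are carried unchanged, so long-horizon projections inherit
the base year's conditional structure.

## Households

**Exact ages** are drawn uniformly within each 5-year band; the open 85+
band uses 85 + Geometric(p = 0.2) on {0, 1, …}, capped at 120, reflecting
the rapid thinning of that cohort. (The cap assigns the tail mass beyond
120 to 120 rather than renormalising; the difference is ~4 × 10⁻⁴ of the
band.)

**Composition law.** From the hierarchical sample, the distribution of a
non-maintainer's (age group, sex) conditional on the maintainer's (age
group, sex) is estimated per household-size category, weighted by record
weights; conditioning cells unseen in the sample fall back to the
size-level distribution. Households without exactly one flagged maintainer
are dropped with a log entry.

**Assignment.** One household per maintainer, capacity given by the
maintainer's size category (1–4 persons; the 5+ category is capped at 5
members in the first two phases and relaxed to a configurable 7 in the
last). Phase 1 fills each household from the pool of non-maintainers whose
own household-size attribute matches, drawing young individuals (drawn age
< 19) before adults — young people placed late would otherwise be the ones
stranded — weighted by the composition law given the maintainer. Phase 2
tops up 5+ households with leftover 5+ individuals. Phase 3 fills any
remaining vacancy from anyone unassigned. Leftovers keep HID = −1; counts
are logged per area. The young/adult split uses the drawn age rather than
the age band, because the 15–19 band straddles the cut.

**Typing** uses member counts and ages only. One member: one-person. Two
members: more than 16 years apart → one-parent; otherwise both over 16 →
couple without children; otherwise other. Three to six members: couple
with children if the two oldest are over 16 and everyone else is under 16,
or if both of the two oldest are more than 16 years above the youngest;
else one-parent if the oldest is more than 16 years above every other
member and all of them are under 16; else other. Seven or more: other.
"Over 16" and "more than 16 years" are strict, so a member aged exactly 16
satisfies neither branch and the household falls through to "other"; the
one-parent gap is required against every other member. Where the
couple-with-children conditions overlap the one-parent condition, the
couple rule is applied first.

## Validation

Per category and geographic level (area, subdivision, province, national),
observed and synthetic counts are compared with Pearson's r, the
range-normalised RMSE (RMSE / (max(obs) − min(obs))) and the per-unit
relative absolute error |obsᵢ − simᵢ| / obsᵢ summarised by median-unbiased
five-number quantiles. Units with a zero observed count are excluded from
the RAE with the exclusion count reported. Income, degree and labour-status
categories are compared over ages 15+ on both sides, mirroring the
publication convention. A widely printed version of the correlation
formula squares the product of deviations inside a single square root,
which degenerates; the standard product-moment definition is used.
Self-comparison is an exact fixed point (r = 1, NRMSE = 0, RAE = 0) at
every level.

The realism fraction is the share of synthetic individuals whose 7-tuple
of attributes occurs in the microdata (multiset semantics). The
rounding-error model gives the error expected from confidentiality
rounding: a count with any non-zero residue mod 5, rounded 50/50 to an
adjacent multiple of 5, has expected absolute error 0.5r + 0.5(5−r) = 2.5
regardless of the residue, hence a relative error of 2.5/N for a count of
magnitude N (0.25 % at 1000, 25 % at 10); an `exact` flag instead uses the
count's own residue, so multiples of 5 return zero.

## The fixture world

The generator builds a complete fictitious ground truth: households with
one maintainer each (sizes 1–7 from a fixed category distribution; second
members are same-age partners with probability 0.8, later members children
with probability 0.85), grouped into small areas targeting 400–700 persons,
with degree, labour status and income drawn conditionally on age class and
under-15s pinned to no-degree / not-in-labour-force / lowest income. The
emitted inputs degrade this world the way a confidentiality-protected
release would: a 2.7 % simple random sample of individuals and a 1 % sample
of whole households (uniform weights = 1/fraction), per-area counts
randomly rounded 50/50 to adjacent multiples of 5 (multiples unchanged, so
rounding is unbiased), areas under 40 persons suppressed entirely, and
projection counts equal to true province counts times per-cell compound
annual growth multipliers (per scenario: low growth 0.4 %/yr, high 1.8 %,
five medium variants 1.0–1.4 %, and fast/slow-aging variants that tilt
growth towards older or younger bands by ±0.8 % across the age range —
plausible magnitudes for the projection horizon). The exact pre-rounding
counts and the manifest (seed, config) are written alongside for
verification.

What the fixtures do **not** emulate: realistic geography, collective
dwellings, calibrated (non-uniform) sample weights, missing-data sentinels
beyond the standard ones, and drift of income or qualification over
projection years. Passing tests therefore demonstrate the pipeline's
contracts (exactness, conservation, determinism, rule fidelity), not
predictive accuracy on real census data.

## Problem sizes and numerical choices

The default test world uses 10 areas of ~500 persons (one province,
~5 000 people); joint-recovery measurements use 100 areas (~50 000).
IPF tolerance 10⁻⁹ absolute, 1000 sweeps maximum; per-draw refit runs 2
sweeps (to convergence for the last 32 persons of an area). Ties in
largest-remainder apportionment resolve by stable sort order (lowest
category first). Degenerate inputs: zero-population areas are errors,
suppressed areas are skipped with a log entry, an all-zero marginal vector
is imputed from the province distribution.

A note on joint recovery: with a 2.7 % microdata sample, roughly half of a
realistic ground truth's joint-distribution mass lies on attribute
combinations the sample never observes, and even an exact 50 000-person
draw from the true joint carries ≈ 0.10 total-variation distance from it
(multinomial noise over a several-thousand-cell support). Aggregate
one-way marginals are recovered to well under 0.05 total variation, but
the full 7-way joint cannot be; the corresponding acceptance test states
the stricter contract and fails with the measured distance.
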