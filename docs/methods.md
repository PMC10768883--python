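# Methods

This note documents the models, estimators and numerical choices behind
`phylodecay`, the assumptions of its synthetic-data generator, and the
limits of what the test suite demonstrates.

## Trees and units

All phylogenies are rooted trees of sampled cells whose branch lengths
are somatic single-nucleotide alteration (SNA) counts per lineage.
Depth from the root is therefore molecular time; no calendar-time
calibration or molecular dating is performed anywhere (only the
generator maps calendar age to expected mutations, through the clock
described below).  Polytomies and zero-length branches are accepted;
tip labels must be unique; a configurable germline/outgroup tip can be
pruned before any statistic, keeping the stem branch so that
subclone-only trees still crop to a single ancestral lineage.

## Decay metrics

Colless imbalance π is the sum over internal nodes of the absolute
difference in descendant-clade tip counts.  Polytomies are resolved
deterministically into a caterpillar of zero-length branches, children
ordered by descendant tip count (largest first, ties by smallest tip
label); zero-length resolution leaves depths and the LTT curve
unchanged, so the resolution affects π only.

The ancestral tree is produced by cropping at a depth t_a: a branch
(u, v) crosses the crop iff depth(u) < t_a ≤ depth(v), each crossing
branch becomes one ancestral tip, and sampled tips shallower than t_a
(degraded colonies) count as their own crossing lineage.  With n and
n_a the contemporary and ancestral tip counts and π, π_a the two
imbalances:

    α = max(0, log₂ max(π,1) − log₂ π_a⌊),   β = log₂ n − log₂ n_a,

where π_a⌊ = 1 whenever n_a < 4 (imbalance is not meaningfully defined
on so small a tree; taking log₂ π_a = 0 makes the ancestral imbalance
smallest) and π_a⌊ = max(π_a, 1) otherwise.  The floor at 1 and the
clamp at 0 make α well defined for perfectly balanced trees and enforce
its minimum of 0 at birth.  β ≥ 0 always, since n_a ≤ n.  A Shannon
index over tips-per-ancestral-lineage is available as a descriptive
statistic only; it takes no part in age modeling.

## Detecting the end of the embryonic burst

The crop depth is the point where the initial burst of lineage
diversification ceased.  Branching events are treated as a pure-birth
point process in molecular time: between events, k concurrent lineages
contribute lineage-time k·Δdepth.  For every candidate changepoint c (a
branching depth), the score is the log-likelihood ratio of
"diversification ceased at c" against "the per-lineage rate observed up
to c continued", evaluated on the event-free interval following c:

    score(c) = rate_before(c) × eventfree_lineage_time_after(c),

with rate_before(c) = (events ≤ c) / (lineage-time ≤ c + τ).  The
pseudo-count τ = L_total/(E+1)² (L_total the tree's total lineage-time,
E the event count) keeps the rate finite and comparable when the
surviving embryonic phase is represented by very few events, as in
heavily displaced trees.  The maximizing event marks the burst's end;
the returned depth sits an epsilon (10⁻⁹ relative) after it so the
whole burst lies on the ancestral side of the crop.  This form was
chosen over a segmented two- or three-rate maximum-likelihood profile
because segment ML is degenerate for events at depth 0 and is misled by
two artefacts of sampled trees: coalescent thinning makes the visible
branching rate taper near the burst's end, and late subclonal
expansions add internally inhomogeneous event clusters; both attract
segment boundaries away from the burst.  The cessation score uses the
same likelihood but compares each candidate only against the lull that
follows it, which is the feature a human reader of an LTT plot anchors
on.  Trees with fewer than 4 branching events fall back to the deepest
branching depth (again plus epsilon); if every branching sits at depth
0, the crop lands immediately above the root.  A fixed crop depth can
always be supplied to override detection.

Known limitation: in a tree containing *only* subclonal cells (no
sampled ancestral lineage at all), the first visible diversification is
the clone's own, and the detected crop follows the clone rather than
the stem; β is then understated for such trees.  With the default
study conditions this configuration is rare (<1% of MPN-scenario
samples).

## Genetic distances and the somatic clock

Pairwise genetic differences between cells count sites at which both
cells are observed and their calls differ (pairwise deletion of missing
data) and are divided by 2 for a per-lineage distance.  Pairs with no
mutually observed site are reported missing with a warning; the
triangle inequality is not guaranteed under pairwise deletion.  The
distribution summary is the midpoint of the modal bin of an
equal-width histogram over [0, max] with 300 bins (ties resolved to the
lower bin); range and tie rules are this package's choices, fixed for
determinism.

SNA/GD accumulation versus age is fitted by through-the-origin least
squares for a constant clock (s·age) and a relaxed clock
(q·age² + s·age); there is no intercept because a newborn has
accumulated essentially no adult-phase variants.  The nested comparison
uses a likelihood ratio with Gaussian errors and MLE variance,
LRT = n·log(RSS_lin/RSS_quad), referred to χ²(1).  This test is
asymptotic: at very small n the finite-sample size of the 5% test is
inflated (exactly computable through the F(1, n−2) distribution, about
11% at n = 7), so the suite calibrates type-I error at n = 50 ages per
replicate, where the nominal level holds.  Published-scale coefficients
(q ≈ 0.06 SNAs/yr², s ≈ 12 SNAs/yr) are recovered exactly from
noiseless tables.  The quadratic coefficient is a small effect: at the
7-adult design with 5% signal noise its least-squares sampling spread
is several times wider than the slope's, which is a property of the
design information, not of the optimizer.

## phyloAge

Each marker m ∈ {α, β} follows m(age) = a·e^(b·age) with a, b > 0.
Fitting minimizes the sum of squared differences between observed and
*predicted age* (residuals in years): r_i = age_i − ln(m_i/a)/b, via a
damped Gauss–Newton iteration over (ln a, ln b) (positivity by
construction), initialized from a log-linear regression of ln m on age,
converged when the relative SSE change drops below 10⁻¹⁰ (at most 100
iterations; non-convergence raises an error carrying the last iterate).
Individuals with non-positive marker values carry no decay signal and
are dropped from fitting with a warning; at least 3 positive values are
required.  Age-space residuals make the fit's residual variance
directly interpretable in years² and feed the prediction error.

Inverting a model gives age(m) = ln(m/a)/b with a first-order
delta-method standard error: the gradient of the inverse map applied to
the (a, b) covariance (itself σ²(JᵀJ)⁻¹ from the converged fit) plus
the residual variance.  The two per-marker predictions are combined by
an inverse-variance random-effects meta-analysis: weights
1/(SE_i² + τ²) with τ² maximizing the profile normal likelihood
(bounded scalar optimization, boundary at τ² = 0 checked explicitly).
The combined phyloAge, its standard error 1/√Σw and a 95% normal
interval are reported; the combination is cross-checked in the test
suite against the reference ML random-effects implementation in R.
residualAge is stored signed (phyloAge − chronological age) because the
risk map needs the sign; summaries report its absolute value as well.

Markers with non-positive values are dropped from the combination; when
both are dropped the individual is reported as "at most the youngest
resolvable age" (the youngest age among the fitted individuals) rather
than given an arbitrary number — predictions for the young are
intrinsically less certain because the markers barely move early in
life.  Leave-one-out validation refits both marker models and the
combination without each individual in turn and reports the prediction
table, Pearson correlation with chronological age and mean
|residualAge| over completed folds (failed folds are recorded as
missing with a warning).  Cohort conventions: only the first sampling
event per individual id is used, and a minimum fitting age (default 18)
excludes infants, who are still diversifying and unrepresentative of
the stable adult phase.

## Risk

MPN incidence per 100 000 is modelled as c·e^(r·age); the shipped
default constants are c = 0.04, r = 0.08 per year, and any
user-supplied incidence table refits them by natural-scale nonlinear
least squares (same Gauss–Newton core, log-linear initialization, R²
reported; tables without an age trend are rejected with a warning).
Because incidence is exponential, the ratio of an individual's
incidence at phyloAge to that at chronological age collapses to
e^(r·residualAge); values below 1 are allowed and flagged as a
younger-than-age HSC pool.  Note the closed form evaluates to ≈28.2
for a residualAge of 41.76 years at r = 0.08; a published
headline figure of 34 for that case is not consistent with the
exponential identity, and this implementation follows the identity.

## The generator

`simulate_phylogeny` composes four processes, all seeded through one
`numpy` generator (outputs are byte-reproducible):

1. **Embryonic burst** — a pure-birth process to `n_founders` (default
   100) lineages with waiting times Exp(k), rescaled so the last split
   lands exactly at `t_emb` (default 30 SNA units); all founders are
   contemporaneous in mutation time at the burst's end.
2. **Adult clock** — every lineage's terminal branch is extended so the
   expected root-to-tip depth is M(age) = q·age² + s·age (defaults
   0.06, 12.43), Poisson-realized per branch.
3. **Neutral symmetric divisions** — each non-expanded founder lineage
   splits at 0.003 events/lineage/yr with both daughters persisting,
   giving young trees their handful of post-embryonic divergences.
4. **Subclonal expansions** — from a calendar onset age, one founder
   seeds a within-clone pure-birth process at `growth_rate`
   divisions/yr (capped at `max_clone_cells` = 2000); calendar
   intervals map to mutations through M(·), Poisson-realized, with an
   optional clone mutation-rate multiplier.

Sampling draws `sample_size` cells uniformly without replacement from
the generated cell population, so expanding clones displace ancestral
lineages exactly as an observational effect of sampling.  Truth labels
record each sampled cell's founder and expansion membership.

`simulate_sna_matrix` assigns each branch a Poisson(branch length)
batch of unique variant sites; a cell carries every variant on its root
path, and calls are masked to missing independently at the configured
rate.  `simulate_marker_cohort` draws (α, β) directly from the
exponential marker models with unit-mean lognormal noise of a given CV,
for estimator tests that need a known generative truth without trees.

Cohort scenarios: **healthy** individuals acquire CHIP-like clones as a
Poisson process (0.05/yr) over an onset window of 15–45 years with
growth rates U(0.08, 0.12)/yr — chosen so that the median decay
trajectory is near zero before ~50, a few tenths around 60–65 and α ≈
2–3, β ≈ 2 by the early 80s, matching the exponential marker curves of
healthy adults; **mpn** individuals additionally carry one driver clone
with onset at U(0.3, 0.5)× their age that reaches a target size of
U(600, 1200) cells by sampling (growth = ln(target)/(age − onset)), so
the clone keeps dividing up to the present and dominates the sample the
way driver clones dominate patient phylogenies.  These parameters are
phenomenological calibration, not claims about HSC biology.

What the generator does *not* emulate: sequencing or variant-calling
error beyond missingness, driver/passenger distinctions, selection
coefficients, within-founder population structure (each non-expanded
founder contributes one sampleable cell lineage plus its neutral
splits), and death/extinction of lineages.  Passing tests therefore
demonstrate correctness of the estimators under the stated generative
assumptions, and robustness claims (e.g. to sampling fraction) hold in
that world; they are evidence, not proof, for real colony data.

## Problem sizes and numerical conventions

Default test and acceptance runs use 50–200-tip trees, cohorts of 7–8
individuals, and 100–1000 Monte-Carlo replicates per property — sizes
at which every suite completes in well under a minute each while
leaving the Monte-Carlo bands comfortably away from their thresholds.
Sampling robustness is asserted as a variance-explained contrast
(fraction explains <20% of α/β variance, >90% of π's per tree), the
stable form of the underlying claim: with hundreds of pooled points, a
raw 5%-level slope test on β flips between verdicts from run to run
because clone counts enter n_a as a term that does not scale with the
fraction.  Ties and degenerate inputs: histogram modal ties resolve to
the lower bin; subsample rounding is half-away-from-zero with a floor
of 2 tips; crop depths must lie in (0, max depth]; all-zero marker
vectors, constant incidence tables, and single-tip trees raise errors
rather than returning conventions.
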