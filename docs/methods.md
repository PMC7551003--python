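# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the package's tests demonstrate.

## Data model

A *study record* is one curated literature entry: the subject studied (a
white/red/black whole extract or one of twelve ginsenosides — Rg1, Re, Rf,
Rb1, Rc, Rb2, Rd, Rg2, Rh1, Rg3, Rk1, Rg5), one of eight benefit categories,
the journal impact factor (IF), the experiment type on the evidence hierarchy
in vitro < in vivo < human, and the number of bioassays/biomarkers reported.
Continuous IFs are discretized into five half-open, lower-inclusive bins.
The shipped default cut points (1, 2, 4, 8) spread typical journal IFs and
are a free parameter: the original survey's exact edges were never published.
A missing IF maps to the lowest bin — the conservative choice (lowest
reliability) that keeps the record usable — with an opt-in reject mode.
Records reporting several experiment types should arrive as one row per type
or pre-collapsed to the highest type; each record occupies exactly one
(IF bin, experiment type) cell.

Composition records summarize published mg/g ginsenoside amounts per variant
as mean, sample SD (n−1 denominator, missing when a single source
contributes) and source count.

One documented inconsistency in the published aggregates the fixtures carry:
the narrative count of red+black extract articles (168) differs from the
printed count table's red+black column sum (163); the distinct-article
counting rule behind the narrative figure is unstated. The package counts
rows as given.

## Optimal scaling

Scores s_ij ∈ [0, 1] on the I×J ordinal grid, nondecreasing in both axes,
maximize the frequency-weighted score variance
V(s) = Σ f_ij s_ij²/n − (Σ f_ij s_ij/n)².  V is convex in s, so the maximum
over the polytope {box constraints + bivariate monotonicity} is attained at
an extreme point, and the extreme points are exactly the 0/1 grids monotone
in both axes — indicators of up-sets of the grid order.  A binary monotone
grid is determined by its per-column switch row, nonincreasing across
columns, giving C(I+J, I) vertices (56 for the default 5×3 grid); the default
solver enumerates them exactly and is deterministic, breaking objective ties
(within 10⁻¹²) by the lexicographically smallest score grid in row-major
order.  Under that rule a uniform 2×2 table returns the row split
(0,0)/(1,1), and a table with all mass in one cell returns all zeros.

The literal program therefore always returns binary scores.  Published
descriptions of this scoring approach, however, exhibit *graded* tables in
which, e.g., any human study outscores any in-vivo study — behavior the
literal program does not force.  Two opt-in refinements reproduce it:

* **strict margin** δ > 0: comparable cells must differ by at least δ;
* **dominance**: s_{I,j} + δ ≤ s_{1,j+1}, so each experiment-type level
  strictly dominates every cell of the previous level.

Both are solved exactly by the affine substitution s = c·z + δ·d, where
d(i,j) counts the margins accumulated along the constraint chain below the
cell (d = (i−1)+(j−1) for the plain margin; d = j−1 for non-strict dominance;
d = (i−1)+(j−1)·I when both are active, since dominance makes the constraint
order the column-major chain) and c = 1 − δ·max(d).  The map is a bijection
between the margin polytope and a plain monotone polytope in z, and the
objective stays convex under an affine substitution, so vertex enumeration in
z remains exact.  Feasibility requires δ·max(d) < 1, checked at solve time.

`penalized_search` is the fallback for grids beyond the enumeration cap
(10⁶ vertices): seeded Nelder–Mead on raw parameters with a monotone repair
(clip to [0,1], cumulative max along both axes — or along the chain under
dominance) plus a small quadratic box penalty; every candidate is then
thresholded to binary vertices and hill-climbed by coordinate ascent over the
per-column switch rows until locally optimal, with additional seeded random
vertex starts.  It is a heuristic: it matched the exact solver on hundreds of
random grids up to 5×3 in testing, but global optimality is only guaranteed
in enumeration mode, which is the default whenever the vertex count is within
the cap.

## Non-inferiority test

For one benefit category with triplets (b_i, g_i, s_i), the model is
b_i = μ + Δ g_i + ε_i with ε_i ~ N(0, σ²/s_i) independent: the quality score
is a precision multiplier, so higher-quality studies constrain the fit more.
With a binary design the WLS solution is closed-form — μ̂ is the s-weighted
mean of the black group, μ̂+Δ̂ of the red group — and
σ̂² = Σ s_i (b_i − fitted_i)² / (n−2).  The non-inferiority hypothesis
H0: μ = γ(μ+Δ) vs H1: μ > γ(μ+Δ), with γ = 0.8 by convention, is the linear
contrast (1−γ)μ̂ − γΔ̂ = μ̂ − γ(μ̂+Δ̂), whose standard error is
√(σ̂²(1/S₀ + γ²/S₁)) with S₀, S₁ the group weight sums; the statistic is
Student-t on n−2 df and the p-value one-sided (upper tail).  Per-function
p-values are reported raw, without multiplicity adjustment, matching how such
batteries are conventionally summarized.

Numerical edge cases:

* σ̂² = 0 (perfect fit): p is the continuous limit of the t statistic — 0 for
  a positive contrast, 1 for negative, 0.5 at zero.
* A score of exactly 0 (possible under binary score tables) means infinite
  assumed variance: the record carries no information about (μ, Δ, σ²) and is
  **excluded** from the regression.  This is the exact s → 0 limit of the WLS
  fit *including its degrees of freedom*.  The alternative of flooring the
  weight at a tiny ε keeps the record in df = n−2 while it contributes
  nothing to the weighted residual sum, which biases σ̂² downward (by roughly
  the fraction of zero-score records) and demonstrably inflates the type-I
  error of the end-to-end pipeline; exclusion restores nominal calibration.
  Scores below 10⁻⁶ are treated as zero.
* A category in which one group has no (positively scored) records is flagged
  *untestable* rather than failing the battery, mirroring categories with no
  literature for one product.

`simulate_type1_power` draws weights from a configurable distribution
(default Uniform(0.25, 1)), errors from the assumed heteroscedastic normal,
and reports the rejection fraction with its binomial Monte-Carlo SE.  At the
boundary null the p-values are uniform (verified by KS distance < 0.02 over
5,000 replicates) and the type-I error sits at the nominal 5 % within
Monte-Carlo error.

## Component weights and Q

For benefit category *fun*, w_g = Σ_{i: g, fun} s_i b_i / Σ_i s_i, the
denominator running over all scored single-ginsenoside articles of that
category (an opt-in global scope uses all scored records instead; with a
single qualifying article the score cancels and w = b).  The weights are
*not* capped at 1: published comparison tables of this kind show weighted
amounts exceeding the raw mg/g means, which is only possible with
unnormalized weights, so the formula is implemented literally; an opt-in
sum-to-one normalization and the raw numerator/denominator provenance are
provided so either convention is auditable.  Q(fun, type) = Σ_g w_g M_g^type
is linear in the composition vector; compounds with positive weight but no
composition entry contribute 0 and are flagged, zero-weight compounds are
omitted.  Q is descriptive — no inference is attached to Q differences.

Scoring for the weights is per benefit category (each category's
single-ginsenoside records form their own frequency table), whereas the
extract comparison scores the pooled black/red extract corpus once —
matching how the two analyses condition on their strata.

## Synthetic corpus generator

The generator emulates the structure the method assumes, and defines the
study conditions used throughout the tests:

* per-(subject, category) stratum record counts, exact by construction;
* cell probabilities over (IF bin × experiment type): outer product of IF
  mass (0.30, 0.30, 0.20, 0.15, 0.05) and experiment mass (0.50, 0.35, 0.15)
  — low-IF in-vitro work dominates real corpora of this kind; IF values
  uniform within the bin (top bin capped at 16);
* bioassay counts Poisson with per-subject means, defaults black 8 / red 10 —
  exactly the γ = 0.8 non-inferiority boundary;
* composition sources drawn from a zero-truncated normal whose location is
  calibrated by root finding so the post-truncation mean equals the
  configured mean (naive truncation at the published means/SDs would bias
  means upward by up to ~0.3 mg/g; the SD shrinks slightly instead, which the
  summaries tolerate).  Published per-variant means/SDs seed the defaults.
* one master seed fans out to independent corpus and composition streams, so
  generating compositions never perturbs the corpus.

What the generator does **not** emulate: real bibliometric IF distributions
(per-bin uniform only), correlation between study quality and reported
bioassay counts, within-journal clustering, and the heteroscedastic
variance-by-score structure the test assumes (counts are Poisson, so their
variance tracks the mean, not 1/s_i).  Consequently the end-to-end pipeline
check at the boundary is expected to sit *near* — mildly below — the nominal
level rather than exactly at it, and the tests assert a band (0.02–0.10 at
α = 0.05) covering Monte-Carlo noise plus that mild misspecification;
exact nominal calibration is asserted only in the simulation harness, where
the data follow the assumed model.  Passing tests therefore demonstrate
correctness of the machinery and calibration under the model, not calibration
under arbitrary real-world corpora.

## Problem sizes

Default test and acceptance runs use 5×3 grids (56 vertices), corpora of
tens of records per stratum, 10,000 replicates for the type-I simulation and
600/300 replicates for the end-to-end boundary/power checks — sizes chosen so
the whole suite completes in well under a minute while keeping Monte-Carlo
SEs a few times smaller than the asserted tolerances.

## Known limitations

* The published per-study record-level dataset behind the original analyses
  is unavailable; published per-category p-values and weighted-amount cells
  are carried as fixtures for aggregation checks, not re-derived.
* The scoring optimum is generically non-unique (ties are resolved
  lexicographically), and with binary defaults half the corpus can receive
  score 0 and thus drop out of the regression; the graded (margin/dominance)
  modes avoid this at the cost of an explicit δ choice.
* The battery treats categories independently; no multiplicity control.
* Q aggregates linearly and ignores compound synergy and non-ginsenoside
  constituents.
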