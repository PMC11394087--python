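# Methods

## Data model and size classes

The sampling unit is one flushed stomach (one individual). Total length is
binned into `k` equal-width classes spanning `[lower, upper]`, width
`(upper − lower)/k`; intervals are left-closed, right-open, with the last
class closed at the upper limit. Breaks are kept at full precision — for the
reference survey, `(509 − 300)/3 = 69.67 mm`, breaks 369.67 and 439.33; the
published bounds "369.6"/"439.3" are treated as display rounding, since the
stated width formula forces the exact values. A length equal to an interior
break belongs to the upper class (so 369.67 mm is *medium*).

Aggregation to the per-class diet table counts incidence only where a prey
row has count > 0: frequency of occurrence measures the stomachs in which an
item actually appears, so an explicit zero-count row contributes volume
bookkeeping but no occurrence. Zero-count categories are retained as all-zero
table rows rather than dropped.

## Diet indices

Per class: `%N = 100·N_i/N_t`, `%V = 100·vd/vTd`, `%FO = 100·n/N`,
`RII = %FO·%V/100`, classed low [0, 10), secondary [10, 40), high [40, 100].
The boundary values 10 and 40 belong to the upper class; the reference table
itself places an RII of exactly 10 (Araneae, initial class) in the secondary
column, which fixes the convention.

The volumetric denominator `vTd` is a policy, not always a sum: in the
reference survey the printed %V columns sum to well under 100 in every class,
so the measured total volume evidently exceeded the sum of identified-item
volumes (unidentifiable material displaces water too). `summarize_diet`
therefore accepts either `vtd="sum"` (default; `vTd = Σ vd` over identified
items) or an explicit per-class total in mL. The explicit totals 10/7/14 mL
reproduce the printed %V cells to within the rounding of the printed
0.1-mL vd values (max gap ≈ 0.7 percentage points, max RII gap 0.4).

Overall (non-classed) %FO pools incidence across classes over all stomachs
(e.g. 27/31 = 87.1% for Coleoptera), not an average of per-class %FO.

All computation is at full precision; display rounding is half-up to one
decimal, matching how such tables are printed (plain `round()` banker's
rounding would flip printed cells like 16.65 → 16.6).

## Integer-count reconstruction

`infer_counts_from_percentages` recovers the smallest total `T ≤ t_max` and
non-negative integers `n_i` summing to `T` whose percentages round half-up to
a printed %N column. For each candidate `T` the admissible `n_i` form a
contiguous integer range derived in exact integer arithmetic
(`(2P−1)T ≤ 2·100·10^d·n < (2P+1)T` for a printed value `P/10^d`), so
feasibility is a range-sum check and the reported vector is the
lexicographically smallest feasible one. Inconsistent columns raise an
explicit no-solution error. On the reference survey this yields the medium
and final class counts uniquely (totals 24 and 54); the initial-class column
is provably inconsistent (printed 26.6 vs 9/34 = 26.5), and the fixture
stores the counts (9, 10, 8, 1, 2, 1, 1, 2) that honour %FO exactly and %N to
within 0.2 points, documenting the discrepancy rather than forcing agreement.

## Diversity and overlap

Simpson diversity uses the plug-in complement form `D = 1 − Σ p_i²` on raw
proportions, not the finite-sample unbiased variant: the plug-in form is what
reproduces the reference medium-class value 0.8229 exactly on reconstructed
counts. The initial/final reference values (0.7539, 0.8715) are not
recoverable from any published column and depend on unpublished stomach-level
structure; they are documented here as out of reach rather than targeted.

Class comparison is a nonparametric bootstrap: stomachs are resampled with
replacement within each class, D is recomputed on each replicate's pooled
counts, and `t = (D_a − D_b)/√(se_a² + se_b²)` with replicate standard errors
is referred to a t distribution with Welch–Satterthwaite degrees of freedom
(class stomach counts as sample sizes). Replicates whose resample is entirely
empty are dropped; a class needs at least two stomachs. Under a shared
multinomial null the test's rejection rate at α = 0.05 is calibrated within
[0.03, 0.07] (checked over 500 simulated surveys in the test suite).

Pianka overlap is the standard normalized inner product of two classes'
proportion vectors. The proportion basis defaults to numeric (%N-derived)
with volumetric and occurrence selectable, because diet studies differ and
the reference survey does not state which basis fed its overlap values (none
of the three bases reproduces them from the published table; all give
≈ 0.87–0.96). Verbal labels ("high" ≥ 0.6, "moderate" [0.4, 0.6)) are
annotation only.

## Bootstrap goodness-of-fit

The null is uniform consumption over the S *observed* categories
(`E_i = T/S`); user-supplied expected proportions are accepted since other
nulls are defensible. The default resampling unit is the individual prey item
(multinomial draw of T items per iteration); a stomach-level variant
resamples whole stomachs to respect within-stomach clustering. The p value is
`(1 + #{χ²_rep ≥ χ²_obs})/(1 + B)` — never exactly zero, bit-for-bit
reproducible given a seed. Standardized residuals `(O−E)/√E` beyond ±1.96
flag over-/under-consumption at the 0.05 level. On the reconstructed survey
the pooled statistic is χ² ≈ 87.96; the reference value 114.12 is not
reproducible from the published counts under any stated construction, so the
test is accepted by its type-I calibration property instead.

## Logistic presence–length model

Per prey item (restricted to items with RII ≥ 1.0 in at least one class,
inclusive), presence/absence per stomach is regressed on TL with a logistic
link. Fitting is IRLS with step-halving, which makes the deviance monotone
non-increasing; convergence at relative log-likelihood change < 10⁻⁸, max 100
iterations. TL is centred at its sample mean for conditioning only —
coefficients are reported on the raw scale (β₁ per mm). The item's test is
the 1-df likelihood-ratio χ² against the intercept-only model; confidence
bands are Wald intervals on the linear predictor mapped through the inverse
link, so they stay inside (0, 1). One-level outcomes and
(quasi-)complete separation — in one covariate, non-overlapping
presence/absence TL ranges — return a flagged non-estimable result; no
finite fit is forced. The reference per-item "X²" values (0.001, 0.006, …)
are inconsistent with 1-df likelihood-ratio statistics of any plausible fit
and are not targeted.

## Synthetic generator

`simulate_stomachs` emulates the survey's data-generating structure: TL
uniform on (300, 509) mm by default (the survey reports only mean 415 mm and
the range, not a distribution); per category, presence Bernoulli with
constant prevalence or a logistic function of TL; given presence, prey count
zero-truncated Poisson (the simplest law consistent with "presence + count"
data; negative binomial is an extension point); item volumes log-normal,
summed per stomach. One seed drives the whole dataset.

What the generator does *not* emulate: seasonal/site structure, prey-size
measurements, between-category dependence within a stomach, and overdispersed
counts. Passing calibration tests therefore shows the estimators recover the
generator's parameters under independence, not that real stomach data meet
those assumptions.

## The reconstructed survey fixture

Per-stomach rows were never published, so the fixture is the canonical
dataset forced by the per-class summary: 31 stomachs (10/7/14 per class) with
TLs at midpoints of equal subdivisions of each class interval (rounded to
0.1 mm); per class, each category's n incident stomachs are the *first* n of
the class in id order, each holding exactly one prey individual (in every
class the reconstructed counts equal the incidences, so one-per-stomach is
forced), with the class's vd split equally among them. Aggregating the
fixture reproduces the published class sizes, incidences, prey counts and vd
cells exactly, and pooled occurrence 87.1/74.2/74.2% for
Coleoptera/Hemiptera/Araneae. The incidence placement and volume split are
conventions, not inferences: any statistic that depends on which items share
a stomach (stomach-bootstrap variances, the per-item logistic fits on the
fixture) is convention-dependent and is treated as illustrative.

## Problem sizes and numerical choices

Calibration properties run at simulation scale chosen to give stable rates at
desk runtime: 500 uniform-null surveys (T = 100 prey, S = 11 categories,
1000 bootstrap iterations each) for the goodness-of-fit type-I check; 100
seeds at n = 500 stomachs for slope recovery (±20% on the median); grid
verification of the IRLS optimum on n ≤ 30 instances to 3 decimals via a
6-stage refined 41×41 likelihood grid. Bootstrap comparisons use 1000
replicates in the analysis drivers and 200–300 in calibration loops. CSV
floats are written at full repr precision and read back with round-trip
parsing so datasets survive IO bit-for-bit.
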