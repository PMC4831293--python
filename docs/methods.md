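# Methods

## Data model

The unit of analysis is a *report*: a study, or an age stratum that its
source publication only reported separately (the catalog contains one such
split study, giving 24 reports from 23 studies). Each report carries an
ordered list of exposure categories — parity ranges with a printed relative
risk and 95% CI — anchored by a nulliparous reference category with RR 1,
plus an optional printed "Parous" (any births vs none) row. Odds ratios and
hazard ratios are stored as relative risks without distinction: thyroid
cancer is rare enough in every included population that the three measures
are interchangeable to well below the rounding error of the printed values.
Parity ranges are closed integer intervals; "≥k" is encoded with an open
upper bound and "Parous" as [1, open).

Printed estimates are used at face precision. No attempt is made to
back-correct rounded CIs; the dominant error in everything downstream is the
one-to-two-digit rounding of the source table (a printed `0.9 (0.6–1.2)`
carries ~6% ambiguity in its implied standard error).

## Log effects and the 95% quantile

`y = ln RR`, `se = (ln UCL − ln LCL) / (2 × 1.959964)`. The full-precision
normal quantile is used rather than 1.96; the difference is far below the
rounding noise but keeps simulated (full-precision) intervals exactly
invertible.

## Collapsing categories to a parous contrast

Eight of the 24 reports print per-category RRs but no overall parous row.
Their categories share the nulliparous reference group, so their log-RRs are
positively correlated: `cov(y_i, y_j) = v0`, where `v0 = 1/a0 + 1/b0` for
case-control (odds) data and `v0 = 1/a0` for cohort-type (person-time) data,
with `a0`/`b0` the reference cases/noncases. A plain inverse-variance
collapse ignores this and overstates the precision of the combined contrast
— materially so for reports whose categories are individually precise (the
combined naive weight of a four-category report can exceed its true weight
two- to three-fold).

The default collapse (`shared_ref`) therefore reconstructs `v0` by fitting
*pseudo-counts*: cell counts that exactly reproduce every category's RR and
CI while matching the report's totals (total cases; total controls for
case-control reports). For cohort-type reports this reduces to one equation
in the reference case count; for case-control reports to two equations in
the two reference cells. The collapse is then GLS with the resulting
uniform-off-diagonal covariance. When no pseudo table fits the margins —
which happens when covariate adjustment has moved the printed estimates far
from any crude table — the collapse falls back to independence with a logged
warning. The naive collapse remains available as `method="independent"`.

**Non-uniqueness.** The margin system can have several roots (intuitively:
the data cannot always tell a small reference group with large corrections
from a large one with small corrections). All roots are gathered from a grid
of starts and the smallest reference-cell root is selected. This is (a) the
conservative choice — it implies the largest shared-variance component and
the widest collapsed interval — and (b) the demographically right one here,
since nulliparous women are the minority in every included population. On
crude tables with a minority reference group the selected root recovers the
true counts exactly (tested).

**What this cannot recover.** The collapse reproduces the heterogeneity
structure of the published analysis closely (overall I², the
prospective/unadjusted/low-quality strata essentially exactly), but a
residual gap of ~0.015–0.02 remains on the overall pooled RR and the
leave-one-out extremes. The printed CIs of some published strata imply
per-study weights larger than any combination of the printed category rows
can produce, so several of the original per-study parous inputs must have
come from the source publications directly; those numbers are not in the
summary table and are not reconstructable from it. The two acceptance tests
asserting those quantities at ±0.01 are left failing rather than loosened.

## Pooling, heterogeneity, model choice

Fixed effects: inverse-variance weights. Random effects:
DerSimonian–Laird, with Q, I² and the heterogeneity p always taken from the
fixed-effects step (the conventional presentation). `p_het` is the
chi-square upper tail with df = k−1, with no small-k correction; Q = 0 maps
to I² = 0 to avoid 0/0; k = 1 pools trivially with p_het = 1. The
random-effects model is reported only when I² > 50%, applied *per analysis*
(overall, each subgroup stratum, each leave-one-out fit) — the only
self-consistent reading of a single switching rule.

Subgroupings: design (prospective vs case-control, with nested case-control
and case-cohort counted as prospective), Newcastle–Ottawa quality (high =
score ≥ 7; unscored reports — the one pooled re-analysis — are omitted from
this grouping), region, control type (defined only for population- vs
hospital-based case-control reports), and confounder adjustment.

## Publication bias

Egger: OLS of the standardized effect `y/se` on precision `1/se` (fit via
statsmodels); the intercept estimates small-study asymmetry, tested
two-sided on t with k−2 df. Begg–Mazumdar: Kendall correlation between the
variance-standardized deviations from the fixed-effects pool and the study
variances, with the continuity correction (|score|−1) and tie-corrected
variance in the normal approximation; for k ≤ 8 the two-sided p is computed
by exhaustive rank permutation instead. Under null simulation at the
literature's scale (k = 24), Egger's empirical type-I error is nominal
within binomial error (tested at 2000 replicates).

## Dose–response

Dose assignment follows the categorical convention: reference 0; a
single-value range is itself; a bounded range takes its arithmetic
midpoint; an open-ended top range extends half the width (upper − lower) of
the adjacent bounded range below, defaulting to one live birth when that
neighbour is a single value or absent (the common "1, 2, ≥3" ladder gives
doses 1, 2, 3.5).

Per-study slopes are GLS through the origin (the reference anchors zero):
`β̂ = (xᵀC⁻¹x)⁻¹ xᵀC⁻¹y`. The covariance C is selectable:

- `independent` (default): diagonal of the printed variances. This is the
  default because it requires nothing beyond the printed rows; the
  correlated options shift the pooled trend by about 0.01–0.015 on the RR
  scale here, which is why the trend is best read as a bracket.
- `hamling`: pseudo-counts from effect sizes, CIs and report totals (as in
  the collapse above).
- `gl_counts`: Greenland–Longnecker pseudo-counts from per-category
  denominators (available in synthetic catalogs, not in the real one).

Slopes are pooled in a second stage under the same I²-switching rule.
Curvature uses a restricted cubic spline with three knots (Harrell
normalization, so the fit is linear outside the boundary knots) placed at
the 10/50/90th percentiles of the unweighted multiset of assigned doses
across studies, interpolating linearly between order statistics. The
spline-vs-linear comparison fits both models to the same category-level
data by GLS with coefficients pooled across studies (summing per-study
moment matrices — fixed-effect multivariate pooling); the likelihood-ratio
statistic is the drop in GLS deviance, referred to chi-square on 1 df, with
the Wald test on the pooled nonlinear coefficient as a cross-check. Reports
whose only contrast is a printed parous row carry no category ladder and
drop out of the trend (22 of 24 remain).

## Synthetic data

The generator mirrors the real literature's structure: 24 studies by
default, 14/24 case-control, category layouts drawn from the templates seen
in the sources, a parity distribution with 12% nulliparous and a geometric
decay beyond one birth, case counts drawn log-uniformly between 30 and 1500
(the real range is 29–2247), and a cohort baseline risk of 1e-4 cases per
person-year (thyroid-cancer incidence in women is of order 10 per 100,000
per year). Case-control studies draw case/control multinomials (cases
tilted by the true RRs); cohorts draw Poisson counts on person-time.
Between-study heterogeneity is a Normal(0, τ²) shift of all of a study's
non-reference log-RRs. CIs are Woolf intervals at full precision so the
log-effect conversion inverts them exactly, making round-trip tests exact.
Optional one-sided selection suppresses studies without a significantly
positive parous contrast with a configurable probability.

What the generator does not emulate: covariate adjustment (synthetic RRs
are crude, so pseudo-count reconstruction is exact by construction —
against real adjusted data it is an approximation), rounding of printed
values, correlated exposure misclassification, or any confounding beyond
the study-level random effect. Passing simulation tests therefore validate
the estimators under the model's assumptions, not the transcription issues
that dominate real summary data.

## Numerical conventions and edge cases

Zero cells in simulation are handled by bounded redraws, then by doubling
the target counts with a logged warning. Degenerate (zero-width) printed
intervals and non-positive RRs are rejected at parse/conversion time.
Pseudo-count feasibility requires `v0` strictly below every category
variance; fitted `v0` is capped at 0.999 × the smallest variance before
inversion. The Begg standardization guards the pooled-variance subtraction
at machine precision. JSON output rounds floats to six significant digits
so manifests diff cleanly across platforms.

## Problem sizes in tests

Simulation-based tests use 24-study catalogs (the literature's size) with
120–2000 replicates depending on the statistic: 1000 for DerSimonian–Laird
mean recovery, 2000 for Egger type-I error, 200 for the uniformity of the
nonlinearity p under a linear truth, 60 at 30–50 studies for curvature
power and slope recovery. The full suite runs in well under a minute on one
CPU; the complete CLI report on the packaged catalog takes ~2 s.
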