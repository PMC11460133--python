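# Methods

## Model overview

`schoolpa` is a population scenario model. A synthetic survey sample of
New Zealand adolescents stands in for restricted national survey microdata;
survey weights are calibrated to known population margins; five determinants
of future physical activity (PA) are estimated with design-based methods; and
intervention effect specifications are applied under eligibility rules to
produce counterfactual national estimates, a cross-intervention scorecard,
and national costs in 2019 NZD.

## Synthetic population

The generator emulates the analytic structure of a national youth PA survey:
6,906 adolescents aged 12–17, of whom 5,035 (≈72.9%) attend a secondary
school or Kura Kaupapa and form the analytic sample. Sociodemographic
composition defaults reproduce the analytic sample's published counts:
age (1.8/19.5/24.9/22.5/18.3/13.0% for ages 12–17), gender
(42.6/56.6/0.8% male/female/diverse), deprivation (37.2/32.4/14.4/16.1%
low/mid/high/unknown, with the 17 respondents missing deprivation folded
into "unknown" so the distribution sums to one), physical disability (6.1%),
and multi-select ethnicity (Māori 13.8%, European 84.5%, Pacific 4.7%,
Asian 11.4%, other 2.5%).

Design choices where the emulated survey's internals are not public:

- **Clusters.** Participants are assigned uniformly to 100 clusters (primary
  sampling units) nested in 16 districts, and each determinant carries a
  small additive cluster-level random intercept (σ between 0.05 and 0.3
  depending on the determinant's scale) so that cluster-robust variance
  estimation is non-degenerate and cluster effects are realistic but modest.
- **PE participation by age** is not published nationally; the default
  declines linearly from 0.95 at age 12 to 0.35 at age 17, reflecting the
  well-documented drop-off of PE enrolment through secondary school. It is
  fully configurable and matters only for the PE-restricted intervention's
  eligible share.
- **Multi-select ethnicity** is drawn as independent Bernoulli indicators
  per label. An empty ethnicity set is not observable in a survey, so the
  fallback label (European) is forced on for empty draws; its own Bernoulli
  rate is back-solved so that the *observed* European marginal still hits
  its target (naive forcing would inflate it by ≈11 percentage points).
- **Base weights** default to 1 (a self-weighting sample) before raking.

### Determinant distributions

Marginal shapes are chosen for correct supports: gamma for weekly PA hours
(mean 9.88, sd 8.0), Poisson truncated at a configured maximum for the
settings and types counts (means 3.15 and 4.93; maxima 10 and 20, roughly
the number of response categories such survey instruments offer), and
bound-truncated normal for the two scores (physical literacy mean 16.49,
sd 2.5 on [4, 20]; social support mean 21.19, sd 2.0 on [5, 25]). The
underlying rate/location parameter of each distribution is solved
numerically (Brent's method, tolerance 1e-12) so the *post-truncation* mean
equals the target.

Draws use **jittered systematic (stratified inverse-CDF) sampling**: a
random permutation assigns each participant one stratum `(rank + U)/n` of
the unit interval, which is mapped through the distribution's quantile
function (with the cluster intercept shifting the location or rate). This is
a standard variance-reduction device for constructing synthetic populations
that must match national calibration targets: the empirical mean of each
determinant is far more stable across seeds (sd ≈ 0.01–0.07 in the
respective units at n = 6,906) than under i.i.d. sampling, while the random
permutation leaves between-cluster variability essentially identical to
multinomial sampling — cluster means behave like draws without replacement
from the pooled sample — so linearised cluster-robust standard errors on the
synthetic data remain realistic. The residual seed-to-seed variation in the
filtered sample's means comes from the random school-attendance filter and
the cluster intercepts.

What the generator does *not* emulate: item-level survey responses and score
construction, non-response and design weights, genuine geographic/school
clustering strength, and sociodemographic gradients in the determinants
(optional additive stratum shifts exist but default to zero). Tests passing
on this synthetic population validate the *pipeline's* statistical
machinery, not substantive conclusions about real adolescents.

## Weight calibration (raking)

Weights are calibrated by iterative proportional fitting: cyclic
multiplicative updates per margin category until the maximum relative gap
between weighted category totals and the margin totals is ≤ 1e-8 (default),
up to 200 cycles. Margins are processed in the configured order (the fixed
point is order-independent for consistent margins; iteration counts are
not). Default margins are district × gender and a single-select
**prioritised ethnic group** (Māori > Pacific > Asian > Other > European),
since a partition is required for raking while the survey ethnicity is
multi-select; the priority rule follows NZ prioritised-ethnicity output
conventions. Default margin totals scale the observed filtered-sample
composition to a national roll of 278,240 (= 376 schools × 740 students).
A weight-trimming hook exists but defaults to no trimming. Inconsistent
grand totals (relative gap > 1e-6) and empty margin categories raise errors
naming the offending margin/category.

## Design-based estimation

National estimates are Hájek ratio means ȳ_w = Σw·y / Σw. Variance uses
Taylor linearisation with the ultimate-cluster estimator over the m clusters
(single implicit stratum, no finite-population correction), and confidence
intervals use Student's t with m − 1 design degrees of freedom — the
conventional choice for ultimate-cluster designs. Calibrated weights are
treated as fixed in the variance (no calibration-variance adjustment),
matching default practice when calibration is not encoded in the variance
estimator. Under equal weights and singleton clusters the estimator reduces
algebraically to s²/n with the (n−1)-divisor sample variance, which the
tests verify to 1e-12, alongside agreement with a 5,000-replicate cluster
bootstrap (within 10%) and 93–97% empirical coverage of nominal-95%
intervals over 2,000 Monte Carlo replicates at m = 100.

## Intervention scenarios

Eligibility is `attends_school AND (takes_pe if pe_only) AND age ∈ range`.
Effects per determinant are absolute (y + v) or relative (y × (1 + v)),
with optional age/gender stratum overrides replacing the base value. When
an effect sets `clamp`, results are projected onto the determinant's valid
range and counts are rounded to the nearest integer, half away from zero;
without `clamp` no flooring or rounding is applied, so aggregate effects
are exactly linear in the weighted mean. Ineligible participants' vectors
are returned bit-identical and inputs are never mutated.

The `published_deltas` preset encodes the published population-level
changes — the per-participant effect sizes behind them are unpublished —
by back-solving each aggregate delta d into a per-eligible absolute effect
d / (eligible weight share); score changes published as percentages are
first converted to mean deltas against the current baseline means. The
preset is constructed with `clamp` off precisely so this inversion is exact
(to 1e-6 in the tests); it validates the apply/estimate/percent/rank
pipeline, not micro-level effect magnitudes. The scorecard ranks
interventions per determinant on mean change for the unit-scale
determinants and percent change for the bounded scores (1 = most
improvement), with ties broken by intervention name for determinism.

## Costing

Each cost component is CPI-adjusted within its source currency to 2019 and
then PPP-converted to NZD (CPI before PPP, the standard health-economics
order). Internal arithmetic is full-precision; rounding half-up to the cent
happens only at reporting boundaries. Per-student cost divides the
per-school cost by the 2019 average secondary roll (740); national rollout
multiplies by the 376 secondary schools.

The shipped CPI/PPP tables (`src/schoolpa/data/`) are small editable
reference tables with plausible index values, calibrated so that the four
shipped cost presets reproduce their published 2019-NZD per-school values
to the cent; replace them with official OECD series when costing new
interventions. One published per-student figure is internally inconsistent
with its own per-school figure ($88,755 / 740 = $119.94, not the printed
$119.40); the package recomputes the division and surfaces the discrepancy
through `check_published_per_student` rather than matching the print.

## Numerical choices and problem sizes

- Calibration solves (truncated-Poisson rate, truncated-normal location)
  use Brent root-finding at 1e-12 tolerance.
- Raking default tolerance 1e-8 relative, 200 cycles maximum — far below
  any reporting precision.
- Percentages in demographic tables are rounded half-up to one decimal;
  costs half-up to the cent, via decimal arithmetic.
- The tests exercise the full survey size (n = 6,906; 100 seeds for the
  baseline-calibration check), 2,000 Monte Carlo replicates for CI
  coverage, and a 5,000-replicate cluster bootstrap — sizes chosen to make
  the statistical checks sharp while keeping the suite fast.

## Known limitations

- The synthetic population is a structural stand-in: distributional shapes
  and cluster strength are assumptions, and all sociodemographic effect
  modification defaults to zero.
- The `published_deltas` preset is an inversion of aggregate results, not
  evidence about individual-level effects; clamping is off there, so a
  handful of low-scoring participants can receive values slightly outside
  natural floors (e.g. marginally negative hours under a negative effect).
- Raked weights are treated as fixed in variance estimation; replicate
  weights (jackknife/BRR) and generalised calibration are out of scope.
- Cost conversion tables are calibrated reference values, not official
  series; cost-effectiveness analysis is out of scope.
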