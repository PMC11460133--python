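# schoolpa

Scenario modelling of secondary-school physical-activity (PA) interventions
on the determinants of adolescents' *future* PA participation, in the
Aotearoa New Zealand setting.

Many school PA interventions are evaluated only on their immediate effects.
`schoolpa` instead asks how school-based interventions move the
adolescent-stage factors that predict being active later in life — five
*determinants of future PA*:

| determinant | scale |
|---|---|
| current weekly PA duration | hours/week |
| number of PA settings | count/week |
| number of PA types | count/week |
| physical literacy score | bounded score, minimum 4 (default range 4–20) |
| social support for PA score | bounded score, minimum 5 (default range 5–25) |

Four modelled interventions are shipped as presets: **TAPE**
(technologically augmented physical education; reaches PE students only),
**PL** (peer-led mentoring; reaches 13–14-year-olds only), **PAL**
(physically active learning; all students) and **NE** (a natural-environment
play area; all students).

## What the package does

1. **Synthetic population** — generates a survey-like sample of 6,906
   adolescents aged 12–17 (5,035 of whom attend a secondary school or Kura
   Kaupapa and enter the analysis), with age/gender/multi-select
   ethnicity/disability/deprivation composition, a cluster design nested in
   districts, PE participation by year group, and determinant distributions
   calibrated to the published national baselines.
2. **Raking** — calibrates weights to known population margins (district ×
   gender, prioritised ethnic group) by iterative proportional fitting (IPF).
3. **Estimation** — design-based national estimates: Hájek weighted means,
   Taylor-linearised cluster-robust standard errors (ultimate-cluster
   estimator), and t-based confidence intervals with `clusters − 1` degrees
   of freedom,

   se²(ȳ_w) = m/(m−1) · Σ_c (Z_c − Z̄)²,  Z_c = Σ_{i∈c} w_i (y_i − ȳ_w) / Σ w.

4. **Interventions** — applies per-determinant effects (absolute or
   relative, with optional age/gender overrides and range clamping) under
   each intervention's eligibility rule, and compares post vs baseline
   estimates, deltas, and percent changes; ranks interventions per
   determinant into a scorecard.
5. **Costing** — converts exemplar intervention costs to 2019 NZD (CPI
   adjustment within the source currency, then purchasing-power-parity
   conversion), and scales to per-student (÷ 740, the average secondary
   school roll) and national rollout (× 376 secondary schools) costs.

## Worked example

```python
from schoolpa import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1), out_dir="out")
print(result.baseline[["determinant", "mean", "ci_low", "ci_high"]])
print(result.scorecard)
print(result.costs)
```

prints (seed 1):

```text
         determinant       mean     ci_low    ci_high
0      pa_hours_week   9.774180   9.534809  10.013552
1         n_settings   3.131407   3.077015   3.185799
2            n_types   4.910746   4.846157   4.975335
3  physical_literacy  16.461943  16.400612  16.523275
4     social_support  21.208273  21.158145  21.258400

                   TAPE   PL  PAL   NE
pa_hours_week       2.0  4.0  3.0  1.0
n_settings          2.0  4.0  3.0  1.0
n_types             3.0  2.0  4.0  1.0
physical_literacy   3.0  1.0  2.0  4.0
social_support      3.0  2.0  1.0  4.0

  intervention  per_school_nzd  per_student_nzd  national_nzd
0         TAPE         7588.54            10.25    2853291.04
1           PL         5315.64             7.18    1998680.64
2          PAL         2208.53             2.98     830407.28
3           NE        88755.00           119.94   33371880.00
```

The baseline table gives the weighted national determinant estimates with
95% cluster-robust CIs. The scorecard ranks interventions per determinant
(1 = most improvement): the natural-environment intervention leads on the
three behavioural determinants while peer-led and physically-active-learning
lead on the two psychosocial scores. The cost table shows each
intervention's per-school cost in 2019 NZD and its per-student and
nationwide-rollout implications (note the per-student figure is always the
per-school cost over a 740-student roll, rounded half-up to the cent).

The same pipeline is available from the shell:

```sh
schoolpa run --config configs/default.yaml --seed 1 --out out/
```

which writes the population, margins, baseline and scenario tables, the
scorecard, the cost table, an estimates figure and a run manifest; repeated
runs with the same config and seed are byte-identical. Individual stages
are exposed as `schoolpa simulate | rake | estimate | scenario | cost |
report`.

## Intervention effect presets

The per-participant effect sizes behind the four interventions are not
published; the `published_deltas` preset therefore back-solves the published
*population-level* changes (e.g. NE +0.2 h/week; PAL social support +5%)
into per-eligible absolute effects by dividing each aggregate delta by the
intervention's eligible weight share. Applying the preset reproduces the
published aggregate changes by construction, which validates the
apply/estimate/rank pipeline end-to-end. Use the `illustrative` preset or
your own `InterventionSpec` objects for genuine what-if analysis.

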