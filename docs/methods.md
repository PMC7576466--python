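# Methods

This note documents the models, assumptions and numerical choices behind
`markovcea`, in the order the pipeline runs them.

## 1. Synthetic cohort generator

The generator emulates a two-arm observational study of frail, multimorbid
older adults in domiciliary care, followed for 8 months. The packaged
defaults describe an intervention arm of 98 and a comparator arm of 100
patients with:

- **Demographics.** Age is Gaussian (intervention mean 85.5 y, comparator
  82.8 y; SDs ≈ IQR/1.349, i.e. 5.4 and 6.2 y), clipped to [60, 105];
  female fractions 0.74 and 0.57.
- **Comorbidities.** Sixteen chronic-condition flags drawn as independent
  Bernoulli variables at arm-specific prevalences (congestive heart failure
  the most prevalent, 62–71%). A Charlson score is computable from the
  flags; the standard 1987 weights ship as defaults and are fully
  configurable.
- **Scores.** Barthel (0–100, steps of 5), IADL (0–8) and GDS (0–15).
  Baseline and follow-up change are Gaussian; the final score is
  `clip(grid_round(baseline + change))`. Only means and confidence
  intervals are reported for score changes in this population, so change
  SDs are back-solved as `CI half-width / 1.96 × √n` (e.g. comparator
  Barthel change −3.23, SD 10.79). Gaussian-plus-clipping is the minimal
  assumption and is isolated in the configuration.
- **Contacts.** Per-patient counts are Poisson with the configured annual
  rate (51.0 / 53.1 contacts per patient-year) scaled by
  `followup_months/12`. Professional type, setting and planned/unplanned
  status are sampled from the three marginal distributions independently —
  only margins are available, not the joint — and the implied product
  distribution is exposed as `ContactMix.joint()`.
- **Admissions.** A Bernoulli "ever hospitalized" indicator (0.327 / 0.45)
  with a `1 + Poisson` conditional count matched to the unconditional mean
  admissions per patient; per-admission length of stay is lognormal,
  moment-matched to the configured mean/SD (the reported SDs exceed the
  means, ruling out a Gaussian; a lognormal keeps stays positive and
  right-skewed).

A single seed drives the cohort, split per patient by counter
(`SeedSequence((seed, index))`), so cohorts are bit-reproducible and adding
patients never perturbs earlier ones.

**What the generator does not emulate.** Dropout and missing follow-up
(none by default), intra-patient correlation between instruments, seasonal
or time-varying contact intensity, and clustering by primary-care centre.
Passing distributional-recovery tests therefore shows the pipeline is
statistically sound under these idealized conditions, not that it captures
every feature of real cohorts. One intrinsic feature worth noting: with the
default comparator Barthel baseline (mean 71.6, SD 28.0) about a sixth of
patients sit at the instrument ceiling, so the *realized* mean change is
more negative (≈ −3.7) than the nominal −3.23 — ceiling truncation of a
bounded instrument, not a bug. Recovery tests for the change distribution
therefore use a mid-scale baseline where truncation is negligible.

## 2. Effectiveness statistics and Markov inputs

- `mean_change_ci` is the paired-differences t procedure. Zero-variance
  differences degenerate to a point CI with p = 1 (zero mean) or 0.
- `compare_groups_categorical` is the chi-square test without continuity
  correction by default (a correction flag exists); expected counts are
  returned for diagnostics. On the packaged gender 2×2 table the p-value
  rounds to .02 with or without correction.
- `compare_groups_continuous` offers t, Mann-Whitney (exact when feasible,
  midranks under ties), and an `auto` mode gated on one-sample
  Kolmogorov–Smirnov normality of both samples at α = .05, mirroring
  SPSS-style practice.
- **Worsening rule.** A patient *worsened* iff
  `final − baseline < −threshold`, strict inequality, default threshold 0
  (any Barthel decline). The published analysis does not state its
  instrument/threshold; both are configuration, and the boundary rule is
  pinned by tests.
- `estimate_transition_probs` uses the worsened fraction as the per-cycle
  incidence and its complement as recovery (the reference input block's
  rows sum to 100%); the engine also accepts independent values. The
  observed 8-month worsening fraction is used directly as the annual
  per-cycle probability — matching how the reference inputs were built —
  and a rate-based annualization `1 − (1 − p)^{12/m}` is available but off
  by default.
- **Utilities.** Barthel maps to utility through a pluggable `UtilityMap`:
  affine `u = a + b·score` clipped to [0, 1] (default `u = score/100`), or
  `direct` per-state utilities, the route used by the reference input
  block (0.56/0.30 intervention, 0.45/0.33 comparator). The original
  published regression mapping from Barthel to utility is not reproduced
  (its coefficients are not public); the affine default is a transparent
  stand-in.

## 3. Costing

Unit costs are 2016 euros: physician €29.23/h, nurse €20.79/h, social
worker €18.19/h, citizen (patient/caregiver) time €6.07/h, bed-day €733.56.
Specialists are costed at the physician wage and "other health care
provider" at the nurse wage (no separate wages exist); volunteer care is
unmonetized. Contact durations are not recorded in the source resource-use
tables, so per-setting defaults ship as documented assumptions (home visit
0.75 h, out-of-home 0.33 h, telephone 0.17 h, writing 0.08 h, other
0.25 h). All observed amounts are homogenized to per patient-year by
`× 12/followup_months`.

The societal perspective adds citizen-time terms whose magnitudes the
source states as rules but not numbers. Defaults are back-solved from the
published per-year cost block: intervention platform-usage time
47.5 h/patient-year (= (5953.15 − 5664.89)/6.07) and comparator travel
0.5 h citizen time (plus €0 out-of-pocket) per out-of-home contact. Both
are configuration, not estimates.

When no patient-level data exist, the pipeline's `passthrough` mode feeds
the published per-state cost block directly into the engine; this is the
headline path. The deteriorated-stage cost being *lower* than the
baseline-stage cost in the intervention arm is passed through as printed,
not rationalized.

## 4. Markov engine

Three states (baseline stage, deteriorated stage, dead), annual cycles,
40-year horizon, 3% discounting of both effects and costs.

Numerical conventions, each of which changes results and is therefore
pinned by tests:

- **Transition ordering.** Death competes first (probability
  `1 − (1 − qx)^rr`, hazard-scale relative risk, valid for any rr > 0; at
  rr = 1.005 it differs from multiplicative scaling by < 1e−4), then
  incidence/recovery among survivors.
- **Reward timing.** End-of-cycle occupancy × (utility, annual state cost),
  discounted by `(1+r)^{−t}`, t = 1..T. A half-cycle correction (averaging
  start- and end-of-cycle occupancy) is available but off by default; the
  flag lets users bracket this ambiguity.
- **Programme costs.** One-off cost charged undiscounted at t = 0;
  recurring cost charged to the alive fraction each cycle and discounted
  like other costs.
- **Entry profile.** 100% baseline stage, age 84, 65% female (the pooled
  cohort profile); sexes are modelled separately and mixed. All three are
  configuration.
- **Life table.** Ages clamp to the table's range; the terminal row is
  forced to qx = 1 on load. The packaged synthetic Gompertz–Makeham table
  (`μ(x) = a + b·e^{0.12x}`; women a = 5e−4, b = 2.3e−6; men a = 2e−3,
  b = 3.56e−6; ages 50–110) approximates Spanish period mortality circa
  2016 at the ages that matter here (women qx(65) ≈ 0.006, qx(84) ≈ 0.056;
  men ≈ 0.011/0.087).

The engine is verified against an independently written bookkeeping loop
(1e−10 on randomized parameter sets) and against the geometric closed form
`Σ (s·v)^t = s·v(1 − (s·v)^T)/(1 − s·v)` for discounted life-years under
constant hazard.

**Known limitation — reproducing the published headline.** With the entry
profile above and Spanish-level mortality, discounted life expectancy at
entry is ≈ 6 years. Both arms reach their stationary stage mix after one
cycle and share identical mortality (all relative risks 1.005), so
ΔE = Δū · DLY ≈ 0.065 × 6.1 ≈ 0.39 QALYs and ΔC ≈ €3.1k (health-care
perspective), against published values of 0.731 and €4755. Those published
values imply ≈ 11 discounted life-years, i.e. an entry age near 74–75 or a
much lighter mortality schedule inside the original web-based modelling
tool, whose entry profile, cycle conventions and life-table vintage are not
published. The package reports what the stated inputs produce; users can
move `start_age` (e.g. `EconConfig(start_age=75)`) to explore the
discrepancy, and the ratio ΔC/ΔE is far less sensitive to it than either
delta.

## 5. Incremental analysis and sensitivity

Dominance follows the CE-plane quadrants; ΔE = 0 leaves the ICER undefined
while NMB remains defined. One-way sweeps multiply the target parameter by
(1 + δ) over a symmetric grid — "0% to 5% change" is read as ±5%, the
stricter interpretation, and the reported quantity is the maximum finite
ICER over the whole grid. Default grids use 11 points (1% steps); the
acceptance script uses 21 (0.5% steps). Parameter paths address single
fields (`intervention.utility_baseline`) or groups (`both.state_costs` =
the per-state costs of both arms). Perturbed utilities and probabilities
are clipped to [0, 1].

The probabilistic sensitivity analysis is an extension beyond the
deterministic sweeps of the source evaluation: beta distributions for
probabilities and utilities, gamma for costs, moment-matched at a
configurable coefficient of variation (default 0.1), with out-of-range
draws resampled (capped and counted). It is off by default and not claimed
to replicate any published scatter.

## 6. Reporting conventions

Human-readable reports round euros to 2 decimals and QALYs to 3; all
machine-readable outputs (CSV/JSON) keep full precision. The monetary unit
is 2016 euros throughout; dollar figures that appear in source material are
presentation-only and never computed. Run directories contain every stage's
delimited outputs plus a `run_log.yaml` echoing the full effective
configuration, sufficient to re-create the run.

Problem sizes used by the test suite — cohorts of up to 10,000 patients for
statistical-recovery checks, 100 randomized parameter sets for engine
equivalence, a few hundred PSA draws for Monte-Carlo self-consistency —
were chosen so the whole suite runs in well under a minute while keeping
every 3-standard-error recovery band narrow enough to be informative.
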