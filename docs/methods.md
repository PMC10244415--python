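# Methods

## Scope and data model

The package analyses irregularly sampled hormone series from a cohort of
female domestic cats observed for months around a contraceptive treatment.
Time is an integer day offset from treatment (day 0); calendar dates are
converted at the I/O boundary. All windows — analysis periods, exclusion
intervals, simulator ground-truth windows — are half-open `[start, end)`.
"Months" are 30-day blocks: the default periods are pre-treatment
`[-180, 0)`, transition `[0, 60)` and post-treatment `[60, 720)`, and the two
default mating-trial windows are `[240, 360)` and `[600, 720)` (months 8–12
and 20–24 post-treatment). Concentrations are carried in their native units
(ng/g dry feces for fecal metabolites, µg/ml or ng/ml for serum analytes) and
never converted.

Periods of pregnancy and lactation are represented as explicit per-animal
exclusion intervals rather than inferred, because their interaction with
analysis windows is a study-design fact, not something the hormone data can
decide. Samples inside exclusions are removed before phase calling, and
window lengths are reduced by their overlap with exclusions when frequencies
are normalized.

## Iterative baseline

`fit_baseline` estimates the non-elevated level of a series on the baseline
window (default: the pre-treatment period) by iterated exclusion: compute the
mean and sample SD (n−1 denominator) of retained points, permanently exclude
every retained point strictly greater than `mean + k·SD` (default k = 1.5),
and stop when an iteration excludes nothing. Ties at the threshold are
baseline; excluded points are never re-tested. A `fold_of_mean` mode
(`threshold = k·mean`) is provided because luteal elevation is sometimes
defined as a fold change over the baseline mean; the package default for both
analytes is `sd_above_mean`. The fit requires at least three samples; the
converged threshold is applied to the entire series.

Two structural properties of this estimator are worth knowing.

* **Convergence is guaranteed** (each non-final iteration excludes at least
  one point, so `n_iterations ≤ n_input`), and the procedure is
  order-invariant and idempotent on its own retained set.
* **With k = 1.5 the exclusion cascades on unimodal noise.** For any locally
  uniform slice of data, `(max − mean)/SD = √3 ≈ 1.73 > 1.5`, so on iid
  continuous unimodal noise the rule keeps trimming and stops only when too
  few points remain above the shrinking threshold. Measured on pure lognormal
  noise (σ = 0.10–0.25, n = 77), 27–36 % of the original samples end up above
  the converged threshold, and the stopping depth is heavy-tailed across
  samples. The method therefore relies on the baseline window being dominated
  by a tight baseline mass with well-separated elevations; the ≥ 6-sample
  luteal run requirement suppresses the resulting false positives almost
  completely (rate ∝ p⁶), while the ≥ 2-sample estrous rule does not — at the
  default noise level the estrous caller's sample-level specificity is ~0.72
  and its event-level precision ~0.7. Users who need a conservative estrous
  caller should raise k or `estrous_min_run`; the defaults reproduce the
  published definitions.

## Phase calling and frequencies

`call_phases` removes excluded samples, segments the remainder at exclusion
boundaries, and reports every maximal run of consecutive samples strictly
above the threshold with length ≥ `min_run` (2 for estrous/E2, 6 for
luteal/P4). Consecutiveness is in collection order, not calendar days, since
sampling is thrice weekly; runs never span an exclusion, and runs separated
by a single below-threshold sample are not merged. Each call records its
first and last sample day, sample count and peak value.

`phase_frequency` counts calls whose *start day* lies in the analysis window
(a phase truncated by the window end still counts if it starts inside) and
normalizes by the window's effective days:
`normalized = n_phases / effective_days × norm_days`, with `norm_days` 30 for
estrous and 180 for luteal phases. A window fully covered by exclusions is a
degenerate-window error.

`amh_threshold_compliance` reports the fraction of post-treatment serum AMH
samples at or above a target level (default 0.25 µg/ml) and whether every
sample met it.

## Group statistics

* **Log-scale t tests.** Hormone concentrations are compared between periods
  with a pooled-variance two-sample t test on natural-log values (log base
  does not affect t or p). A pooled within-group variance of exactly zero is
  a degenerate-variance error rather than a silent division by zero. Welch's
  correction is deliberately not the default, matching the classical pooled
  formulation.
* **RCB ANOVA.** Phase frequencies are analysed as a randomized complete
  block design: animals are blocks nested in dose groups and crossed with
  period, one observation per animal × period. The balanced sequential
  decomposition `SS_total = SS_group + SS_block(group) + SS_period +
  SS_period:group + SS_residual` is computed from factor-level means. This is
  a split-plot layout: the group F uses the block (between-animal) mean
  square as its denominator — animals, not samples, are the experimental
  units for group — while period and the interaction use the residual. Under
  a null with animal-level random effects this makes the group test exact
  (simulated type-I error ≈ 0.05 at α = 0.05 over 2,000 replicates). With all
  values identical, F is undefined and p is reported as 1 with a note so that
  degenerate simulated cohorts do not abort pipelines. Tukey-adjusted
  pairwise p-values compare the six period × group cell means using the
  studentized range with the residual mean square.
* **Dunnett contrasts.** Follicle-count style comparisons use one-way ANOVA
  with Dunnett's many-to-one adjustment (equicorrelated multivariate-t,
  correlation 1/2 for balanced designs) against the control group, via
  `scipy.stats.dunnett`; a 10⁶-resample Monte-Carlo oracle in the test suite
  confirms the adjusted p-values to < 0.005. The stereological correction for
  counting every fifth serial section is a plain multiplication by the
  correction factor (default 5).
* **Uniform-null chi-square.** Mating-trial count rows are tested against a
  uniform expectation across g groups: `E = total/g`, `χ² = Σ(O−E)²/E`,
  `df = g−1`, upper-tail p, no continuity correction. For g = 3 this gives
  the closed form `p = exp(−χ²/2)` (so (3,0,0) → p ≈ 0.0498 and (10,0,0) →
  p ≈ 4.5 × 10⁻⁵). With counts this small the multinomial null is discrete:
  the continuous p lies between the strict and non-strict exact exceedances,
  which is how the Monte-Carlo calibration test asserts it. A zero total is
  an undefined-test error, surfaced per row in trial tables rather than
  aborting the trial.

## Mating-trial analysis

A breeding bout is a maximal run of consecutive calendar days each containing
at least one confirmed intromission ("breeding" events; "attempt" events are
ignored). A bout is followed by a luteal phase iff some luteal call starts in
`(bout_end, bout_end + max_lag_days]` (default lag 21 days, configurable and
recorded in output); each luteal call credits at most its nearest preceding
bout, so one ovulation cannot be attributed to two bouts. When the pipeline
builds trial tables it lifts the *pregnancy* exclusion for this linkage step:
the fertile luteal rise is precisely what the trial table counts as a
post-bout luteal phase, and excluding gestation samples would structurally
zero that row for every conceiving female. Frequency and period analyses keep
the full exclusions. Kitten counts come from an explicit births table
(female, conception day, litter size) because litter sizes are not derivable
from hormones or event logs.

## The simulator

`synthetic_data` emulates the study conditions the analysis assumes: nine
females (three per dose group) followed for 900 days (180 pre-treatment),
fecal sampling on three fixed weekdays, and two 4-month mating trials. Each
animal runs an independent renewal state machine — interestrous gap (uniform
14–21 d) → estrus (5–7 d) → either ovulation (induced by a mating bout with
per-group probability, or spontaneous with per-estrus probability) opening a
luteal window (30–45 d if non-pregnant; gestation-length 65 d plus 56 d
lactation if conception occurred), or straight to the next cycle. Mating occurs only
during estrus windows inside trial windows, at most one bout (1–4 consecutive
days) per estrus. Dose-group effects (suppressed induced/spontaneous
ovulation, reduced mating receptivity, damped luteal P4 amplitude) act from
day 0; before treatment every animal behaves as a control.

Hormone levels are piecewise-constant fold elevations over a constant
baseline with iid multiplicative lognormal noise (default σ = 0.25 for both
analytes): E2 elevated during estrus, P4 during luteal windows (including the
window spanning a gestation, which lies inside the pregnancy exclusion).
Fold amplitudes are drawn per window (E2 uniform 2.5–4, P4 uniform 4–9):
between-cycle amplitude variation is realistic and removes a degeneracy of
the iterative baseline in the zero-noise limit, where exactly equal elevated
values occupying > ~31 % of the baseline window would make the first
exclusion impossible. The per-estrus spontaneous-ovulation default (0.05 in
controls) is deliberately at the low end of the published range for
group-housed cats, keeping the 6-month baseline window baseline-dominated —
the operating assumption of the k = 1.5 method itself; it is a placeholder
the user should calibrate to their colony. Per-animal RNG substreams are
keyed on (master seed, group index, animal-within-group index), so enlarging
the cohort never reshuffles existing animals.

What the simulator does **not** emulate: seasonality/photoperiod, male
endocrinology, assay drift or autocorrelated noise, within-phase hormone
kinetics (rise/fall shapes), partial or failed luteal phases, and AMH
pharmacokinetics (serum AMH, if needed, is a simple declining exponential for
threshold-compliance tests only). Passing detector validation on simulated
cohorts therefore demonstrates correctness of the threshold/run-length logic
under the stated noise model, not field performance on real fecal assays.

## Detector validation

Validation compares phase calls with simulator ground truth two ways: at the
event level, calls are matched to truth windows by interval overlap (a call
may begin one scheduled sample early through a chance elevation adjacent to a
true window — a boundary artifact, not a false detection), with sensitivity
measured against *detectable* truth windows (those containing ≥ `min_run`
scheduled, non-excluded samples; windows truncated by study end or buried in
exclusions are invisible to any sample-based detector) and precision against
all truth windows. At the sample level, standard sensitivity/specificity are
computed over non-excluded scheduled samples. In the zero-noise limit the
caller recovers every detectable window exactly (event sensitivity =
precision = 1 for both phases, verified across master seeds 0–7); at the
default noise level over 51 simulated animals the luteal caller's
sample-level sensitivity is ≥ 0.99 and specificity ≥ 0.94, while the estrous
caller's specificity is limited by the k = 1.5 cascade discussed above.

## Problem sizes and numerical choices

The test suite and acceptance script use: exhaustive oracle comparison of the
baseline iterator over all ~1,800 value-multisets of length ≤ 12 from a
4-value alphabet; 9-animal cohorts for zero-noise validation and pipeline
determinism; 51-animal cohorts for noisy detector validation; 2,000 null
replicates for ANOVA type-I calibration; 10⁵ multinomial replicates for
chi-square calibration; and 10⁶ resamples for the Dunnett oracle. Dunnett
p-values use scipy's multivariate-t integration (tolerance well below the
0.005 assertion level). CSV outputs are written with `%.10g` float formatting
so that repeated runs with identical inputs and seeds are byte-identical.
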