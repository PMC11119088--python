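# Methods

This note documents the task model, the adaptive controller, the synthetic
respondent model and its calibration, the statistical conventions, and the
numerical choices behind `flankit`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Task structure and scheduling

A session is 8 practice trials followed by 42 test trials. Practice is
half congruent, half incongruent (an odd practice count would give the
extra trial to the congruent class); the test block realizes the 2:1
congruent:incongruent ratio by largest-remainder rounding, which at the
defaults gives exactly 28 congruent and 14 incongruent trials (67% to the
nearest whole percent). Within each congruency class, left/right targets
are split 50:50, with the extra trial going LEFT when the count is odd —
a deterministic tie-break so schedules differ only in order across seeds.

Trial order is constrained so that no more than 3 consecutive trials share
a congruency and no more than 3 share a target direction, preventing
degenerate streaks that would confound the staircase's consecutive-correct
rule with stimulus runs. Because valid orders are a vanishing fraction of
all shuffles at a 28:14 split, rejection sampling of the full shuffle is
impractical; the congruency order is instead drawn **uniformly over
constraint-satisfying sequences** by completion-counting dynamic
programming (at each position, the next congruency is chosen with
probability proportional to the number of valid completions). Direction
assignment within that order is a per-class shuffle accepted when the
global direction-run constraint holds; acceptance is high at a near-even
direction mix, so plain rejection suffices there. Schedules are
bit-for-bit reproducible from (config, seed).

Practice "clearing" is not further specified by the task description, so
the engine uses a configurable pass criterion: at least 6 of 8 correct,
with at most 2 re-presentations of the same practice block. Repeated
practice trials carry a repeat counter and are never scored. Practice
trials use the fixed 1700 ms window in both conditions; the staircase
operates only on the test block.

## The staircase controller

The gamified condition's adaptive difficulty is a one-way descending
staircase on the response window:

* start: 8000 ms (the window on the first test trial),
* step: −500 ms after every run of 3 consecutive correct responses,
* stagnation: any commission or omission resets the streak and leaves the
  window unchanged,
* floor: 500 ms (decrements clamp here; windows below half a second are
  not physically answerable by preschoolers).

The start value matters: gamified mean RTs can exceed the traditional
1700 ms cap, so the staircase must begin well above it; 8000 ms allows all
14 possible decrements (a perfect run ends at 1000 ms) while keeping
early trials effectively unlimited for 3-year-olds. It is configurable
and recorded in every event log.

Two readings of the "3 consecutive correct per level" rule are possible:
a rolling streak that persists across the 3-trial hidden-level boundaries,
or a block rule where only a fully correct level earns a decrement. The
rolling-streak reading is the default (the rule is stated in terms of
consecutive correct responses, not blocks); the block variant is exposed
as `StaircaseConfig(level_reset=True)` without any claim about which an
existing implementation used. The two coincide on streaks aligned with
level boundaries.

Classification is by the deadline rule: a press after the window closes
is an **omission**, not a commission — the deadline defines the omission,
and late presses are recorded as non-responses (no RT is stored). The
reward jar starts empty, gains one treasure per correct trial, loses one
per error, and clamps at zero; the exact magnitudes are a definition of
this implementation, fixed once.

## Synthetic respondent model

There is no standard generative model for preschool flanker behavior;
this package defines one and labels it clearly as a test fixture, not a
validated psychological model. A child's response to a trial with window
*w*:

1. with probability `lapse`, no response;
2. otherwise `RT = t0 + exp(mu + delta·[incongruent] + sigma·z)`,
   `z ~ N(0,1)`; if `RT > w`, omission;
3. an in-time response is a commission with probability `err_cong` or
   `err_incong` for the trial's congruency, correct otherwise.

The shifted lognormal was chosen for closed-form moments (the mean
congruency RT gap is `exp(mu)·(e^delta − 1)·e^(sigma²/2)`, used as a test
oracle) and trivial truncation at the deadline. With no deadline the MLE
is closed-form, which `fit_respondent` exploits for the parameter-recovery
property test.

### The `preschool2024` calibration

Age rows (units: t0 ms; mu, sigma, delta on the log scale; probabilities):

| age | t0  | mu        | sigma | delta | err_cong | err_incong | lapse |
|-----|-----|-----------|-------|-------|----------|------------|-------|
| 3   | 300 | log 1400  | 0.55  | 0.18  | 0.05     | 0.18       | 0.04  |
| 4   | 250 | log 800   | 0.40  | 0.20  | 0.15     | 0.32       | 0.02  |
| 5   | 250 | log 650   | 0.35  | 0.22  | 0.10     | 0.28       | 0.01  |

A latent ability factor `z_a ~ N(0,1)` per child shifts `mu` by −0.35·z_a
and both commission logits by −1.0·z_a. Two synthetic achievement
covariates (scaled-score metric, population mean 10) load on age and
ability: `verbal = 10 + 1.2(age−4) + 2.2 z_a + N(0,1)` and
`matrix = 10 + 1.2(age−4) + 2.3 z_a + N(0,0.9)`.

These constants were tuned **once**, then committed, against four
qualitative/quantitative targets typical of 3–5-year-old flanker cohorts:
(a) pooled congruent accuracy near 68% under the fixed 1700 ms deadline in
a 6/6/8-by-age cohort; (b) roughly 23 omissions out of 42 trials for
3-year-olds at the fixed deadline versus low single digits under the
staircase; (c) a positive conflict effect in accuracy and RT at every age
(`delta > 0`, `err_incong > err_cong`); (d) performance–covariate and
cross-condition correlations in the 0.6–0.85 band at large n. The age
subgroup split (6/6/8 at n = 20, i.e. a 30/30/40% mix) is a default, not
an assertion; ages are assigned by sequential quota apportionment so a
growing cohort never re-ages existing children.

Enjoyment is a discretized latent Gaussian (`N(3.0, 2.0)`, rounded and
clipped to 1–5) with a per-child positive shift (mean +2.3, SD 0.5) in the
gamified condition; preference is multinomial with default probabilities
0.80 / 0.15 / 0.05 for gamified / traditional / no answer.

What the generator deliberately does **not** emulate: within-session
learning or fatigue (parameters are stationary), post-error slowing,
sequential trial dependencies, response bias toward one side, and any
order effect of playing one condition first. Passing calibration tests
therefore shows the pipeline recovers the structure this generator puts
in — not that a real cohort would show it.

### Randomness

All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawning: one substream per child profile, and
separate per-child substreams for schedule, play, rating, and preference.
Adding a child never perturbs earlier children's draws.

## Scoring conventions

* Accuracy = correct / all test trials × 100; omissions and commissions
  both count against it. Percentages are carried 0–100.
* RT means use correct trials only by default; commission RTs measure a
  different process and omissions have none. A
  `rt_include_commissions=True` flag exists for sensitivity analysis.
  Whether published RT summaries excluded commissions is usually
  unstated; this default is declared, not asserted of any other study.
* A congruency class with zero correct trials yields an absent RT mean
  (None), never a silent zero; the RT conflict score is then absent too.
* Omission summaries report mean and SD (n−1 denominator) per age ×
  condition; an n=1 cell has no SD, an empty cell is absent.

## Statistical conventions

Two-sided tests, α = 0.05 throughout; no multiple-testing correction (the
report states how many tests it ran). Paired t-test from the differences:
`SE = SD/√n`, `df = n−1`, CI from the exact t distribution
(`t_crit(19) = 2.093`). Paired Cohen's d is `M/SD = t/√n`; the pooled-SD
variant is out of scope. Pearson CIs use the Fisher z transform with
`SE = 1/√(n−3)`; p-values from `t = r√((n−2)/(1−r²))`. The mixed ANOVA is
the classical split-plot sums-of-squares decomposition with
`partial η² = SS_effect / (SS_effect + SS_error_of_that_effect)`; the
chi-square is the Pearson statistic without continuity correction.

Numerical choices: full precision end-to-end, with half-up rounding to 2
decimals only at report render time; correlations within 1e−12 of ±1 are
snapped to ±1 (exact collinearity); an ANOVA effect with zero error SS
and zero effect SS reports F = 0 (null data), not 0/0. Degenerate inputs
raise errors rather than silently correcting: negative RTs, mismatched
paired lengths, missing pairs, zero-variance correlation inputs,
zero-margin contingency tables, subjects missing a within-level.

## Problem sizes used in validation

The staircase sequence-equivalence oracle runs on 10⁴ random outcome
sequences; brute-force statistical oracles run on small (≤12-row) random
instances at 1e−10 relative tolerance; Fisher-z coverage uses 500
bivariate-normal replicates at ρ = 0.5, n = 1000; calibration checks use
200 simulated children per age cell, a 1000-child traditional cohort, and
100 seeded 20-child two-condition studies. These sizes make the full
suite run in well under a minute while keeping Monte-Carlo error far
below the asserted tolerances.

## Known limitations

* The respondent model is a fixture: its parameters are plausible, not
  fitted to any child's data, and cohort-level printed summaries from
  real studies are not reproduction targets for the simulator.
* The staircase ambiguity (rolling vs block streaks) is resolved by
  configuration, not by evidence.
* The mixed ANOVA supports one between and one within factor only, the
  design it exists for.
* Event logs are JSONL only; no binary or database backends.
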