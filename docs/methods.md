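# Methods

## Model

The decision variable is a single Wiener process between absorbing
boundaries at 0 and `a`, starting at the midpoint `a/2` (the model has
no bias parameter and drops start-point variability, so the symmetric
start is the only neutral choice).  Its drift is the attention-weighted
sum of two channel outputs,

    v(t) = w_a(t)·(s·d_a) + w_c(t)·d_c,
    w_a(t) = A0·exp(−k t),  w_c(t) = 1 − w_a(t),

with `s = +1` (congruent) or `−1` (incongruent) applied to the
automatic base drift, and `k ∈ {k_c, k_i}` selected by condition.  The
drift relaxes monotonically from `A0·s·d_a + (1−A0)·d_c` toward `d_c`;
the automatic contribution `w_a(t)·s·d_a` never changes sign, which is
the substantive difference from the pulse-function reference model,
whose automatic drift (the derivative of a rescaled gamma pulse) is
positive before the pulse peak at `t = (α−1)τ` and negative after.

Between-trial variability in drift and start point is deliberately
omitted: error rates in conflict tasks are low (< 10%), so the
correct/error RT ordering those parameters control is weakly
constrained by data anyway.

### Parameters

| symbol | meaning | units | typical / default |
|---|---|---|---|
| `A0` | initial automatic weight | – | 0.6–0.9 |
| `k_c`, `k_i` | attention shift rates | 1/s | 0–80 / 20–80 |
| `d_a` | automatic base drift (magnitude) | evid/s | 0.3–0.7 |
| `d_c` | controlled base drift | evid/s | 0.4–0.8 |
| `a` | boundary separation | evid | 0.07–0.15 |
| `Ter` | mean non-decision time | ms | 300–370 |
| `st` | non-decision range (uniform on `Ter ± st/2`) | ms | 70 |
| `σ` | diffusion scale | evid/√s | fixed 0.1 |

`σ` is a scaling constant, not a free parameter; it is overridable only
through an explicit argument.  `d_a` is stored as a positive magnitude
and signed at evaluation, matching the positive plausible range used in
recovery.

Time units: the decision process runs in seconds internally, consistent
with the σ = 0.1, a ≈ 0.09 conventions; `Ter`/`st` are specified and
reported in ms and converted at the simulator boundary.  The
pulse-function reference model runs in ms (a = 100, σ = 3 conventions)
to match its customary parameterization.

## Simulation

Euler–Maruyama with Gaussian increments,
`X ← X + v(t)dt + σ√dt·N(0,1)`, default step `dt = 0.5 ms`: the fastest
fitted attention dynamic (k ≈ 93/s) has a time constant of ~11 ms, so
0.5 ms resolves it with >20 steps.  Discrete monitoring of a continuous
barrier overestimates first-passage times by O(√dt); each boundary is
therefore shifted inward by `0.5826·σ·√dt` (the standard continuity
correction for discretely monitored barriers), which cancels the
leading-order bias — empirically, halving `dt` from 1 ms to 0.5 ms then
moves the mean RT by well under 1 ms.  The shift is capped at `a/4` so
pathological (huge-`dt`) calls cannot invert the boundaries; in the
noise-free σ = 0 limit it vanishes, so the integrator reduces to the
deterministic drift path.

Walks that reach neither boundary by 5 s are censored and flagged, never
silently dropped (the empirical task cut-off is ~1.5 s, so 5 s is
conservative).  Trials are simulated vectorized with a shrinking active
set; all randomness flows from one `numpy` Generator, so a dataset is a
pure function of (parameters, n, dt, seed).

A noise-free oracle, `deterministic_crossing_time`, solves
`|d_c·t + (s·d_a − d_c)·A0·(1 − e^(−kt))/k| = a/2` by bracketed root
finding on the closed-form displacement integral; it exists for testing
the integrator and is not part of the stochastic model.

## Summaries

* Quantiles: linear interpolation between order statistics (the common
  default estimator); an independent brute-force implementation in the
  test suite keeps the choice explicit and swappable.
* RT exclusions: keep `200 ms ≤ RT ≤ 1200 ms`, bounds inclusive
  (trials *shorter* than 200 or *longer* than 1200 are dropped).
* Delta plot: per-probability difference of condition quantiles
  (incongruent − congruent) against the mean of the two quantiles (the
  standard x-coordinate convention); slope by ordinary least squares,
  with the sign of (last − first) delta as a secondary classifier.  A
  bin-mean mode uses mean RT within five equal-count bins instead.
* CAF: all trials of a condition sorted by RT and split into five
  equal-count bins, remainder trials assigned to the earliest (fastest)
  bins — deterministic and exactly partition-preserving.
* Group averaging: arithmetic mean of per-subject quantiles at matched
  probabilities; accuracy averaged unweighted across subjects (the
  weighting convention is not dictated by anything in the data model;
  unweighted is the simpler and declared choice).

## Fitting

Quantile chi-square: per condition, correct RTs are binned by their
.1/.3/.5/.7/.9 quantiles into six half-open intervals `(−∞, q1], …,
(q5, ∞)`, and all errors form a seventh bin.  Expected frequencies are
`E_i = P_i·N` with `P_i` the proportion of `n_sim` simulated trials
(default 8000) in bin `i` and `N` the condition trial count; the
statistic is `Σ(O−E)²/E` summed over both conditions, which share all
eight parameters.  The denominator is floored at one observation so a
model predicting (near-)zero errors cannot blow up the statistic; a bin
with `O = E = 0` contributes exactly zero.

One simulation seed is fixed per fit and reused across objective
evaluations (common random numbers), making the objective a
deterministic function of the parameters — a noisy objective would
defeat the simplex's shrink steps.  Minimization is Nelder–Mead within
box bounds, restarted from 10 points drawn within ±10% of the supplied
start; the best restart wins.  Convergence tolerances default to 1e−4
on parameters and objective with at most 1500 evaluations per restart.
When no generating truth exists to centre the multistart, a coarse
seeded random search over the plausible ranges picks the centre (CLI
`fit` without `--start`).

## Synthetic data and what the tests show

The simulator doubles as the synthetic-data generator for every test
and experiment.  It emulates two-condition choice-RT data with the
realistic features the model itself predicts: low error rates (< 10%),
right-skewed RT distributions, fast incongruent errors, and
task-dependent delta-plot slopes.  It does not emulate practice or
fatigue trends, sequential (congruency-sequence) dependencies,
attention lapses/contaminant RTs, or between-subject heterogeneity —
so passing tests demonstrate internal consistency and estimability
under the model's own assumptions, not robustness of the fitting
pipeline to real-data contaminants.

## Experiment problem sizes

Demonstration experiments simulate 4000 trials per condition, the
conventional size for approximating asymptotic model predictions of
delta plots; top-quantile delta estimates carry ~3 ms of Monte-Carlo
noise at that size, so comparisons between presets average a few
replicate runs.  The parameter-recovery harness defaults to a
desk-scale design — 8 datasets, 500 trials/condition, 3 restarts,
2000-trial objective simulations at dt = 1 ms, 200 evaluations per
restart — which finishes in about two minutes on one CPU while leaving
the generating-vs-recovered correlations of the well-identified
parameters (`d_c`, `a`, `Ter`) above 0.9; the full-scale design
(40 datasets, N ∈ {200, 500, 1000}, 10 restarts, 8000-trial
simulations) is available through the same function's arguments.
Recovery starts are drawn within ±10% of the generating values, so the
study measures estimability (whether the objective's optimum sits at
truth), not global-search difficulty.  The generating `st` is the
constant 70 ms, so its recovery correlation is undefined and reported
as `n/a`.

The (k_c, k_diff) slope grid defaults to k_c ∈ {1, 2, 5, 10, 20, 40}
and k_diff = k_i − k_c ∈ {0, 10, 20, 30, 50}, spanning the regimes of
the bundled presets; the reference-model demo exposes the pulse scale
τ as a list argument with {30, 60, 90} ms as illustrative defaults.

## Numerical notes and edge cases

* The pulse-function drift at `t = 0` uses the right limit: `A·e/τ` for
  α = 2, zero for α > 2; for α < 2 the derivative diverges and `t = 0`
  is rejected.
* Quantile bin counts use half-open intervals closed on the right, so
  ties on a bin edge fall in the earlier bin, matching the quantile
  construction.
* The chi-square objective clamps the simplex's exploratory points into
  the valid parameter region (weights in [0, 1], positive drifts and
  boundary, `Ter ≥ st/2`) before simulating.
* Degenerate inputs raise informative errors: empty trial tables,
  all-excluded RT windows, fewer than two RTs for quantiles, fewer
  trials than CAF bins, degenerate x-spread in delta-slope regression,
  unreachable boundaries in the noise-free oracle.

## Known limitations

* No analytic first-passage densities exist for the time-varying drift,
  so all predictions are simulation-based; objective precision is
  limited by `n_sim`.
* Error-RT quantiles are not modelled (errors form a single bin); the
  model as implemented is not suited to tasks with high error rates.
* The fit assumes the two conditions share all parameters; paradigms
  that manipulate speed-accuracy instructions across conditions would
  need per-condition boundaries.
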