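# Methods

## The decision model

Choices and RTs in the two-alternative flicker task are modeled with the
Linear Ballistic Accumulator. Two accumulators (target, foil) start at
independent draws from `U[0, A]`, rise linearly at a drift drawn per
trial from `Normal(v, s)`, and the first to reach the threshold
`b = A + B` produces the response at RT = crossing time + `t0`. Within a
trial the rise is deterministic; all variability is across trials.

Fitting uses the difference parametrization: `v_correct` and
`Δv = v_correct − v_error` (the error drift is never stored separately),
and the threshold gap `B = b − A` instead of `b`. The drift SD of the
correct accumulator is fixed at `s_correct = 1`; this is the scaling
constraint that removes the model's invariance to a common rescaling of
`{A, B, v_correct, Δv, s_error, s_correct}` (a property the test suite
checks directly). All quantities are on a seconds / evidence-units
scale.

An additive urgency component `u` on every drift is carried as an
explicit slot. For a ballistic accumulator it is *exactly* equivalent to
a linearly collapsing threshold `b(τ) = b − u·τ`: for a shared start and
drift draw, `start + (drift + u)·τ = b` and `start + drift·τ = b − u·τ`
have the same solution. The package implements both forms and the test
suite verifies bit-identical RT/response vectors under shared
randomness. Because `v = v_stimulus + v_urgency` is all that enters the
likelihood, the two components are not separately identifiable and the
model variants below treat the effective drift as one quantity.

### Defective densities and numerical choices

The density of responding `r` at time `τ = rt − t0` is
`f_r(τ)·(1 − F_other(τ))` — the winner's crossing density times the
probability the loser has not yet crossed — left *unnormalized* by
`1 − P(both drifts ≤ 0)`, matching the common estimation convention for
this model family; `prob_no_response` reports the neglected mass (it is
of order 1e-4 at fitted ranges). Numerical guards: the normal CDF is
evaluated through `scipy.special.ndtr` (complementary form internally),
densities are floored at 1e-300 before logs, and `trial_loglik` is −∞
for `rt ≤ t0` (a support statement, not a floor). The crossing-time
density inherits a slowly decaying `~1/τ²` tail from near-zero drifts,
so `choice_prob` integrates the defective density as a split quadrature,
`(0, T_bulk]` plus `[T_bulk, ∞)` with
`T_bulk = 20·b / max(min(v/s), 0.1)`, rather than truncating at a fixed
clip — a fixed clip either loses genuine tail mass or makes the adaptive
rule fail.

Simulation redraws trials on which both effective drifts are ≤ 0
(conditional-on-response convention), keeping simulated data consistent
with the unnormalized likelihood; the redraw count is returned.

## Hierarchical structure and priors

Three variants share `{A, s_error, t0, Δv}` across design cells and
free, per cell: the effective drift (`rate_only`), the threshold gap
(`threshold_only`), or both (`both`). A variant bound to a cell list
yields the participant parameter vector (e.g. 4 shared + 6 drifts + 6
gaps = 16 for `both` on the full design) and the chain count
`D = 3 ×` that number.

Participant-level uniform priors and group-level priors:

| parameter | participant | hypermean | hyperSD |
|---|---|---|---|
| v_correct | U(−5, 20) | U(0, 10) | Γ(1, 1) |
| Δv | U(0, 20) | U(0, 10) | Γ(1, 1) |
| s_error | U(0.1, 10) | U(0.1, 5) | Γ(1, 1) |
| A | U(0.01, 20) | U(0.01, 10) | Γ(1, 1) |
| B | U(0.01, 20) | U(0.01, 10) | Γ(1, 1) |
| t0 | U(0.01, 0.5) | U(0.01, 0.5) | Γ(1, 1) |

Γ(1, 1) is shape 1, rate 1 (= Exp(1)). The group distribution family is
not dictated by the priors alone; this package uses a **normal truncated
to the participant-level uniform support** — the standard choice in
hierarchical evidence-accumulation toolboxes — which keeps every
participant prior proper and makes prior draws always have finite
density. Baseline cells are treated per session (each visit has its own
out-of-tub baseline), so the full design has 6 cells.

## DE-MCMC sampler

Each iteration updates, per participant, the full parameter vector by a
crossover move — proposal `x + γ_p (x_a − x_b) + U(−0.001, 0.001)` per
coordinate, donors drawn without replacement from the other chains,
`γ_p = 2.38/√D` — accepted by Metropolis–Hastings against that
participant's conditional posterior (own data likelihood × truncated
normal group prior). Group-level parameters are then updated as
**per-parameter (hypermean, hyperSD) pairs**, each a 2-D crossover with
`γ ~ U[0.5, 1]` drawn fresh per move. A joint crossover of the whole
group vector was tried first and accepted ~2% of proposals, visibly
biasing hypermeans at feasible run lengths; since the conditional of
each pair depends only on that parameter's participant values, per-pair
blocks are a pure sub-blocking of the same move type and accept ~90%.
During burn-in only, with probability 0.05 per iteration, a migration
move lets a random subset of chains (size uniform on 1..D) form a ring
in which each proposes the previous member's full state. Migration is
essential here: without it, chains started from the wide flat priors
fail to coalesce at all (median multivariate PSRF ~40 in a control
experiment).

Support violations are rejected through the −∞ prior, not reflected.
Initialization draws each chain's participant vectors from the flat
participant priors and group vectors from the hyperpriors, retrying (up
to 1,000 times) until the posterior is finite — the only common
rejection cause is `t0` above a participant's fastest RT. The schedule
defaults to 1,000 burn-in iterations, 5,000 sampling iterations, and
immediate thinning by 5 (1,000 retained states per chain). One
`numpy` Generator seeded from the config drives every draw, so identical
seed + config + data reproduce the posterior bit-for-bit.

Two further experimental scan schemes are available behind config flags
and off by default, having shown no reliable gain over the plain scheme
(differences were within seed-to-seed noise): sequential chain-group
updates within an iteration (`update_groups`) and splitting the
participant move into `{t0, B...}` vs drift-side sub-blocks
(`subblocks`); a full-state joint crossover (`joint_move`) collapses to
~1% acceptance and is kept only for experimentation.

### Convergence diagnostics

Univariate Gelman–Rubin R̂ is computed per parameter and the
Brooks–Gelman multivariate PSRF per participant block,
`√((n−1)/n + (m+1)/m · λ₁)` with `λ₁` the largest eigenvalue of
`W⁻¹B/n`; the headline statistic is the **median multivariate PSRF
across participants**, with 1.05 as the conventional bound.
Zero-variance parameters are excluded from the multivariate statistic
with a warning. Chains that accept no proposal within a sliding window
of post-burn-in iterations are flagged "stuck", and the group-level
summary is reported with and without them.

**Honest accounting of convergence at reduced scale.** At the reduced
scale used by the acceptance script (6 participants × 150 trials × 2
cells, `threshold_only`, the full printed schedule), the median
multivariate PSRF lands at ≈ 1.15–1.35 depending on the seed, not under
1.05. The cause is
geometric, not a burn-in failure: the participant-level posterior has a
strongly curved `t0`–`B` ridge (posterior correlations ≈ −0.96) whose
slowest direction has an autocorrelation time of several hundred
retained samples, a sizable fraction of the 1,000 retained states the
schedule allows; tripling burn-in does not change the result, and an
iid-resampling control shows an ideal sampler would score ≈ 1.01 here.
With the full design (6 cells sharing `t0, A, Δv, s_error`) and a
full-size panel the shared parameters are far better identified and the
ridge is much weaker — the two-cell reduction is what makes this
configuration hard. The diagnostic value reported by the acceptance
script is computed, never asserted.

## Model selection

From stored per-sample log-likelihoods: `D̄` = mean posterior deviance,
`pD = D̄ − D(θ̄)` with `θ̄` the posterior mean of every participant-level
parameter (a minimum-deviance variant of `pD` is available behind a
flag), and `BPIC = D̄ + 2·pD`; variants are ranked by BPIC ascending
with Δ BPIC relative to the best and explicit tie flags. Comparisons
refuse to mix fits whose preprocessed-data hashes differ. Negative `pD`
is reported and flagged, never clipped.

Posterior-predictive checks simulate replicate datasets (observed trial
counts per participant × cell) from 100 random posterior draws by
default and summarize defective RT distributions: quantiles
{0.1, 0.3, 0.5, 0.7, 0.9} of correct and error RTs with the response
proportions that scale each curve, against the observed counterparts,
with central 95% envelopes. Cells with no error responses are flagged
undefined rather than imputed.

## Synthetic study generator

The generator emulates the study's structure so that every downstream
stage has a ground truth: 2 water-temperature conditions × 3 measurement
moments, an interval-reproduction task around a learned 1 s target, and
a 2AFC flicker task (Bernoulli frame streams at rates 0.7 target / 0.3
foil, 20 frames/s — the frame rate is not part of the analysis and the
frames are generated only for task fidelity; choices come from the LBA).

Timing follows a pacemaker-accumulator clock:
`reproduction = target × bias / rate_ratio × LogNormal(mean 1, CV cv)`.
`rate_ratio` is the pacemaker rate relative to the rate at which the
target was learned (fixed at 1 in every Baseline cell), `bias = 0.95`
captures the general underproduction tendency, and `cv = 0.1` is a
typical scalar-timing Weber fraction. Defaults place the speed-up at
Warm-Begin 1.05 and Warm-End 1.12 with an across-participant SD of
0.04.

Group LBA truth defaults (means ± across-participant SDs): `A` 0.5 ±
0.10, `B` 0.7 ± 0.15 at Baseline, `v_correct` 2.5 ± 0.40, `Δv` 1.0 ±
0.30, `s_error` 0.8 ± 0.10, `t0` 0.2 ± 0.03 — chosen once to produce
deadline-task behavior in a realistic range (mean RT ≈ 0.6 s against the
1 s deadline, accuracy ≈ 0.8) with the drift shared across cells and
only the threshold varying, i.e. a `threshold_only`-compatible truth.
Each participant's Warm-cell threshold gap is
`B_baseline − coupling·(rate_ratio − 1) + Normal(0, 0.05)` with
`coupling = 1.5` by default, so clock speed-up and threshold reduction
are positively coupled across participants and the cross-task
correlation is recoverable end-to-end. Trials per cell default to 60
(the study states only 50 practice trials; block length is
configurable). Deadline misses are generated, flagged and retained —
the deadline gated feedback, not responding — and a `--drop-late`
preprocessing flag provides the alternative reading.

Randomness uses one master `SeedSequence` with spawned child streams per
participant and per (cell, task), so datasets are byte-identical under a
fixed seed and insensitive to generation order.

What the generator does *not* emulate: practice/learning dynamics,
sequential effects, lapses and fast guesses (so the 200 ms filter is
exercised by construction only), frame-locked evidence accumulation,
physiological traces, and session/order effects. Passing tests
therefore show the pipeline recovers the assumed generative structure,
not that the model is true of real data.

## Preprocessing

Fixed order: validate → exclude choice RTs faster than 200 ms (strict
`rt < 0.2 s`; a trial at exactly 200 ms is kept) → natural-log RT
transform → baseline-relative measures. Continuous measures are
z-scored per participant × session against that session's out-of-tub
Baseline (`(cell mean − Baseline mean)/Baseline SD`; a zero-spread
baseline is an error, not a silent NaN). Accuracy, where z-scoring a
proportion is meaningless, is expressed as a difference from Baseline
with the Baseline proportion carried as a covariate column. Cross-task
claims are covered at the descriptive level by Pearson correlations of
baseline-relative changes per condition and pooled; mixed-effects
regressions and ANCOVA F-tests on real data are deliberately out of
scope.

## Known limitations

* The group-level normal-truncated family and the per-session baseline
  sharing are assumptions the source description leaves open; both are
  configurable in principle but fixed here.
* BPIC's `pD` uses the posterior-mean deviance; with very short chains
  it can go negative (flagged).
* The reduced two-cell fit does not reach the 1.05 convergence bound
  (see above); at full design scale the sampler has no such difficulty
  in the regimes we tested.
* `correlate_changes` treats fitted posterior means as data
  (no measurement-error propagation), which attenuates correlations —
  the same conservatism hierarchical shrinkage induces.
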