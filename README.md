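# thermolba

Hierarchical Bayesian modeling of speeded choice under deadlines, built
around the Linear Ballistic Accumulator (LBA), for studies that link an
internal-clock speed-up (for example under passive hyperthermia) to how
people set their decision thresholds.

The package provides, as a tested, reusable pipeline:

* **an LBA kernel** — closed-form accumulator densities, defective
  PDFs/CDFs, choice probabilities, trial log-likelihoods, and the exact
  equivalence between an additive urgency signal and a linearly
  collapsing threshold;
* **three hierarchical model variants** — the effective drift rate, the
  threshold gap, or both may vary across design cells, with all printed
  participant-level and group-level priors;
* **a DE-MCMC sampler** — differential-evolution MCMC with crossover and
  migration moves, blocked participant/group updates, Gelman–Rubin and
  Brooks–Gelman convergence diagnostics, and stuck-chain detection;
* **model selection** — deviance summaries, BPIC, and
  posterior-predictive defective CDFs;
* **behavioral preprocessing** — trial-table I/O, the 200 ms fast-guess
  exclusion, log-RT transform, baseline-relative z-scores, accuracy
  covariates, and cross-task change correlations;
* **a synthetic study generator** — both tasks of a
  2 (Neutral/Warm) × 3 (Baseline/Begin/End) design: interval
  reproductions from a pacemaker-accumulator clock and 2AFC flicker
  choices from the LBA, with a configurable coupling between each
  participant's clock speed-up and threshold reduction, so every stage
  of the pipeline is testable without participant data.

## The model in brief

Each response option accrues evidence linearly from a start point drawn
uniformly on `[0, A]` toward a threshold `b = A + B`, at a drift drawn
once per trial from a normal distribution (mean `v`, SD `s`); the first
accumulator to reach `b` gives the response, and RT = crossing time +
`t0`. Fitting uses the difference parametrization `Δv = v_correct −
v_error`, `B = b − A`, with `s_correct = 1` as the scaling constraint.
An additive urgency `u` on every drift is exactly equivalent to a
threshold collapsing as `b − u·τ`.

Participants' parameters are drawn from group-level normals (hypermean,
hyperSD) truncated to wide uniform supports, with uniform hypermean
priors and `Γ(1, 1)` hyperSD priors. Sampling uses `D = 3 ×` (number of
participant-level parameters) chains; crossover proposals are
`γ·(x_a − x_b)` plus a small uniform perturbation with
`γ = 2.38/√D` at the participant level and `γ ~ U[0.5, 1]` at the group
level; migration runs with probability 0.05 during a 1,000-iteration
burn-in; 5,000 sampling iterations are thinned by 5. Model variants are
compared by BPIC = D̄ + 2·pD.

The timing task follows a pacemaker-accumulator clock:
`reproduction = target × bias / rate_ratio × lognormal noise`, so a
faster clock (rate_ratio > 1) shortens reproductions.

## Worked example

```python
from thermolba import build_model, generate_study, run_sampler, SamplerConfig
from thermolba.pipeline import filter_fast_rts
from thermolba.sampler import psrf

cells = [("Warm", "Baseline"), ("Warm", "End")]
study = generate_study(n_participants=6, n_trials_per_cell=150,
                       seed=11, cells=cells)
choice, report = filter_fast_rts(study.trials[study.trials.task == "choice"])
print(f"retained {report['n_retained']}/{report['n_input']} trials")

model = build_model("threshold_only", cells)
print(f"{model.n_params} participant-level parameters, D = {model.n_chains} chains")

post = run_sampler(choice, model,
                   config=SamplerConfig(n_burn=1000, n_sample=5000,
                                        thin=5, seed=3))
print(post.group_summary().round(3).to_string(index=False))
print(f"median multivariate PSRF: {psrf(post)['median_mpsrf']:.3f}")
```

Output (abridged):

```
retained 1800/1800 trials
7 participant-level parameters, D = 21 chains
       parameter  hypermean_mean  hypermean_sd  hypersd_mean  hypersd_sd
               A           0.454         0.222         0.346       0.229
         s_error           0.855         0.078         0.075       0.097
              t0           0.198         0.047         0.082       0.254
         delta_v           0.885         0.279         0.506       0.302
       v_correct           2.800         0.326         0.652       0.293
B[Warm:Baseline]           0.737         0.164         0.086       0.100
     B[Warm:End]           0.525         0.191         0.207       0.145
median multivariate PSRF: 1.223
```

The generating group means were A = 0.5, s_error = 0.8, t0 = 0.2,
Δv = 1.0, v_correct = 2.5, B = 0.7 at Baseline and 0.52 at Warm-End
(threshold reduction coupled to the clock speed-up) — each recovered
within roughly one posterior SD.

A command-line interface mirrors the library:

```bash
thermolba simulate --participants 27 --trials-per-cell 60 --seed 1 --out data/
thermolba preprocess --in data/trials.csv --out clean.csv --report report.json
thermolba fit --data clean.csv --variant threshold --seed 2 --out fit/
thermolba diagnose --fit fit/
thermolba compare --fits fitA fitB fitC --out table.csv
thermolba ppc --fit fit/ --data clean.csv --out ppc.csv
```

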