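"""Differential-evolution MCMC for the hierarchical LBA model.

A population of D chains (D = 3 x the number of participant-level
parameters) is updated by Metropolis–Hastings with two move types:

* crossover — a chain proposes its current state plus a scaled difference
  of two other chains' states, gamma * (x_a - x_b), plus a small uniform
  perturbation on [-0.001, 0.001] per coordinate.  gamma = 2.38 / sqrt(D)
  for participant-level blocks; for the group-level block gamma is drawn
  fresh from U[0.5, 1] at every move.
* migration — with probability 0.05 per iteration (during burn-in only),
  a random subset of chains forms a ring and each proposes the previous
  ring member's full state.

Updates are blocked: each participant's parameter vector conditional on
the group parameters and that participant's own trials, then the group
vector conditional on all participants.  The hierarchical structure lets
one participant's parameters be informed by everyone else's through the
group level.  Burn-in runs 1,000 iterations by default, followed by at
least 5,000 sampling iterations thinned by 5 as they are produced.

Convergence is assessed by the Gelman–Rubin diagnostic, including the
Brooks–Gelman multivariate PSRF computed per participant and summarized
by its median (threshold 1.05).  Chains that stop accepting proposals for
long stretches ("stuck" chains) are flagged, and posterior summaries with
and without them are reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import linalg

from .design import DesignCell
from .hier import (
    DEFAULT_PRIORS,
    ModelVariant,
    PriorSpec,
    hypermean_bounds,
    hyperprior_param_logpdf,
    log_prior_participant,
    log_prior_participant_components,
    participant_bounds,
    sample_group_prior,
    sample_participant_prior,
    trunc_normal_logpdf,
)
from .lba import defective_logpdf_arrays

__all__ = [
    "SamplerConfig",
    "HierarchicalPosterior",
    "crossover_update",
    "migration_update",
    "run_demcmc",
    "run_sampler",
    "gelman_rubin",
    "multivariate_psrf",
    "psrf",
    "detect_stuck",
    "PSRF_THRESHOLD",
]

#: conventional convergence bound on the (multivariate) PSRF
PSRF_THRESHOLD = 1.05


@dataclass(frozen=True)
class SamplerConfig:
    """DE-MCMC schedule and tuning constants.

    Defaults are the full-scale settings; reduced-scale runs shorten
    n_burn / n_sample but keep every tuning constant.
    """

    n_burn: int = 1000
    n_sample: int = 5000
    thin: int = 5
    migration_prob: float = 0.05  # burn-in only
    perturbation_halfwidth: float = 0.001
    group_gamma_range: tuple = (0.5, 1.0)
    seed: int | None = None
    max_init_tries: int = 1000
    stuck_window: int = 200
    #: optionally propose one full-state (all participants + group)
    #: crossover per iteration; rarely useful — the joint dimension makes
    #: acceptance collapse — kept for experimentation
    joint_move: bool = False
    #: split each participant update into two crossover sub-blocks:
    #: {t0, threshold gaps} versus the drift-side parameters.  Off by
    #: default: the posterior ridge couples the two groups, so Gibbs
    #: alternation between them mixes worse than full-vector moves.
    subblocks: bool = False
    #: number of chain groups updated sequentially within one iteration
    #: (1 = fully synchronous sweep, the default).  Later groups draw
    #: donors from already-updated chains (Gauss-Seidel-style); measured
    #: gains over the synchronous sweep were within seed noise, so the
    #: plain scheme stays the default.
    update_groups: int = 1

    def __post_init__(self):
        if self.n_burn < 0 or self.n_sample < 1 or self.thin < 1:
            raise ValueError("invalid schedule")
        if not 0.0 <= self.migration_prob <= 1.0:
            raise ValueError("migration_prob must be in [0, 1]")

    @property
    def n_retained(self) -> int:
        return self.n_sample // self.thin


def participant_gamma(n_chains: int) -> float:
    """Crossover weight 2.38 / sqrt(D) for participant-level blocks."""
    return 2.38 / np.sqrt(n_chains)


# ---------------------------------------------------------------------------
# population moves (generic: operate on (D, P) state arrays)
# ---------------------------------------------------------------------------

def _pick_donor_pairs(D: int, rng: np.random.Generator):
    """For every chain i, two distinct donor chains a, b, both != i."""
    idx = np.arange(D)
    a = rng.integers(0, D - 1, size=D)
    a += a >= idx
    b = rng.integers(0, D - 2, size=D)
    lo = np.minimum(idx, a)
    hi = np.maximum(idx, a)
    b += b >= lo
    b += b >= hi
    return a, b


def crossover_update(pop, logp, logpost_fn, gamma, rng,
                     perturb: float = 0.001):
    """One synchronous crossover sweep over all chains of one block.

    pop (D, P) and logp (D,) are modified in place; returns the boolean
    acceptance vector.  gamma may be a scalar or a (D, 1) array.  Donor
    states are taken from the pre-sweep population snapshot.
    """
    pop = np.asarray(pop)
    D = pop.shape[0]
    if D < 3:
        raise ValueError("crossover requires at least 3 chains")
    a, b = _pick_donor_pairs(D, rng)
    prop = pop + gamma * (pop[a] - pop[b]) + rng.uniform(
        -perturb, perturb, size=pop.shape
    )
    lp = logpost_fn(prop)
    with np.errstate(invalid="ignore"):
        accept = np.log(rng.random(D)) < (lp - logp)
    accept &= np.isfinite(lp)
    pop[accept] = prop[accept]
    logp[accept] = lp[accept]
    return accept


def migration_update(states: list, logp, rng):
    """One migration event over full chain states.

    `states` is a list of arrays whose first axis indexes chains; a
    random subset of chains (uniform size 1..D) forms a ring in which
    each member proposes the previous member's state, accepted by MH
    against the cached log posterior `logp` (modified in place).
    Returns the boolean acceptance vector (False for non-ring chains).
    """
    D = len(logp)
    k = int(rng.integers(1, D + 1))
    ring = rng.choice(D, size=k, replace=False)
    accept = np.zeros(D, dtype=bool)
    if k < 2:
        return accept  # self-exchange is a no-op
    src = np.roll(ring, 1)  # ring[j] proposes state of ring[j-1]
    snaps = [np.array(s[src]) for s in states]
    logp_src = logp[src].copy()
    ok = np.log(rng.random(k)) < (logp_src - logp[ring])
    for s, sn in zip(states, snaps):
        s[ring[ok]] = sn[ok]
    logp[ring[ok]] = logp_src[ok]
    accept[ring[ok]] = True
    return accept


def run_demcmc(logpost_fn, x0, n_burn, n_sample, thin, rng,
               gamma=None, migration_prob=0.0, perturb=0.001):
    """Generic DE-MCMC on a single flat target (no blocking).

    x0: (D, P) initial population with finite log posterior.  Returns
    (samples (S, D, P), accept_rate).  Used for sampler validation on toy
    targets with known moments.
    """
    pop = np.array(x0, dtype=float)
    D, P = pop.shape
    if gamma is None:
        gamma = participant_gamma(D)
    logp = np.asarray(logpost_fn(pop), dtype=float)
    if not np.all(np.isfinite(logp)):
        raise ValueError("initial population has non-finite log posterior")
    retained = []
    n_acc = 0
    n_tot = 0
    for it in range(n_burn + n_sample):
        if it < n_burn and migration_prob > 0 and rng.random() < migration_prob:
            migration_update([pop], logp, rng)
        acc = crossover_update(pop, logp, logpost_fn, gamma, rng, perturb)
        n_acc += int(acc.sum())
        n_tot += D
        if it >= n_burn and (it - n_burn + 1) % thin == 0:
            retained.append(pop.copy())
    return np.array(retained), n_acc / n_tot


# ---------------------------------------------------------------------------
# hierarchical fit
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalPosterior:
    """Retained DE-MCMC samples with chain structure preserved.

    theta: (S, D, n_participants, P) participant-level samples
    phi:   (S, D, 2P) group-level samples [hypermeans, hyperSDs]
    loglik: (S, D, n_participants) data log-likelihood per sample
    accepted: (n_iterations, D) accepted block-updates per iteration
              (participant crossovers + group crossover + migration)
    """

    model: ModelVariant
    config: SamplerConfig
    participants: list
    theta: np.ndarray
    phi: np.ndarray
    loglik: np.ndarray
    accepted: np.ndarray
    n_blocks_per_iter: int
    accept_rate: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.theta.shape[0]

    @property
    def n_chains(self) -> int:
        return self.theta.shape[1]

    def flat_theta(self) -> np.ndarray:
        """(S*D, n_participants, P): chains pooled."""
        S, D, n, P = self.theta.shape
        return self.theta.reshape(S * D, n, P)

    def flat_phi(self) -> np.ndarray:
        S, D, Q = self.phi.shape
        return self.phi.reshape(S * D, Q)

    def participant_mean(self) -> np.ndarray:
        """(n_participants, P) posterior-mean parameter vectors."""
        return self.flat_theta().mean(axis=0)

    def theta_of(self, participant_id) -> np.ndarray:
        i = self.participants.index(participant_id)
        return self.flat_theta()[:, i, :]

    def group_summary(self, chains=None) -> pd.DataFrame:
        """Posterior mean/SD of every hypermean and hyperSD.

        `chains` optionally restricts to a subset of chain indices (used
        by the stuck-chain influence report).
        """
        phi = self.phi if chains is None else self.phi[:, chains, :]
        flat = phi.reshape(-1, phi.shape[-1])
        P = self.model.n_params
        rows = []
        for j, name in enumerate(self.model.param_names):
            rows.append({
                "parameter": name,
                "hypermean_mean": flat[:, j].mean(),
                "hypermean_sd": flat[:, j].std(ddof=1),
                "hypersd_mean": flat[:, P + j].mean(),
                "hypersd_sd": flat[:, P + j].std(ddof=1),
            })
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (level, participant, parameter, cell, chain,
        iteration, value) table of every retained sample."""
        S, D, n, P = self.theta.shape
        names = self.model.param_names
        cells = [c.label if c is not None else "" for c in self.model.cell_of]
        recs = []
        it_idx = np.repeat(np.arange(S), D)
        ch_idx = np.tile(np.arange(D), S)
        for j in range(P):
            for i, pid in enumerate(self.participants):
                vals = self.theta[:, :, i, j].reshape(-1)
                recs.append(pd.DataFrame({
                    "level": "participant", "participant": pid,
                    "parameter": names[j], "cell": cells[j],
                    "chain": ch_idx, "iteration": it_idx, "value": vals,
                }))
            for lvl, col in (("hypermean", j), ("hypersd", P + j)):
                vals = self.phi[:, :, col].reshape(-1)
                recs.append(pd.DataFrame({
                    "level": lvl, "participant": "",
                    "parameter": names[j], "cell": cells[j],
                    "chain": ch_idx, "iteration": it_idx, "value": vals,
                }))
        return pd.concat(recs, ignore_index=True)

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        cfg["group_gamma_range"] = list(cfg["group_gamma_range"])
        return {
            "model": self.model.to_config(),
            "config": cfg,
            "participants": [str(p) for p in self.participants],
            "n_retained": int(self.n_retained),
            "n_chains": int(self.n_chains),
            "accept_rate": {k: float(v) for k, v in self.accept_rate.items()},
        }

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_long_frame().to_csv(out / "samples.csv", index=False)
        S, D, n, _ = self.theta.shape
        ll = pd.DataFrame({
            "iteration": np.repeat(np.arange(S), D * n),
            "chain": np.tile(np.repeat(np.arange(D), n), S),
            "participant": np.tile([str(p) for p in self.participants], S * D),
            "loglik": self.loglik.reshape(-1),
        })
        ll.to_csv(out / "loglik.csv", index=False)
        man = self.manifest()
        rep = psrf(self)
        man["psrf"] = rep["table"].to_dict(orient="records")
        man["median_mpsrf"] = float(rep["median_mpsrf"])
        np.savetxt(out / "accepted.csv", self.accepted, fmt="%d", delimiter=",")
        (out / "manifest.json").write_text(json.dumps(man, indent=2))

    @classmethod
    def load(cls, fitdir) -> "HierarchicalPosterior":
        """Rebuild a posterior from :meth:`save` output (samples.csv,
        loglik.csv, accepted.csv, manifest.json)."""
        from pathlib import Path

        from .hier import build_model

        out = Path(fitdir)
        man = json.loads((out / "manifest.json").read_text())
        model = build_model(man["model"]["variant"], man["model"]["cells"])
        cfg_d = dict(man["config"])
        cfg_d["group_gamma_range"] = tuple(cfg_d["group_gamma_range"])
        config = SamplerConfig(**cfg_d)
        participants = man["participants"]
        S, D, P = man["n_retained"], man["n_chains"], model.n_params
        n = len(participants)
        long = pd.read_csv(out / "samples.csv",
                           dtype={"participant": str}, na_filter=False)
        theta = np.empty((S, D, n, P))
        phi = np.empty((S, D, 2 * P))
        pidx = {pid: i for i, pid in enumerate(participants)}
        jidx = {name: j for j, name in enumerate(model.param_names)}
        for (level, part, param), grp in long.groupby(
                ["level", "participant", "parameter"]):
            j = jidx[param]
            vals = grp.sort_values(["iteration", "chain"])["value"] \
                .to_numpy().reshape(S, D)
            if level == "participant":
                theta[:, :, pidx[part], j] = vals
            elif level == "hypermean":
                phi[:, :, j] = vals
            else:
                phi[:, :, P + j] = vals
        ll_long = pd.read_csv(out / "loglik.csv", dtype={"participant": str})
        loglik = np.empty((S, D, n))
        for part, grp in ll_long.groupby("participant"):
            loglik[:, :, pidx[part]] = grp.sort_values(
                ["iteration", "chain"])["loglik"].to_numpy().reshape(S, D)
        accepted = np.loadtxt(out / "accepted.csv", dtype=np.int32,
                              delimiter=",", ndmin=2)
        return cls(model=model, config=config, participants=list(participants),
                   theta=theta, phi=phi, loglik=loglik, accepted=accepted,
                   n_blocks_per_iter=n + 1,
                   accept_rate=man.get("accept_rate", {}))


class _ParticipantData:
    """Per-participant trial arrays grouped by cell, with slot indices
    resolved once so likelihood evaluation is pure array work."""

    __slots__ = ("blocks",)

    def __init__(self, trials: pd.DataFrame, model: ModelVariant):
        self.blocks = []
        for (cond, mom), grp in trials.groupby(["condition", "moment"],
                                               observed=True):
            cell = DesignCell(cond, mom)
            s = model.cell_slots(cell)
            ix = (s["A"], s["B"], s["v_correct"], s["delta_v"],
                  s["s_error"], s["t0"])
            rt = grp["rt_s"].to_numpy(dtype=float)
            is_t = (grp["response"].to_numpy() == "target")
            self.blocks.append((ix, rt, is_t))

    def loglik(self, theta: np.ndarray) -> np.ndarray:
        """theta (m, P) -> (m,) data log-likelihood.  Parameters are
        clipped into the positivity domain for evaluation; out-of-support
        proposals are vetoed by the prior term, not here."""
        m = theta.shape[0]
        out = np.zeros(m)
        for ix, rt, is_t in self.blocks:
            A = np.maximum(theta[:, ix[0]], 1e-9)[:, None]
            B = np.maximum(theta[:, ix[1]], 0.0)[:, None]
            v = theta[:, ix[2]][:, None]
            dv = np.maximum(theta[:, ix[3]], 0.0)[:, None]
            se = np.maximum(theta[:, ix[4]], 1e-9)[:, None]
            t0 = theta[:, ix[5]][:, None]
            ll = defective_logpdf_arrays(
                rt[None, :], is_t[None, :],
                A, A + B, v, v - dv, 1.0, se, t0,
            )
            out += ll.sum(axis=1)
        return out


def run_sampler(trials: pd.DataFrame, model: ModelVariant,
                priors: PriorSpec = DEFAULT_PRIORS,
                config: SamplerConfig = SamplerConfig()) -> HierarchicalPosterior:
    """Fit the hierarchical LBA to a preprocessed choice-trial table.

    `trials` needs columns participant_id, condition, moment, rt_s,
    response, restricted to choice trials that passed the fast-RT filter.
    Identical seed, config and data give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    participants = sorted(trials["participant_id"].unique())
    n_part = len(participants)
    if n_part == 0:
        raise ValueError("no trials")
    P = model.n_params
    D = model.n_chains
    gamma_p = participant_gamma(D)
    pdata = [
        _ParticipantData(trials[trials["participant_id"] == pid], model)
        for pid in participants
    ]

    # --- initialization: prior draws, retried until the posterior is finite
    phi = np.empty((D, 2 * P))
    theta = np.empty((D, n_part, P))
    for d in range(D):
        phi[d] = sample_group_prior(model, rng, priors)
    for d in range(D):
        for i in range(n_part):
            for attempt in range(config.max_init_tries):
                cand = sample_participant_prior(model, rng, priors)
                lp = log_prior_participant(cand, phi[d], model, priors)
                if not np.isfinite(lp):
                    continue
                ll = pdata[i].loglik(cand[None, :])[0]
                if np.isfinite(ll):
                    theta[d, i] = cand
                    break
            else:
                raise RuntimeError(
                    f"no finite-posterior start for participant "
                    f"{participants[i]} chain {d} after "
                    f"{config.max_init_tries} tries (check data/t0 support)"
                )

    # --- caches
    # prior_cube[d, i, j] = log TN(theta[d, i, j] | mu_j, sd_j) per chain;
    # hyper_mat[d, j] = log hyperprior of the j-th (mu, sd) pair
    ll = np.stack([pdata[i].loglik(theta[:, i, :]) for i in range(n_part)],
                  axis=1)                                   # (D, n_part)
    prior_cube = log_prior_participant_components(
        theta, phi[:, None, :], model, priors)              # (D, n_part, P)
    hm_lo, hm_hi = hypermean_bounds(model, priors)
    lo_p, hi_p = participant_bounds(model, priors)
    g_shape, g_rate = priors.hypersd_gamma
    hyper_mat = np.stack([
        hyperprior_param_logpdf(phi[:, j], phi[:, P + j], hm_lo[j], hm_hi[j],
                                g_shape, g_rate)
        for j in range(P)
    ], axis=1)                                              # (D, P)

    # participant-update coordinate blocks: the non-decision time and the
    # threshold gaps form one tightly correlated cluster (raising the
    # threshold and shifting t0 trade off against each other), the
    # drift-side parameters the other
    if config.subblocks:
        ridge = np.array([j for j, base in enumerate(model.base_names)
                          if base in ("t0", "B")], dtype=int)
        rest = np.array([j for j in range(P) if j not in set(ridge)],
                        dtype=int)
        part_blocks = [blk for blk in (rest, ridge) if len(blk)]
    else:
        part_blocks = [np.arange(P)]

    n_total = config.n_burn + config.n_sample
    n_blocks = n_part + 1
    accepted = np.zeros((n_total, D), dtype=np.int32)
    acc_counts = {"participant": 0, "group": 0, "migration": 0}
    prop_counts = {"participant": 0, "group": 0, "migration": 0}

    S = config.n_retained
    theta_out = np.empty((S, D, n_part, P))
    phi_out = np.empty((S, D, 2 * P))
    ll_out = np.empty((S, D, n_part))
    s_idx = 0

    for it in range(n_total):
        in_burn = it < config.n_burn
        if in_burn and rng.random() < config.migration_prob:
            total = ll.sum(axis=1) + prior_cube.sum(axis=(1, 2)) \
                + hyper_mat.sum(axis=1)
            acc = _migrate_full(theta, phi, ll, prior_cube, hyper_mat,
                                total, rng)
            accepted[it] += acc.astype(np.int32)
            acc_counts["migration"] += int(acc.sum())
            prop_counts["migration"] += D

        # optional joint move: crossover on the concatenated
        # (all-participant, group) state against the full posterior
        if config.joint_move:
            flat = np.concatenate(
                [theta.reshape(D, n_part * P), phi], axis=1)
            a, b = _pick_donor_pairs(D, rng)
            gamma_j = 2.38 / np.sqrt(flat.shape[1])
            prop = flat + gamma_j * (flat[a] - flat[b]) + rng.uniform(
                -config.perturbation_halfwidth,
                config.perturbation_halfwidth, size=flat.shape)
            th_new = prop[:, :n_part * P].reshape(D, n_part, P)
            phi_new = prop[:, n_part * P:]
            pr_new_c = log_prior_participant_components(
                th_new, phi_new[:, None, :], model, priors)
            hyp_new = np.stack([
                hyperprior_param_logpdf(phi_new[:, j], phi_new[:, P + j],
                                        hm_lo[j], hm_hi[j], g_shape, g_rate)
                for j in range(P)
            ], axis=1)
            pr_sum = pr_new_c.sum(axis=(1, 2)) + hyp_new.sum(axis=1)
            ll_new = np.full((D, n_part), -np.inf)
            valid = np.isfinite(pr_sum)
            if valid.any():
                for i in range(n_part):
                    ll_new[valid, i] = pdata[i].loglik(th_new[valid, i, :])
            logr = (pr_sum + ll_new.sum(axis=1)) - (
                prior_cube.sum(axis=(1, 2)) + hyper_mat.sum(axis=1)
                + ll.sum(axis=1))
            with np.errstate(invalid="ignore"):
                acc = np.log(rng.random(D)) < logr
            acc &= np.isfinite(logr)
            theta[acc] = th_new[acc]
            phi[acc] = phi_new[acc]
            ll[acc] = ll_new[acc]
            prior_cube[acc] = pr_new_c[acc]
            hyper_mat[acc] = hyp_new[acc]
            accepted[it] += acc.astype(np.int32)
            acc_counts.setdefault("joint", 0)
            prop_counts.setdefault("joint", 0)
            acc_counts["joint"] += int(acc.sum())
            prop_counts["joint"] += D

        # participant blocks
        for i in range(n_part):
            g = max(1, min(config.update_groups, D))
            if g > 1:
                perm = rng.permutation(D)
                chain_sets = np.array_split(perm, g)
            else:
                chain_sets = [np.arange(D)]
            for upd in chain_sets:
                for coords in part_blocks:
                    pop = theta[:, i, :]
                    a, b = _pick_donor_pairs(D, rng)
                    a, b = a[upd], b[upd]
                    prop = pop[upd].copy()
                    prop[:, coords] += (
                        gamma_p * (pop[a][:, coords] - pop[b][:, coords])
                        + rng.uniform(-config.perturbation_halfwidth,
                                      config.perturbation_halfwidth,
                                      size=(len(upd), len(coords))))
                    pr_new_c = log_prior_participant_components(
                        prop, phi[upd], model, priors)       # (m, P)
                    pr_new = pr_new_c.sum(axis=1)
                    ll_new = np.full(len(upd), -np.inf)
                    valid = np.isfinite(pr_new)
                    if valid.any():
                        ll_new[valid] = pdata[i].loglik(prop[valid])
                    logr = (pr_new + ll_new) - (
                        prior_cube[upd, i, :].sum(axis=1) + ll[upd, i])
                    with np.errstate(invalid="ignore"):
                        acc = np.log(rng.random(len(upd))) < logr
                    acc &= np.isfinite(pr_new + ll_new)
                    dest = upd[acc]
                    theta[dest, i, :] = prop[acc]
                    ll[dest, i] = ll_new[acc]
                    prior_cube[dest, i, :] = pr_new_c[acc]
                    accepted[it, dest] += 1
                    acc_counts["participant"] += int(acc.sum())
                    prop_counts["participant"] += len(upd)

        # group block: one (hypermean, hyperSD) pair per base parameter —
        # each pair's conditional depends only on that parameter's
        # participant values, so small blocks mix far better than a
        # joint update of the whole group vector
        group_acc = np.zeros(D, dtype=bool)
        for j in range(P):
            pair = np.column_stack([phi[:, j], phi[:, P + j]])   # (D, 2)
            a, b = _pick_donor_pairs(D, rng)
            gamma_g = rng.uniform(*config.group_gamma_range, size=(D, 1))
            prop = pair + gamma_g * (pair[a] - pair[b]) + rng.uniform(
                -config.perturbation_halfwidth,
                config.perturbation_halfwidth, size=pair.shape)
            hyp_new = hyperprior_param_logpdf(
                prop[:, 0], prop[:, 1], hm_lo[j], hm_hi[j], g_shape, g_rate)
            pr_new = trunc_normal_logpdf(
                theta[:, :, j], prop[:, 0:1], prop[:, 1:2],
                lo_p[j], hi_p[j])                            # (D, n_part)
            logr = (hyp_new + pr_new.sum(axis=1)) - (
                hyper_mat[:, j] + prior_cube[:, :, j].sum(axis=1))
            with np.errstate(invalid="ignore"):
                acc = np.log(rng.random(D)) < logr
            acc &= np.isfinite(hyp_new)
            phi[acc, j] = prop[acc, 0]
            phi[acc, P + j] = prop[acc, 1]
            hyper_mat[acc, j] = hyp_new[acc]
            prior_cube[acc, :, j] = pr_new[acc]
            group_acc |= acc
        accepted[it] += group_acc.astype(np.int32)
        acc_counts["group"] += int(group_acc.sum())
        prop_counts["group"] += D

        if not in_burn and (it - config.n_burn + 1) % config.thin == 0:
            theta_out[s_idx] = theta
            phi_out[s_idx] = phi
            ll_out[s_idx] = ll
            s_idx += 1

    rates = {k: acc_counts[k] / prop_counts[k]
             for k in acc_counts if prop_counts[k]}
    post = HierarchicalPosterior(
        model=model, config=config, participants=list(participants),
        theta=theta_out[:s_idx], phi=phi_out[:s_idx], loglik=ll_out[:s_idx],
        accepted=accepted, n_blocks_per_iter=n_blocks, accept_rate=rates,
    )
    return post


def _migrate_full(theta, phi, ll, prior_mat, hyper, total, rng):
    """Migration over full chain states (theta, phi and caches)."""
    D = len(total)
    k = int(rng.integers(1, D + 1))
    ring = rng.choice(D, size=k, replace=False)
    accept = np.zeros(D, dtype=bool)
    if k < 2:
        return accept
    src = np.roll(ring, 1)
    snaps = [np.array(x[src]) for x in (theta, phi, ll, prior_mat, hyper, total)]
    ok = np.log(rng.random(k)) < (snaps[5] - total[ring])
    dest = ring[ok]
    for x, sn in zip((theta, phi, ll, prior_mat, hyper), snaps[:5]):
        x[dest] = sn[ok]
    accept[dest] = True
    return accept


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(x: np.ndarray) -> np.ndarray:
    """Univariate R-hat per parameter.  x: (iterations, chains, params).

    R-hat = sqrt(((n-1)/n W + B/n) / W); identical chains give
    sqrt((n-1)/n) < 1.
    """
    x = np.asarray(x, dtype=float)
    n, m, P = x.shape
    if m < 2 or n < 2:
        raise ValueError("need >= 2 chains and >= 2 iterations")
    W = x.var(axis=0, ddof=1).mean(axis=0)          # (P,)
    B_over_n = x.mean(axis=0).var(axis=0, ddof=1)   # (P,)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n - 1) / n * W + B_over_n
        return np.sqrt(var_hat / W)


def multivariate_psrf(x: np.ndarray) -> float:
    """Brooks–Gelman multivariate PSRF of one parameter block.

    x: (iterations, chains, params).  sqrt((n-1)/n + (m+1)/m * lambda1)
    with lambda1 the largest eigenvalue of W^{-1} B/n.  Parameters with
    zero within-chain variance are excluded with a warning.
    """
    x = np.asarray(x, dtype=float)
    n, m, P = x.shape
    if m < 2 or n < 2:
        raise ValueError("need >= 2 chains and >= 2 iterations")
    W = np.zeros((P, P))
    for j in range(m):
        W += np.cov(x[:, j, :], rowvar=False).reshape(P, P)
    W /= m
    keep = np.diag(W) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance parameter(s) "
            "from the multivariate PSRF", RuntimeWarning, stacklevel=2)
    if not keep.any():
        return float(np.sqrt((n - 1) / n))
    Wk = W[np.ix_(keep, keep)]
    means = x.mean(axis=0)[:, keep]                  # (m, k)
    Bn = np.cov(means, rowvar=False).reshape(keep.sum(), keep.sum())
    try:
        lam = linalg.eigh(Bn, Wk, eigvals_only=True)[-1]
    except linalg.LinAlgError:
        lam = np.real(np.linalg.eigvals(np.linalg.pinv(Wk) @ Bn)).max()
    lam = max(lam, 0.0)
    return float(np.sqrt((n - 1) / n + (m + 1) / m * lam))


def psrf(posterior: HierarchicalPosterior) -> dict:
    """Full convergence report.

    Univariate R-hat for every participant-level parameter and group
    parameter, the multivariate PSRF per participant, and their median —
    the headline statistic checked against the 1.05 threshold.
    """
    S, D, n_part, P = posterior.theta.shape
    names = posterior.model.param_names
    rows = []
    for i, pid in enumerate(posterior.participants):
        r = gelman_rubin(posterior.theta[:, :, i, :])
        for j in range(P):
            rows.append({"level": "participant", "participant": pid,
                         "parameter": names[j], "rhat": r[j]})
    r_phi = gelman_rubin(posterior.phi)
    for j in range(P):
        rows.append({"level": "hypermean", "participant": "",
                     "parameter": names[j], "rhat": r_phi[j]})
        rows.append({"level": "hypersd", "participant": "",
                     "parameter": names[j], "rhat": r_phi[P + j]})
    per_part = {
        pid: multivariate_psrf(posterior.theta[:, :, i, :])
        for i, pid in enumerate(posterior.participants)
    }
    return {
        "table": pd.DataFrame(rows),
        "mpsrf_per_participant": per_part,
        "median_mpsrf": float(np.median(list(per_part.values()))),
        "threshold": PSRF_THRESHOLD,
        "converged": float(np.median(list(per_part.values()))) < PSRF_THRESHOLD,
    }


def _has_zero_window(counts: np.ndarray, window: int) -> bool:
    """True if any `window` consecutive entries of `counts` are all zero."""
    if len(counts) < window:
        return bool((counts == 0).all()) and len(counts) > 0
    csum = np.concatenate([[0], np.cumsum(counts)])
    return bool((csum[window:] - csum[:-window] == 0).any())


def detect_stuck(posterior: HierarchicalPosterior, window: int | None = None) -> dict:
    """Flag chains that accept no proposal within any sliding window of
    `window` post-burn-in iterations, and report the group-level summary
    with and without the flagged chains."""
    if window is None:
        window = posterior.config.stuck_window
    if window < 2:
        raise ValueError("window must be >= 2")
    acc = posterior.accepted[posterior.config.n_burn:]
    flags = np.array([_has_zero_window(acc[:, d], window)
                      for d in range(acc.shape[1])])
    keep = np.where(~flags)[0]
    report = {
        "flags": flags,
        "n_flagged": int(flags.sum()),
        "summary_all": posterior.group_summary(),
        "summary_excluding": (
            posterior.group_summary(chains=keep) if 0 < len(keep) else None
        ),
    }
    return report
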