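"""Hierarchical model variants, parameter layouts, and prior densities.

Three model variants explain behavioral differences between design cells:

* ``rate_only``      — the effective drift v (stimulus + urgency) varies
                       per cell; the threshold gap B is shared.
* ``threshold_only`` — B varies per cell; v is shared.
* ``both``           — v and B both vary per cell.

A, s_error, t0 and delta_v are always shared across cells.  Each
participant-level parameter has a group-level hypermean and hyperSD; the
group distribution is a normal truncated to the participant-level uniform
prior support (the truncation keeps participant priors proper — see the
methods note).  Hypermeans carry uniform priors and hyperSDs carry
Gamma(shape=1, rate=1) priors, i.e. Exp(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .design import DesignCell
from .lba import LBACellParams, defective_logpdf_arrays, trial_loglik

__all__ = [
    "VARIANTS",
    "PriorSpec",
    "DEFAULT_PRIORS",
    "ModelVariant",
    "build_model",
    "log_prior_participant",
    "log_hyperprior",
    "dataset_loglik",
    "cell_params",
]

#: parameters shared across cells in every variant
SHARED_ALWAYS = ("A", "s_error", "t0", "delta_v")

VARIANTS = {
    "rate_only": ("v_correct",),
    "threshold_only": ("B",),
    "both": ("v_correct", "B"),
}

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Uniform participant-level bounds and hypermean bounds per base
    parameter, plus the (shape, rate) of the gamma hyperSD prior."""

    participant: dict = field(
        default_factory=lambda: {
            "v_correct": (-5.0, 20.0),
            "delta_v": (0.0, 20.0),
            "s_error": (0.1, 10.0),
            "A": (0.01, 20.0),
            "B": (0.01, 20.0),
            "t0": (0.01, 0.5),
        }
    )
    hypermean: dict = field(
        default_factory=lambda: {
            "v_correct": (0.0, 10.0),
            "delta_v": (0.0, 10.0),
            "s_error": (0.1, 5.0),
            "A": (0.01, 10.0),
            "B": (0.01, 10.0),
            "t0": (0.01, 0.5),
        }
    )
    hypersd_gamma: tuple = (1.0, 1.0)  # (shape, rate); shape 1 == Exp(rate)


DEFAULT_PRIORS = PriorSpec()


@dataclass(frozen=True)
class ModelVariant:
    """A variant bound to a concrete cell list: the per-participant
    parameter vector layout and the DE-MCMC chain count it implies."""

    name: str
    cells: tuple  # of DesignCell
    param_names: tuple  # e.g. ("A", ..., "B[Warm:End]")
    base_names: tuple  # base parameter per slot, for prior lookup
    cell_of: tuple  # DesignCell for per-cell slots, None for shared

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_chains(self) -> int:
        """D = 3 x number of participant-level parameters."""
        return 3 * self.n_params

    @property
    def free(self) -> tuple:
        return VARIANTS[self.name]

    def slot(self, base: str, cell: DesignCell | None = None) -> int:
        """Index of a parameter slot in the participant vector."""
        for i, (b, c) in enumerate(zip(self.base_names, self.cell_of)):
            if b == base and (c is None or c == cell):
                return i
        raise KeyError(f"no slot for {base!r} in cell {cell!r}")

    def cell_slots(self, cell: DesignCell) -> dict:
        """Map base parameter name -> vector index, resolved for `cell`
        (shared parameters broadcast to every cell)."""
        return {base: self.slot(base, cell) for base in
                ("A", "B", "v_correct", "delta_v", "s_error", "t0")}

    def to_config(self, priors: PriorSpec = DEFAULT_PRIORS) -> dict:
        """Serializable description of the layout, for run manifests."""
        return {
            "variant": self.name,
            "cells": [c.label for c in self.cells],
            "param_names": list(self.param_names),
            "n_params": self.n_params,
            "n_chains": self.n_chains,
            "priors": {
                "participant": {k: list(v) for k, v in priors.participant.items()},
                "hypermean": {k: list(v) for k, v in priors.hypermean.items()},
                "hypersd_gamma": list(priors.hypersd_gamma),
            },
        }


def build_model(variant: str, cells) -> ModelVariant:
    """Lay out the per-participant parameter vector for a variant.

    Shared slots come first (A, s_error, t0, delta_v, then v_correct when
    it does not vary), followed by one slot per free parameter per cell.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}")
    cells = tuple(DesignCell.parse(c) for c in cells)
    if not cells:
        raise ValueError("cells must be nonempty")
    if len(set(cells)) != len(cells):
        raise ValueError("duplicate cells")
    free = VARIANTS[variant]
    names, bases, cell_of = [], [], []
    for p in SHARED_ALWAYS:
        names.append(p); bases.append(p); cell_of.append(None)
    for p in ("v_correct", "B"):
        if p not in free:
            names.append(p); bases.append(p); cell_of.append(None)
    for p in free:
        for c in cells:
            names.append(f"{p}[{c.label}]"); bases.append(p); cell_of.append(c)
    return ModelVariant(variant, cells, tuple(names), tuple(bases), tuple(cell_of))


def cell_params(model: ModelVariant, theta: np.ndarray, cell) -> LBACellParams:
    """Resolve a participant parameter vector into the LBA parameters of
    one design cell."""
    cell = DesignCell.parse(cell)
    s = model.cell_slots(cell)
    return LBACellParams(
        A=theta[s["A"]],
        B=theta[s["B"]],
        v_correct=theta[s["v_correct"]],
        delta_v=theta[s["delta_v"]],
        s_error=theta[s["s_error"]],
        t0=theta[s["t0"]],
    )


def _participant_bounds(model: ModelVariant, priors: PriorSpec):
    lo = np.array([priors.participant[b][0] for b in model.base_names])
    hi = np.array([priors.participant[b][1] for b in model.base_names])
    return lo, hi


def _hypermean_bounds(model: ModelVariant, priors: PriorSpec):
    lo = np.array([priors.hypermean[b][0] for b in model.base_names])
    hi = np.array([priors.hypermean[b][1] for b in model.base_names])
    return lo, hi


def participant_bounds(model: ModelVariant, priors: PriorSpec = DEFAULT_PRIORS):
    """(lo, hi) arrays of the participant-level uniform supports, one
    entry per parameter slot."""
    return _participant_bounds(model, priors)


def hypermean_bounds(model: ModelVariant, priors: PriorSpec = DEFAULT_PRIORS):
    """(lo, hi) arrays of the hypermean uniform supports per slot."""
    return _hypermean_bounds(model, priors)


def trunc_normal_logpdf(x, mu, sd, lo, hi):
    """Public alias of the truncated-normal log density (broadcasts)."""
    return _trunc_normal_logpdf(x, mu, sd, lo, hi)


def hyperprior_param_logpdf(mu, sd, lo, hi, gamma_shape=1.0, gamma_rate=1.0):
    """Log hyperprior of one (hypermean, hyperSD) pair: uniform on the
    hypermean, Gamma(shape, rate) on the hyperSD.  Vectorized."""
    from scipy.special import gammaln

    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    lp_mu = np.where((mu >= lo) & (mu <= hi), -np.log(hi - lo), -np.inf)
    sd_ok = sd > 0
    sd_safe = np.where(sd_ok, sd, 1.0)
    lp_sd = np.where(
        sd_ok,
        gamma_shape * np.log(gamma_rate) - gammaln(gamma_shape)
        + (gamma_shape - 1.0) * np.log(sd_safe) - gamma_rate * sd_safe,
        -np.inf,
    )
    return lp_mu + lp_sd


def _trunc_normal_logpdf(x, mu, sd, lo, hi):
    """Log density of Normal(mu, sd) truncated to [lo, hi]; -inf outside.

    Complementary forms keep the normalizer accurate when the interval
    sits far into one tail.
    """
    x, mu, sd = np.broadcast_arrays(x, mu, sd)
    x = np.asarray(x, dtype=float)
    ok = (x >= lo) & (x <= hi) & (sd > 0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    a = (lo - mu) / sd_safe
    b = (hi - mu) / sd_safe
    # Phi(b) - Phi(a), evaluated in whichever tail is better conditioned
    z = np.where(a > 0, ndtr(-a) - ndtr(-b), ndtr(b) - ndtr(a))
    z = np.maximum(z, 1e-300)
    lp = (
        -np.log(sd_safe)
        - _LOG_SQRT_2PI
        - 0.5 * np.square((x - mu) / sd_safe)
        - np.log(z)
    )
    return np.where(ok, lp, -np.inf)


def log_prior_participant(theta, phi, model: ModelVariant,
                          priors: PriorSpec = DEFAULT_PRIORS):
    """Log density of participant vector(s) under the group distribution.

    theta: (..., P); phi: (..., 2P) as [hypermeans, hyperSDs].  Each
    coordinate is Normal(hypermean, hyperSD) truncated to the participant
    uniform support; -inf outside.  Broadcasts; sums over the last axis.
    """
    return log_prior_participant_components(theta, phi, model, priors).sum(axis=-1)


def log_prior_participant_components(theta, phi, model: ModelVariant,
                                     priors: PriorSpec = DEFAULT_PRIORS):
    """Per-parameter terms of :func:`log_prior_participant` (no sum over
    the last axis); used by the sampler's per-parameter group blocks."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    P = model.n_params
    mu, sd = phi[..., :P], phi[..., P:]
    lo, hi = _participant_bounds(model, priors)
    return _trunc_normal_logpdf(theta, mu, sd, lo, hi)


def log_hyperprior(phi, model: ModelVariant, priors: PriorSpec = DEFAULT_PRIORS):
    """Log density of the group parameter vector(s).

    Uniform on the hypermeans, Gamma(shape, rate) on the hyperSDs
    (shape 1, rate 1 by default, i.e. Exp(1)); -inf outside support.
    """
    phi = np.asarray(phi, dtype=float)
    P = model.n_params
    mu, sd = phi[..., :P], phi[..., P:]
    lo, hi = _hypermean_bounds(model, priors)
    shape, rate = priors.hypersd_gamma
    from scipy.special import gammaln

    mu_ok = (mu >= lo) & (mu <= hi)
    lp_mu = np.where(mu_ok, -np.log(hi - lo), -np.inf)
    sd_ok = sd > 0
    sd_safe = np.where(sd_ok, sd, 1.0)
    lp_sd = np.where(
        sd_ok,
        shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(sd_safe)
        - rate * sd_safe,
        -np.inf,
    )
    return lp_mu.sum(axis=-1) + lp_sd.sum(axis=-1)


def sample_participant_prior(model: ModelVariant, rng: np.random.Generator,
                             priors: PriorSpec = DEFAULT_PRIORS,
                             size=()) -> np.ndarray:
    """Draw participant vectors from the flat participant-level priors."""
    lo, hi = _participant_bounds(model, priors)
    return rng.uniform(lo, hi, size=tuple(np.atleast_1d(size)) + (model.n_params,)) \
        if size else rng.uniform(lo, hi)


def sample_group_prior(model: ModelVariant, rng: np.random.Generator,
                       priors: PriorSpec = DEFAULT_PRIORS) -> np.ndarray:
    """Draw a group vector [hypermeans, hyperSDs] from the hyperpriors."""
    lo, hi = _hypermean_bounds(model, priors)
    shape, rate = priors.hypersd_gamma
    mu = rng.uniform(lo, hi)
    sd = rng.gamma(shape, 1.0 / rate, size=model.n_params)
    return np.concatenate([mu, sd])


def dataset_loglik(trials: pd.DataFrame, theta_all: dict,
                   model: ModelVariant) -> float:
    """Summed trial log-likelihood of a choice-trial table.

    `trials` needs columns participant_id, condition, moment, rt_s,
    response.  `theta_all` maps participant_id -> parameter vector.
    Empty table -> 0.  A participant present in the data but absent from
    theta_all is an error.
    """
    if len(trials) == 0:
        return 0.0
    missing = set(trials["participant_id"]) - set(theta_all)
    if missing:
        raise KeyError(f"no parameters for participants {sorted(missing)}")
    known = {c.label for c in model.cells}
    total = 0.0
    for (pid, cond, mom), grp in trials.groupby(
        ["participant_id", "condition", "moment"], observed=True
    ):
        cell = DesignCell(cond, mom)
        if cell.label not in known:
            raise KeyError(f"cell {cell.label} not covered by the model layout")
        theta = np.asarray(theta_all[pid], dtype=float)
        p = cell_params(model, theta, cell)
        v_t, v_f = p.effective_drifts()
        s_t, s_f = p.drift_sds()
        ll = defective_logpdf_arrays(
            grp["rt_s"].to_numpy(dtype=float),
            grp["response"].to_numpy() == "target",
            p.A, p.b, v_t, v_f, s_t, s_f, p.t0,
        )
        total += float(ll.sum())
    return total


def dataset_loglik_loop(trials: pd.DataFrame, theta_all: dict,
                        model: ModelVariant) -> float:
    """Naive per-trial loop; reference implementation for testing."""
    total = 0.0
    for row in trials.itertuples(index=False):
        cell = DesignCell(row.condition, row.moment)
        p = cell_params(model, np.asarray(theta_all[row.participant_id]), cell)
        total += trial_loglik(row.rt_s, row.response, p)
    return total
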