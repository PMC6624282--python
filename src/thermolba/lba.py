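"""Linear Ballistic Accumulator (LBA) kernel.

Each response option is an independent accumulator that rises linearly
from a start point drawn uniformly on [0, A] toward a fixed threshold
b = A + B.  The rise rate (drift) is drawn once per trial from a normal
distribution; the first accumulator to reach b determines the response,
and the crossing time plus a non-decision time t0 gives the RT.  Within a
trial the rise is deterministic — all variability is across trials.

The parametrization follows the difference convention used for fitting:
the drift of the error accumulator is v_correct - delta_v and is never
stored separately, the threshold is expressed through the gap B = b - A,
and the drift SD of the correct accumulator is fixed at 1 as the scaling
constraint.  An optional additive urgency term u shifts the drift of
*every* accumulator; for a ballistic accumulator this is exactly
equivalent to a threshold that collapses linearly at rate u (see
:func:`collapse_equivalent`).

All densities here are *defective*: the density of responding with a
particular option at a particular RT, unnormalized by the probability
that any accumulator has a positive drift.  At the parameter ranges
relevant for fitting, the all-negative-drift mass is negligible;
:func:`prob_no_response` reports it as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate
from scipy.special import ndtr  # fast standard-normal CDF

__all__ = [
    "LBACellParams",
    "accumulator_cdf",
    "accumulator_pdf",
    "defective_pdf",
    "defective_logpdf_arrays",
    "choice_prob",
    "prob_no_response",
    "trial_loglik",
    "collapse_equivalent",
    "sample_lba",
    "sample_lba_collapsing",
]

#: densities are floored at this value before taking logs
DENSITY_FLOOR = 1e-300

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _npdf(z):
    return np.exp(-0.5 * np.square(z)) / _SQRT_2PI


@dataclass(frozen=True)
class LBACellParams:
    """LBA parameters for one design cell.

    A          : start-point range (start ~ U[0, A]), evidence units, > 0
    B          : threshold gap b - A, evidence units, > 0
    v_correct  : mean drift of the accumulator matching the stimulus
    delta_v    : drift difference v_correct - v_error, >= 0
    s_error    : drift SD of the error accumulator, > 0
    t0         : non-decision time, seconds, > 0
    urgency    : additive drift component shared by both accumulators
                 (default 0); kept explicit only so the collapsing-bound
                 equivalence can be exercised — it is not identifiable
                 separately from the stimulus drift.

    s_correct is fixed at 1 (the scaling constraint).
    """

    A: float
    B: float
    v_correct: float
    delta_v: float
    s_error: float
    t0: float
    urgency: float = 0.0

    s_correct: float = 1.0  # scaling constraint; do not override in fits

    def __post_init__(self) -> None:
        for name in ("A", "B", "s_error", "t0"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be finite and > 0")
        if not np.isfinite(self.v_correct):
            raise ValueError("v_correct must be finite")
        if self.delta_v < 0 or not np.isfinite(self.delta_v):
            raise ValueError("delta_v must be finite and >= 0")
        if self.s_correct <= 0:
            raise ValueError("s_correct must be > 0")

    @property
    def b(self) -> float:
        """Response threshold b = A + B."""
        return self.A + self.B

    @property
    def v_error(self) -> float:
        return self.v_correct - self.delta_v

    def effective_drifts(self) -> tuple[float, float]:
        """(target, foil) mean drifts including the urgency component."""
        return (self.v_correct + self.urgency, self.v_error + self.urgency)

    def drift_sds(self) -> tuple[float, float]:
        return (self.s_correct, self.s_error)


def accumulator_cdf(t, A, b, v, s):
    """P(single accumulator has crossed b by accumulation time t).

    Start point ~ U[0, A], drift ~ Normal(v, s).  Nondecreasing in t and
    in v; the t -> inf limit is Phi(v / s) (non-positive drifts never
    cross).  t <= 0 gives 0.  Vectorized over every argument.
    """
    t = np.asarray(t, dtype=float)
    A, b, v, s = (np.asarray(x, dtype=float) for x in (A, b, v, s))
    if np.any(A <= 0) or np.any(s <= 0) or np.any(b < A):
        raise ValueError("require A > 0, s > 0, b >= A")
    ts = np.where(t > 0, t, 1.0) * s
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    out = (
        1.0
        + ((b - A - t * v) * ndtr(z1) - (b - t * v) * ndtr(z2)) / A
        + ts * (_npdf(z1) - _npdf(z2)) / A
    )
    out = np.clip(out, 0.0, 1.0)
    return np.where(t > 0, out, 0.0)


def accumulator_pdf(t, A, b, v, s):
    """Density of the crossing time of a single accumulator.

    Nonnegative; integrates over (0, inf) to Phi(v / s).
    """
    t = np.asarray(t, dtype=float)
    A, b, v, s = (np.asarray(x, dtype=float) for x in (A, b, v, s))
    if np.any(A <= 0) or np.any(s <= 0) or np.any(b < A):
        raise ValueError("require A > 0, s > 0, b >= A")
    ts = np.where(t > 0, t, 1.0) * s
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    out = (-v * ndtr(z1) + s * _npdf(z1) + v * ndtr(z2) - s * _npdf(z2)) / A
    out = np.maximum(out, 0.0)
    return np.where(t > 0, out, 0.0)


def _resolve_accumulators(params: LBACellParams):
    """((v_t, s_t), (v_f, s_f), b) with urgency folded into the drifts."""
    v_t, v_f = params.effective_drifts()
    s_t, s_f = params.drift_sds()
    return (v_t, s_t), (v_f, s_f), params.b


def defective_pdf(rt_s, response: str, params: LBACellParams):
    """Density of responding `response` ('target' or 'foil') at RT rt_s.

    winner pdf x (1 - loser CDF) at accumulation time rt_s - t0;
    zero for rt_s <= t0.  Unnormalized (see module docstring).
    """
    (v_t, s_t), (v_f, s_f), b = _resolve_accumulators(params)
    if response == "target":
        (v_w, s_w), (v_l, s_l) = (v_t, s_t), (v_f, s_f)
    elif response == "foil":
        (v_w, s_w), (v_l, s_l) = (v_f, s_f), (v_t, s_t)
    else:
        raise ValueError(f"unknown response label {response!r}")
    tau = np.asarray(rt_s, dtype=float) - params.t0
    win = accumulator_pdf(tau, params.A, b, v_w, s_w)
    lose = accumulator_cdf(tau, params.A, b, v_l, s_l)
    return win * (1.0 - lose)


def defective_logpdf_arrays(rt, is_target, A, b, v_t, v_f, s_t, s_f, t0):
    """Vectorized log defective density for arrays of trials and parameters.

    `rt` and boolean `is_target` broadcast against the parameter arrays
    (the fitting code passes parameters shaped (chains, 1) against trials
    shaped (n,)).  Returns -inf where rt <= t0, else log of the floored
    defective density.
    """
    tau = np.asarray(rt, dtype=float) - t0
    ok = tau > 0
    tau_safe = np.where(ok, tau, 1.0)
    f_t = accumulator_pdf(tau_safe, A, b, v_t, s_t)
    F_t = accumulator_cdf(tau_safe, A, b, v_t, s_t)
    f_f = accumulator_pdf(tau_safe, A, b, v_f, s_f)
    F_f = accumulator_cdf(tau_safe, A, b, v_f, s_f)
    dens = np.where(is_target, f_t * (1.0 - F_f), f_f * (1.0 - F_t))
    out = np.log(np.maximum(dens, DENSITY_FLOOR))
    return np.where(ok, out, -np.inf)


def trial_loglik(rt_s: float, response: str, params: LBACellParams) -> float:
    """Log defective density of one trial; -inf when rt_s <= t0."""
    if rt_s <= params.t0:
        return -np.inf
    dens = float(defective_pdf(rt_s, response, params))
    return float(np.log(max(dens, DENSITY_FLOOR)))


def prob_no_response(params: LBACellParams) -> float:
    """P(both drifts drawn non-positive): the mass the defective densities
    leave unaccounted for.  Diagnostic; negligible at fitted ranges."""
    (v_t, s_t), (v_f, s_f), _ = _resolve_accumulators(params)
    return float(ndtr(-v_t / s_t) * ndtr(-v_f / s_f))


def choice_prob(params: LBACellParams) -> float:
    """Probability of a correct (target) response.

    Integral of the target defective density over (0, inf), divided by the
    total response mass 1 - P(no response); in [0, 1] and nondecreasing in
    delta_v.  The crossing-time density has a slowly decaying tail (mass
    from near-zero drifts ~ 1/tau^2), so the quadrature is split at a
    bulk scale and run to infinity.
    """
    (v_t, s_t), (v_f, s_f), b = _resolve_accumulators(params)

    def integrand(tau):
        return accumulator_pdf(tau, params.A, b, v_t, s_t) * (
            1.0 - accumulator_cdf(tau, params.A, b, v_f, s_f)
        )

    # bulk scale: typical crossing time of the slower accumulator
    v_slow = max(min(v_t / s_t, v_f / s_f), 0.1)
    T = 20.0 * b / v_slow
    m1, _ = integrate.quad(integrand, 0.0, T, limit=300)
    m2, _ = integrate.quad(integrand, T, np.inf, limit=300)
    total = 1.0 - prob_no_response(params)
    return float(np.clip((m1 + m2) / total, 0.0, 1.0))


def collapse_equivalent(params: LBACellParams):
    """Map the additive-urgency form onto the collapsing-threshold form.

    Adding u to every drift under a fixed threshold b produces exactly the
    same crossing times as leaving the drifts alone and letting the
    threshold decrease linearly, b(tau) = b - u * tau: for a shared start
    and drift draw, start + (drift + u) * tau = b and
    start + drift * tau = b - u * tau have the same solution
    tau = (b - start) / (drift + u).

    Returns (static_params, slope): the drift-shifted static-bound
    parametrization (urgency folded into v_correct, urgency slot zeroed)
    and the slope u of the equivalent linearly collapsing threshold.
    """
    u = params.urgency
    static = replace(params, v_correct=params.v_correct + u, urgency=0.0)
    return static, u


def _draw_trial_randomness(params: LBACellParams, n: int, rng: np.random.Generator):
    """Shared start-point and *stimulus*-drift draws for both model forms.

    Draws are made before any urgency is applied, so the static-bound and
    collapsing-bound forms can consume identical randomness.  Trials on
    which both effective drifts (stimulus + urgency) are non-positive are
    redrawn (the conditional-on-response convention used throughout); the
    redraw count is returned as a diagnostic.
    """
    v_t, v_f = params.v_correct, params.v_error
    s_t, s_f = params.drift_sds()
    u = params.urgency
    starts = rng.uniform(0.0, params.A, size=(n, 2))
    drifts = np.column_stack(
        [rng.normal(v_t, s_t, size=n), rng.normal(v_f, s_f, size=n)]
    )
    n_redrawn = 0
    bad = (drifts + u <= 0).all(axis=1)
    while bad.any():
        k = int(bad.sum())
        n_redrawn += k
        drifts[bad, 0] = rng.normal(v_t, s_t, size=k)
        drifts[bad, 1] = rng.normal(v_f, s_f, size=k)
        bad = (drifts + u <= 0).all(axis=1)
    return starts, drifts, n_redrawn


def sample_lba(params: LBACellParams, n: int, rng: np.random.Generator):
    """Simulate n trials. Returns (rt_s, is_target, n_redrawn).

    Static-bound form: urgency is added to the drawn stimulus drifts and
    the race runs against the fixed threshold b.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    starts, drifts, n_redrawn = _draw_trial_randomness(params, n, rng)
    effective = drifts + params.urgency
    with np.errstate(divide="ignore"):
        times = np.where(effective > 0, (params.b - starts) / effective, np.inf)
    winner = np.argmin(times, axis=1)
    rt = params.t0 + times[np.arange(len(winner)), winner]
    return rt, winner == 0, n_redrawn


def sample_lba_collapsing(params: LBACellParams, n: int, rng: np.random.Generator):
    """Simulate n trials under the linearly-collapsing-threshold form.

    The drifts stay at their stimulus values and the threshold decreases
    as b(tau) = b - u * tau; each accumulator crosses when
    start + drift * tau = b - u * tau.  With the same rng state as
    :func:`sample_lba` the start/drift draws are shared, so the two forms
    produce identical RT and response vectors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    starts, drifts, n_redrawn = _draw_trial_randomness(params, n, rng)
    u = params.urgency
    denom = drifts + u  # solving start + drift*tau = b - u*tau
    with np.errstate(divide="ignore"):
        times = np.where(denom > 0, (params.b - starts) / denom, np.inf)
    winner = np.argmin(times, axis=1)
    rt = params.t0 + times[np.arange(len(winner)), winner]
    return rt, winner == 0, n_redrawn
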