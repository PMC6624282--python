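"""LBA kernel: closed forms against brute-force and quadrature oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.special import ndtr

from thermolba.lba import (
    LBACellParams,
    accumulator_cdf,
    accumulator_pdf,
    choice_prob,
    collapse_equivalent,
    defective_pdf,
    prob_no_response,
    sample_lba,
    sample_lba_collapsing,
    trial_loglik,
)

from helpers import KERNEL_PARAM_SETS


def mc_crossing_prob(t, A, b, v, s, n, rng):
    """Brute-force oracle: P(start + drift * t >= b) for start ~ U[0, A],
    drift ~ N(v, s), crossing only possible for positive drift."""
    start = rng.uniform(0, A, n)
    drift = rng.normal(v, s, n)
    crossed = (drift > 0) & ((b - start) / np.where(drift > 0, drift, 1.0) <= t)
    p = crossed.mean()
    se = np.sqrt(max(p * (1 - p), 1e-12) / n)
    return p, se


class TestAccumulatorCDF:
    def test_zero_before_accumulation_starts(self):
        assert accumulator_cdf(0.0, 0.5, 1.0, 2.0, 1.0) == 0.0
        assert accumulator_cdf(-1.0, 0.5, 1.0, 2.0, 1.0) == 0.0

    def test_infinite_time_limit_is_positive_drift_mass(self):
        # drifts <= 0 never cross, so the limit is Phi(v / s)
        assert accumulator_cdf(1e9, 0.5, 1.0, 2.0, 1.0) == pytest.approx(
            ndtr(2.0), abs=1e-6)

    def test_matches_monte_carlo_oracle(self, rng):
        t, A, b, v, s = 1.0, 0.5, 1.0, 2.0, 1.0
        p, se = mc_crossing_prob(t, A, b, v, s, 10**6, rng)
        assert abs(float(accumulator_cdf(t, A, b, v, s)) - p) < 3 * se

    def test_nondecreasing_in_t_and_v(self):
        ts = np.linspace(0.01, 5, 100)
        vals = accumulator_cdf(ts, 0.5, 1.0, 1.5, 1.0)
        assert (np.diff(vals) >= -1e-12).all()
        vs = np.linspace(-2, 5, 50)
        vals_v = accumulator_cdf(1.0, 0.5, 1.0, vs, 1.0)
        assert (np.diff(vals_v) >= -1e-12).all()

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            accumulator_cdf(1.0, -0.5, 1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            accumulator_cdf(1.0, 0.5, 1.0, 2.0, 0.0)


class TestAccumulatorPDF:
    def test_zero_for_nonpositive_time(self):
        assert accumulator_pdf(0.0, 0.5, 1.0, 2.0, 1.0) == 0.0
        assert accumulator_pdf(-0.5, 0.5, 1.0, 2.0, 1.0) == 0.0

    @pytest.mark.parametrize("t", [0.3, 0.7, 1.0, 2.5])
    def test_matches_cdf_derivative(self, t):
        h = 1e-6
        fd = (accumulator_cdf(t + h, 0.5, 1.0, 2.0, 1.0)
              - accumulator_cdf(t - h, 0.5, 1.0, 2.0, 1.0)) / (2 * h)
        pdf = float(accumulator_pdf(t, 0.5, 1.0, 2.0, 1.0))
        assert pdf == pytest.approx(float(fd), rel=1e-6)

    def test_total_mass_is_positive_drift_probability(self):
        # crossing-time tail decays ~ 1/t^2, integrate to infinity in parts
        m1, _ = integrate.quad(
            lambda t: float(accumulator_pdf(t, 0.5, 1.0, 2.0, 1.0)), 0, 50,
            limit=200)
        m2, _ = integrate.quad(
            lambda t: float(accumulator_pdf(t, 0.5, 1.0, 2.0, 1.0)), 50,
            np.inf, limit=200)
        assert m1 + m2 == pytest.approx(ndtr(2.0), abs=1e-8)


class TestDefectivePDF:
    def test_zero_at_or_below_t0(self, typical_params):
        assert defective_pdf(typical_params.t0, "target", typical_params) == 0.0
        assert defective_pdf(0.05, "foil", typical_params) == 0.0

    def test_symmetry_at_equal_drifts(self):
        p = LBACellParams(A=0.5, B=0.5, v_correct=2.0, delta_v=0.0,
                          s_error=1.0, t0=0.2)
        ts = np.linspace(0.25, 3.0, 40)
        t_dens = defective_pdf(ts, "target", p)
        f_dens = defective_pdf(ts, "foil", p)
        np.testing.assert_allclose(t_dens, f_dens, rtol=1e-12)

    def test_unknown_response_label(self, typical_params):
        with pytest.raises(ValueError):
            defective_pdf(0.5, "banana", typical_params)

    @pytest.mark.parametrize("params", KERNEL_PARAM_SETS)
    def test_mass_conservation(self, params):
        """target mass + foil mass + P(both drifts <= 0) = 1."""
        def total(tau):
            return float(defective_pdf(tau + params.t0, "target", params)
                         + defective_pdf(tau + params.t0, "foil", params))

        split = 20.0 * params.b / max(min(
            params.v_correct, params.v_error + params.urgency), 0.1)
        m1, _ = integrate.quad(total, 0, split, limit=300)
        m2, _ = integrate.quad(total, split, np.inf, limit=300)
        assert m1 + m2 + prob_no_response(params) == pytest.approx(1.0, abs=1e-6)


class TestChoiceProb:
    def test_equal_drifts_equal_noise_gives_half(self):
        p = LBACellParams(A=0.5, B=0.5, v_correct=2.0, delta_v=0.0,
                          s_error=1.0, t0=0.2)
        assert choice_prob(p) == pytest.approx(0.5, abs=1e-9)

    def test_dominance_limit(self):
        p = LBACellParams(A=0.5, B=0.5, v_correct=21.0, delta_v=20.0,
                          s_error=1.0, t0=0.2)
        assert choice_prob(p) >= 0.999

    def test_nondecreasing_in_delta_v(self):
        probs = [
            choice_prob(LBACellParams(A=0.5, B=0.5, v_correct=2.0 + dv,
                                      delta_v=dv, s_error=1.0, t0=0.2))
            for dv in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(probs, probs[1:]))

    def test_matches_simulated_accuracy(self, rng):
        p = LBACellParams(A=0.5, B=0.5, v_correct=3.0, delta_v=2.0,
                          s_error=1.0, t0=0.2)
        _, is_target, _ = sample_lba(p, 10**5, rng)
        acc = is_target.mean()
        se = np.sqrt(acc * (1 - acc) / 10**5)
        assert abs(choice_prob(p) - acc) < 3 * se

    def test_invariant_to_common_rescaling(self):
        """Rescaling A, B, drifts and drift SDs together leaves choice
        probability unchanged — the degeneracy motivating s_correct = 1."""
        base = dict(A=0.5, B=0.5, v_correct=2.5, delta_v=1.5, s_error=0.7,
                    t0=0.2)
        p1 = LBACellParams(**base)
        for c in (0.5, 2.0, 3.7):
            p2 = LBACellParams(A=c * base["A"], B=c * base["B"],
                               v_correct=c * base["v_correct"],
                               delta_v=c * base["delta_v"],
                               s_error=c * base["s_error"], t0=base["t0"],
                               s_correct=c)
            assert choice_prob(p2) == pytest.approx(choice_prob(p1), abs=1e-7)


class TestTrialLoglik:
    def test_minus_inf_at_or_below_t0(self, typical_params):
        assert trial_loglik(typical_params.t0, "target", typical_params) == -np.inf
        assert trial_loglik(0.01, "foil", typical_params) == -np.inf

    def test_equals_log_defective_pdf(self, typical_params):
        rt = 0.6
        assert trial_loglik(rt, "target", typical_params) == pytest.approx(
            float(np.log(defective_pdf(rt, "target", typical_params))))

    def test_concentrates_at_true_parameters(self, rng):
        """Summed log-likelihood at the generating parameters beats almost
        every random perturbation at large n."""
        p = LBACellParams(A=0.5, B=0.7, v_correct=2.5, delta_v=1.0,
                          s_error=0.8, t0=0.2)
        rt, is_t, _ = sample_lba(p, 4000, rng)
        resp = np.where(is_t, "target", "foil")

        def total(params):
            return sum(trial_loglik(r, s, params) for r, s in zip(rt, resp))

        ll_true = total(p)
        wins = 0
        n_dir = 40
        for _ in range(n_dir):
            eps = rng.normal(0, 0.12, size=6)
            q = LBACellParams(
                A=max(p.A + eps[0], 0.01), B=max(p.B + eps[1], 0.01),
                v_correct=p.v_correct + eps[2],
                delta_v=max(p.delta_v + eps[3], 0.0),
                s_error=max(p.s_error + eps[4], 0.1),
                t0=min(max(p.t0 + eps[5], 0.01), float(rt.min()) - 1e-6),
            )
            wins += ll_true >= total(q)
        assert wins >= 0.95 * n_dir


class TestCollapsingBoundEquivalence:
    def test_zero_urgency_is_identity(self, typical_params):
        static, slope = collapse_equivalent(typical_params)
        assert slope == 0.0
        assert static == typical_params

    @given(start=st.floats(0.0, 0.5), drift=st.floats(-1.0, 4.0),
           u=st.floats(0.0, 2.0))
    @settings(deadline=None, max_examples=200)
    def test_algebraic_identity(self, start, drift, u):
        """(b - start) / (drift + u) solves start + drift*t = b - u*t."""
        b = 1.0
        if drift + u <= 1e-9:
            return
        tau = (b - start) / (drift + u)
        assert start + drift * tau == pytest.approx(b - u * tau, abs=1e-9)

    def test_shared_randomness_simulation_identical(self):
        p = LBACellParams(A=0.5, B=0.5, v_correct=2.0, delta_v=1.0,
                          s_error=1.0, t0=0.2, urgency=0.8)
        rt1, resp1, _ = sample_lba(p, 10**5, np.random.default_rng(42))
        rt2, resp2, _ = sample_lba_collapsing(p, 10**5,
                                              np.random.default_rng(42))
        assert np.array_equal(rt1, rt2)
        assert np.array_equal(resp1, resp2)

    def test_static_form_reproduces_urgency_densities(self):
        p = LBACellParams(A=0.4, B=0.6, v_correct=1.5, delta_v=0.5,
                          s_error=0.9, t0=0.15, urgency=0.6)
        static, slope = collapse_equivalent(p)
        assert slope == 0.6
        ts = np.linspace(0.2, 2.0, 25)
        np.testing.assert_allclose(
            defective_pdf(ts, "target", p),
            defective_pdf(ts, "target", static), rtol=1e-12)


@pytest.mark.parametrize("params", KERNEL_PARAM_SETS[:3])
def test_simulation_matches_analytic_conditional_cdf(params, rng):
    """KS distance between simulated RTs (per response) and the analytic
    conditional CDF stays below 0.01 at 1e5 trials."""
    n = 10**5
    rt, is_t, _ = sample_lba(params, n, rng)
    (v_t, s_t), (v_f, s_f) = (
        (params.v_correct + params.urgency, params.s_correct),
        (params.v_error + params.urgency, params.s_error),
    )

    def total_density(x):
        return float(
            accumulator_pdf(x, params.A, params.b, v_t, s_t)
            * (1 - accumulator_cdf(x, params.A, params.b, v_f, s_f))
            + accumulator_pdf(x, params.A, params.b, v_f, s_f)
            * (1 - accumulator_cdf(x, params.A, params.b, v_t, s_t)))

    sub = np.sort(rt - params.t0)
    split = float(sub[-1])
    m1, _ = integrate.quad(total_density, 0, split, limit=300)
    m2, _ = integrate.quad(total_density, split, np.inf, limit=300)
    mass = m1 + m2
    grid_idx = np.linspace(0, n - 1, 200).astype(int)
    taus = sub[grid_idx]
    cum = np.empty(len(taus))
    prev_t, prev_m = 0.0, 0.0
    for i, T in enumerate(taus):
        m, _ = integrate.quad(total_density, prev_t, T, limit=200)
        prev_m += m
        prev_t = float(T)
        cum[i] = prev_m
    analytic = cum / mass
    empirical = (grid_idx + 1) / n
    ks = np.max(np.abs(analytic - empirical))
    assert ks < 0.01
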