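"""Sequential-sampling Bayesian ICA: probabilities, sampler, gradient, learning."""

import itertools

import numpy as np
import pytest

from corrspike import params, stimuli
from corrspike.bayes_ica import (
    ICAState,
    ltp_ltd_curve,
    phi_weights,
    posterior_over_states,
    run_learning,
    sample_discrete_stream,
    sample_step,
    spike_prob,
    update_qtilde,
)


def make_state(L=4, p=2, q=0.0, r_o_hz=4.0, seed=0, eta=0.001):
    rng = np.random.default_rng(seed)
    Qt = np.full((L, p), q) if np.isscalar(q) else np.asarray(q)
    return ICAState(Qt=Qt, r_o=np.full(L, r_o_hz / 1000.0), eta=eta)


class TestPhiWeights:
    def test_unit_mass_and_peak(self):
        phi = phi_weights(theta_t=2.0, dt_bin=5.0)
        # midpoint-rule weights approximate unit mass (the coarse 5 ms bins
        # overweight the kernel peak by a few percent)
        assert abs(phi.sum() - 1.0) < 0.1
        # and converge to unit mass as the bins shrink
        assert abs(phi_weights(theta_t=2.0, dt_bin=0.1).sum() - 1.0) < 1e-4
        # kernel mode at 2*theta = 4 ms lies in the first 5 ms bin
        assert np.argmax(phi) == 0
        phi2 = phi_weights(theta_t=6.0, dt_bin=5.0)
        # mode at 12 ms -> third bin (midpoint 12.5)
        assert np.argmax(phi2) == 2


class TestSpikeProb:
    def test_silent_history_no_baseline(self):
        st = make_state(q=0.6, r_o_hz=0.0)
        y = np.zeros((2, 10))
        assert np.allclose(spike_prob(st, y), 0.0)

    def test_zero_qtilde_gives_baseline(self):
        st = make_state(q=0.0, r_o_hz=4.0)
        y = np.ones((2, 10))
        assert np.allclose(spike_prob(st, y), st.r_o * st.dt_bin)

    def test_single_event_one_bin_ago(self):
        st = make_state(q=0.6, r_o_hz=4.0)
        y = np.zeros((2, 10))
        y[0, 1] = 1.0
        phi = st.phi
        expect = 1 - (1 - st.r_o[0] * st.dt_bin) * (1 - 0.6 * phi[1])
        assert np.allclose(spike_prob(st, y)[:], expect)


class TestSampler:
    def test_posterior_normalized(self):
        st = make_state(L=6, p=3, q=0.4, seed=1)
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 6)
        probs = posterior_over_states(st, x, np.zeros(3))
        assert probs.shape == (8,)
        assert np.isclose(probs.sum(), 1.0, atol=1e-12)

    def test_zero_qtilde_recovers_prior(self):
        st = make_state(L=4, p=2, q=0.0)
        probs = posterior_over_states(st, np.array([1, 0, 1, 0]), np.zeros(2))
        rs = st.r_s_bin
        prior = np.array([(rs if (s >> mu) & 1 else 1 - rs)
                          for s in range(4) for mu in range(2)]).reshape(4, 2)
        assert np.allclose(probs, prior.prod(axis=1), atol=1e-12)

    @pytest.mark.parametrize("p", [1, 2, 3])
    def test_matches_exhaustive_enumeration(self, p):
        # independent brute-force evaluation of the unnormalized posterior
        rng = np.random.default_rng(3 + p)
        L = 5
        Qt = rng.uniform(0.1, 0.7, (L, p))
        st = make_state(L=L, p=p, q=Qt, r_o_hz=4.0)
        x = rng.integers(0, 2, L)
        a_prev = rng.uniform(0, 0.3, p)
        probs = posterior_over_states(st, x, a_prev)
        brute = np.zeros(2**p)
        rs = st.r_s_bin
        for s_idx in range(2**p):
            bits = [(s_idx >> mu) & 1 for mu in range(p)]
            w = 1.0
            for i in range(L):
                pik = 1.0
                for mu in range(p):
                    pik *= 1 - Qt[i, mu] * (a_prev[mu] + st.phi[0] * bits[mu])
                pik = 1 - (1 - st.r_o[i] * st.dt_bin) * pik
                w *= pik if x[i] else (1 - pik)
            for mu in range(p):
                w *= rs if bits[mu] else (1 - rs)
            brute[s_idx] = w
        assert np.allclose(probs, brute / brute.sum(), atol=1e-12)

    def test_single_source_silent_input(self):
        # p = 1, silent input, tiny prior: P[y=1] from 2-state enumeration
        st = make_state(L=3, p=1, q=0.5, r_o_hz=2.0)
        x = np.zeros(3)
        probs = posterior_over_states(st, x, np.zeros(1))
        rs = st.r_s_bin
        p0 = (1 - rs) * np.prod([(1 - st.r_o[i] * st.dt_bin) for i in range(3)])
        p1 = rs * np.prod([(1 - st.r_o[i] * st.dt_bin) * (1 - 0.5 * st.phi[0])
                           for i in range(3)])
        assert np.isclose(probs[1], p1 / (p0 + p1), atol=1e-12)

    def test_sample_step_draws_from_posterior(self):
        st = make_state(L=4, p=2, q=0.5, seed=4)
        rng = np.random.default_rng(5)
        x = np.array([1, 1, 0, 0])
        draws = np.zeros(4)
        n = 4000
        for _ in range(n):
            y, probs = sample_step(st, x, np.zeros(2), rng)
            draws[int(y[0]) + 2 * int(y[1])] += 1
        assert np.max(np.abs(draws / n - probs)) < 4 * np.sqrt(0.25 / n)


class TestGradient:
    def test_signs(self):
        st = make_state(L=2, p=1, q=0.3, r_o_hz=4.0)
        y = np.zeros((1, 10))
        y[0, 1] = 1.0
        d = update_qtilde(st, np.array([1, 0]), y)
        assert d[0, 0] > 0   # input spike + recent sampled event -> LTP
        assert d[1, 0] < 0   # silent input + recent sampled event -> LTD

    def test_no_recent_events_no_update(self):
        st = make_state(L=2, p=1, q=0.3)
        d = update_qtilde(st, np.array([1, 0]), np.zeros((1, 10)))
        assert np.allclose(d, 0.0)


class TestLtpLtdCurve:
    def test_ltp_peaks_at_kernel_mode(self):
        st = make_state(L=2, p=1, q=0.0)
        lags, ltp, ltd = ltp_ltd_curve(st, q_values=(0.1, 0.3, 0.5))
        assert np.argmax(ltp[0]) == np.argmax(st.phi)

    def test_ltd_total_at_zero_weight(self):
        st = make_state(L=2, p=1)
        _, _, ltd = ltp_ltd_curve(st, q_values=(0.0,))
        assert np.isclose(ltd[0], -st.phi.sum(), rtol=1e-12)

    def test_ltd_magnitude_grows_with_weight(self):
        st = make_state(L=2, p=1)
        _, _, ltd = ltp_ltd_curve(st, q_values=(0.1, 0.3, 0.5))
        assert -ltd[0] < -ltd[1] < -ltd[2]


class TestLearning:
    def test_zero_sources_drifts_down(self):
        # pure background spikes: estimated responses shrink toward 0
        rng = np.random.default_rng(6)
        L, K = 6, 40000
        X = (rng.random((L, K)) < 0.05).astype(np.uint8)
        st = ICAState(Qt=np.full((L, 1), 0.4), r_o=np.full(L, 0.01),
                      eta=0.005)
        res = run_learning(st, X, mode="sampled", seed=7)
        assert res.Qt.mean() < 0.15

    def test_logposterior_trend_nondecreasing(self, ica_recovery_runs):
        # per-bin log-posterior of the sampled trajectory improves on
        # average while the estimate converges
        lp = ica_recovery_runs[0]["result"].logpost_trace
        n = len(lp)
        early, late = lp[: n // 4].mean(), lp[-n // 4:].mean()
        assert late > early

    def test_recovery_within_tolerance(self, ica_recovery_runs):
        errs = sorted(r["max_abs_err"] for r in ica_recovery_runs)
        assert errs[len(errs) // 2] < 0.1  # median of 5 seeds

    def test_conditioning_variants_both_learn(self):
        # the update's p_i^k may condition on the current sample or only on
        # the past history; both variants must learn the same structure
        rm = stimuli.build_Q("crosstalk", L=20, L_a=10, q_S=0.6, q_N=0.0)
        K = int(400e3 / 5.0)
        S, X = sample_discrete_stream(rm.Q, rm.r_o, K, seed=12)
        outcomes = {}
        for cond in (True, False):
            rng = np.random.default_rng(3)
            st = ICAState(Qt=rng.uniform(0.05, 0.25, rm.Q.shape),
                          r_o=rm.r_o, condition_on_current=cond)
            res = run_learning(st, X, mode="sampled", seed=13)
            err = min(float(np.abs(res.Qt[:, perm] - rm.Q).max())
                      for perm in itertools.permutations(range(2)))
            outcomes[cond] = err
        assert outcomes[True] < 0.25
        assert outcomes[False] < 0.25

    def test_too_many_sources_rejected(self):
        with pytest.raises(ValueError):
            ICAState(Qt=np.zeros((4, 13)), r_o=np.zeros(4))


def test_matched_stream_statistics():
    rm = stimuli.build_Q("crosstalk", L=20, L_a=10, q_S=0.6, q_N=0.0)
    S, X = sample_discrete_stream(rm.Q, rm.r_o, K=200000, seed=9)
    # source rate and mean input probability match the generative model
    assert abs(S.mean() - params.NU_S * 5.0) < 3 * np.sqrt(0.05 / S.size)
    p_bar = X.mean()
    assert 0.03 < p_bar < 0.08
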