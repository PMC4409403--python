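"""Analytic layer: h, correlation kernels, g-coefficients, mean field."""

import numpy as np
import pytest
from scipy.integrate import quad

from corrspike import params, theory
from corrspike.plasticity import STDPConfig, lateral_window
from corrspike.stimuli import response_kernel
from corrspike.theory import (
    Fbar,
    MeanFieldParams,
    TheoryConfig,
    chi1X,
    chi2X,
    find_fixed_points,
    g1Y,
    g1Z,
    h_closed_form,
    inhibitory_rates,
    kernel_coefficients,
    meanfield_rhs,
    specialization_index,
)


class TestCorrelationDensity:
    def test_value_at_zero(self):
        assert np.isclose(h_closed_form(0.0, 2.0), 3.0 / 32.0, rtol=1e-12)

    @pytest.mark.parametrize("kind", ["gamma3", "exponential"])
    @pytest.mark.parametrize("theta", [0.5, 2.0, 4.0])
    def test_unit_integral(self, kind, theta):
        val, _ = quad(lambda t: h_closed_form(t, theta, kind), -60 * theta,
                      60 * theta, limit=300)
        assert abs(val - 1.0) < 1e-8

    def test_symmetry(self):
        tau = np.array([-7.3, -0.2, 0.9, 4.4])
        assert np.allclose(h_closed_form(tau, 1.7), h_closed_form(-tau, 1.7))

    @pytest.mark.parametrize("kind", ["gamma3", "exponential"])
    def test_matches_numeric_autocorrelation(self, kind):
        # h is the autocorrelation of the response kernel: independent
        # quadrature of the defining integral
        theta = 2.0
        for tau in (0.0, 0.7, 2.0, 5.0, -3.1):
            val, _ = quad(
                lambda t: response_kernel(t, theta, kind)
                * response_kernel(t - tau, theta, kind)
                if t - tau >= 0 else 0.0,
                max(tau, 0.0), max(tau, 0.0) + 60 * theta, limit=400,
            )
            assert abs(val - h_closed_form(tau, theta, kind)) < 1e-6


class TestKernelCoefficients:
    def test_positive_at_reference_weight(self, coeffs):
        assert coeffs.g1X > 0
        assert coeffs.g2X > 0

    def test_zero_window_gives_zero(self):
        cfg = TheoryConfig(stdp=STDPConfig(C_p=0.0, C_d=0.0))
        c = kernel_coefficients(cfg)
        assert c.g1X == 0.0 and c.g2X == 0.0

    def test_dual_route_consistency(self, coeffs):
        # G1X via the weight-factorized integrals must equal the direct
        # chi_1-kernel route int chi1(tau; w) h(tau) dtau
        cfg = TheoryConfig()
        for w in (1.0, 2.5, 8.0):
            tau = np.arange(-80.0, 200.0, 0.02)
            chi = chi1X(tau, w, cfg)
            direct = np.trapezoid(chi * h_closed_form(tau, cfg.theta_t), tau)
            assert abs(direct - coeffs.G1X(w)) < 2e-3 * abs(coeffs.G1X(w)) + 1e-6

    def test_chi2_route_consistency(self, coeffs):
        cfg = TheoryConfig()
        w = 2.5
        tau = np.arange(-100.0, 260.0, 0.02)
        chi = chi2X(tau, w, cfg)
        direct = np.trapezoid(chi * h_closed_form(tau, cfg.theta_t), tau)
        assert abs(direct - coeffs.G2X(w)) < 2e-3 * abs(coeffs.G2X(w)) + 1e-6

    def test_monte_carlo_oracle_G1X(self, coeffs):
        # sample r ~ eps_X and integrate F(w_o, s) h(r - s + 2 d_Xd) over s
        # by sampling lags from the window branches
        rng = np.random.default_rng(0)
        cfg = TheoryConfig()
        n = 100_000
        # sample r ~ eps_X by inversion on a fine grid
        t = np.arange(0.0, 150.0, 0.01)
        pdf = (np.exp(-t / 5.0) - np.exp(-t / 1.0)) / 4.0
        cdf = np.cumsum(pdf) * 0.01
        r = np.interp(rng.random(n), cdf / cdf[-1], t)
        st = cfg.stdp
        s_grid = np.arange(-250.0, 250.0, 0.25)
        F = np.where(s_grid >= 0,
                     np.exp(-s_grid / st.tau_p),
                     np.exp(s_grid / st.tau_d))
        fp = float(np.exp(-st.w_o / (st.beta * st.w_o)))
        fd = float(-st.C_d * np.log1p(st.alpha) / np.log1p(st.alpha))
        amp = np.where(s_grid >= 0, fp, fd)
        # average h(r - s + 2 d_Xd) over samples, vectorized in chunks
        acc = np.zeros_like(s_grid)
        for ch in np.array_split(r, 20):
            acc += h_closed_form(ch[:, None] - s_grid[None, :] + 2 * cfg.d_Xd,
                                 cfg.theta_t).sum(axis=0)
        acc /= n
        est = np.trapezoid(F * amp * acc, s_grid)
        assert abs(est - coeffs.g1X) < 0.02 * abs(coeffs.g1X) + 1e-3

    def test_kappa_increases_with_timescale(self):
        kappas, g1s, g2s = [], [], []
        for th in (0.5, 2.0, 4.0):
            c = kernel_coefficients(TheoryConfig(theta_t=th))
            kappas.append(c.kappa)
            g1s.append(c.g1X)
            g2s.append(c.g2X)
        assert kappas[0] < kappas[1] < kappas[2]
        assert g1s[0] > g1s[1] > g1s[2]
        # g2X decreases too, up to grid tolerance at the flat left end
        assert g2s[2] < g2s[0] + 1e-3
        assert g2s[2] < g2s[1]

    def test_exponential_kernel_has_smaller_kappa(self):
        for th in (1.0, 2.0, 3.0):
            kg = kernel_coefficients(TheoryConfig(theta_t=th)).kappa
            ke = kernel_coefficients(
                TheoryConfig(theta_t=th, kernel="exponential")).kappa
            assert ke < kg


class TestLateralCoefficients:
    def test_g1Y_sign_follows_ltd_window(self):
        cfg = TheoryConfig()
        assert g1Y(cfg, tau_d=5.0) < 0      # narrow LTD window
        assert g1Y(cfg, tau_d=40.0) > 0     # long LTD window

    def test_g1Z_negative_for_hebbian_defaults(self):
        # negative g1Z predicts non-reciprocal wiring = mutual inhibition
        assert g1Z(TheoryConfig()) < 0

    def test_zero_window_zero_coefficient(self):
        cfg = TheoryConfig()
        zero = lateral_window("hebbian", C_p=0.0)
        assert theory._lateral_coeff(cfg, zero, "Y") == 0.0

    def test_monte_carlo_oracle_g1Y(self):
        # independent MC estimate: sample (r, u, r') from the PSP densities,
        # integrate the window over s on a grid
        rng = np.random.default_rng(1)
        cfg = TheoryConfig()
        n = 100_000

        def sample_pdf(tauA, tauB, size):
            t = np.arange(0.0, 40 * tauA, 0.01)
            pdf = (np.exp(-t / tauA) - np.exp(-t / tauB)) / (tauA - tauB)
            cdf = np.cumsum(pdf) * 0.01
            return np.interp(rng.random(size), cdf / cdf[-1], t)

        r = sample_pdf(5.0, 1.0, n)
        u = sample_pdf(4.0, 0.8, n)
        rp = sample_pdf(5.0, 1.0, n)
        lag = u + rp - r
        window = lateral_window("hebbian", 20.0, 20.0, params.GAMMA_Y)
        # the window jumps at s = 0: integrate the branches separately
        est = 0.0
        for s_grid, eval_grid in (
            (np.arange(0.0, 250.0, 0.25),) * 2,
            (np.arange(-250.0, 0.0 + 1e-9, 0.25),
             np.minimum(np.arange(-250.0, 0.0 + 1e-9, 0.25), -1e-12)),
        ):
            F = window(eval_grid)
            acc = np.zeros_like(s_grid)
            for ch in np.array_split(lag, 20):
                acc += h_closed_form(ch[:, None] - s_grid[None, :],
                                     cfg.theta_t).sum(axis=0)
            est += np.trapezoid(F * acc / n, s_grid)
        ref = g1Y(cfg)
        assert abs(est - ref) < 0.02 * abs(ref) + 1e-3


class TestMeanField:
    def test_inhibitory_rates_symmetric_reduction(self, meanfield):
        mf = meanfield.with_loop_gain(0.215)
        w = [5.0, 5.0, 5.0, 5.0]
        nu1, nu2 = inhibitory_rates(w, mf)
        P = mf.loop_gain
        lam = mf.gain_I * mf.gain_E * mf.M_a * mf.w_Y * mf.nu_X
        S = mf.L_a * (10.0 + 2 * mf.w_o_X)
        assert np.isclose(nu1, nu2)
        assert np.isclose(nu1, lam * S / (1 + P), rtol=1e-12)

    def test_inhibitory_rates_no_feedback(self, meanfield):
        mf = meanfield.with_loop_gain(0.0)
        w = [3.0, 1.0, 7.0, 2.0]
        nu1, nu2 = inhibitory_rates(w, mf)
        lam = mf.gain_I * mf.gain_E * mf.M_a * mf.w_Y * mf.nu_X
        assert np.isclose(nu1, lam * mf.L_a * (3 + 1 + 2 * mf.w_o_X))
        assert np.isclose(nu2, lam * mf.L_a * (7 + 2 + 2 * mf.w_o_X))

    def test_inhibitory_rates_self_consistent(self, meanfield):
        # the closed form solves the implicit two-group balance: substitute
        # back and iterate
        mf = meanfield.with_loop_gain(0.3)
        w = [9.0, 3.0, 4.0, 8.0]
        nu1, nu2 = inhibitory_rates(w, mf)
        lam = mf.gain_I * mf.gain_E * mf.M_a * mf.w_Y
        S1 = mf.L_a * (w[0] + w[1] + 2 * mf.w_o_X)
        S2 = mf.L_a * (w[2] + w[3] + 2 * mf.w_o_X)
        # fixed-point iteration of the implicit two-group balance
        # nu_mu = lam * (S_mu * nu_X - N_a w_Z * nu_mubar)
        a, b = 0.0, 0.0
        for _ in range(2000):
            a, b = (lam * (S1 * mf.nu_X - mf.N_a * mf.w_Z * b),
                    lam * (S2 * mf.nu_X - mf.N_a * mf.w_Z * a))
        assert np.isclose(a, nu1, rtol=1e-10)
        assert np.isclose(b, nu2, rtol=1e-10)

    def test_rhs_symmetry(self, coeffs):
        mf = MeanFieldParams(coeffs=coeffs, q_A=0.5, q_B=0.5).with_loop_gain(0.2)
        d = meanfield_rhs([4.0, 6.0, 4.0, 6.0], mf)
        assert np.isclose(d[0], d[2]) and np.isclose(d[1], d[3])

    def test_rhs_homeostatic_only_without_correlation(self, coeffs):
        mf = MeanFieldParams(coeffs=coeffs, q_A=0.0, q_B=0.0).with_loop_gain(0.2)
        w = [4.0, 2.0, 5.0, 3.0]
        d = meanfield_rhs(w, mf)
        P = mf.loop_gain
        S1 = 4 + 2 + 2 * mf.w_o_X
        S2 = 5 + 3 + 2 * mf.w_o_X
        expect0 = (Fbar(4.0, coeffs.stdp) * mf.nu_X**2 * mf.L_a
                   * (S1 - P * S2) / (1 - P**2))
        assert np.isclose(d[0], expect0, rtol=1e-12)

    def test_fixed_points_are_roots(self, meanfield, fixed_points_by_gain):
        for P, fps in fixed_points_by_gain.items():
            mf = meanfield.with_loop_gain(P)
            assert fps, f"no fixed points found at P={P}"
            for fp in fps:
                assert np.max(np.abs(meanfield_rhs(fp.w, mf))) < 1e-9

    def test_regime_structure(self, fixed_points_by_gain):
        weak = fixed_points_by_gain[0.1]
        stable_weak = [f for f in weak if f.stable]
        assert len(stable_weak) == 1
        w = stable_weak[0].w
        assert w[0] > w[1] and w[2] > w[3]  # winner-take-all on source A

        mod = fixed_points_by_gain[0.215]
        assert sum(f.stable for f in mod) == 3
        assert sum(not f.stable for f in mod) == 2

        strong = fixed_points_by_gain[0.4]
        stable_strong = [f for f in strong if f.stable]
        assert len(stable_strong) == 2
        assert all(f.w_SI == 1 for f in stable_strong)

    def test_stability_matches_forward_integration(self, meanfield,
                                                   fixed_points_by_gain):
        from scipy.integrate import solve_ivp

        mf = meanfield.with_loop_gain(0.215)
        for fp in fixed_points_by_gain[0.215]:
            if not fp.stable:
                continue
            # ~30 times the slowest relaxation timescale of this point
            horizon = 30.0 / np.abs(fp.eigvals.real).min()
            w0 = fp.w * (1 + 0.02 * np.array([1, -1, 1, -1]))
            sol = solve_ivp(lambda t, w: meanfield_rhs(w, mf), (0, horizon),
                            w0, rtol=1e-8, atol=1e-10)
            assert np.linalg.norm(sol.y[:, -1] - fp.w) < 0.05

    def test_specialization_index(self):
        assert specialization_index(10, 2, 2, 10) == 1
        assert specialization_index(10, 2, 10, 2) == -1
        assert specialization_index(5, 5, 5, 5) == 0
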