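"""Stimulus generation: kernels, source events, rate modulation, Q matrices,
auditory scenes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from corrspike import params, stimuli
from corrspike.stimuli import (
    AuditoryScene,
    ResponseMatrix,
    SourceConfig,
    build_Q,
    correlation_matrix,
    input_rates,
    response_kernel,
    sample_input_spikes,
    sample_source_events,
    synth_auditory_scene,
)


class TestResponseKernel:
    def test_zero_at_origin(self):
        assert response_kernel(0.0, 2.0, "gamma3") == 0.0

    @pytest.mark.parametrize("kind", ["gamma3", "exponential"])
    @pytest.mark.parametrize("theta", [0.5, 2.0, 4.0])
    def test_unit_area(self, kind, theta):
        val, _ = quad(lambda t: response_kernel(t, theta, kind), 0, 50 * theta)
        assert abs(val - 1.0) < 1e-6

    def test_mode_at_two_theta(self):
        # brute-force grid search against the closed-form mode location
        theta = 2.0
        t = np.linspace(0, 40, 40001)
        assert abs(t[np.argmax(response_kernel(t, theta))] - 2 * theta) < 2e-3

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            response_kernel(-1.0, 2.0)
        with pytest.raises(ValueError):
            response_kernel(1.0, -2.0)
        with pytest.raises(ValueError):
            SourceConfig(kernel="boxcar")


class TestSourceEvents:
    def test_event_counts_poissonian(self):
        cfg = SourceConfig(p=3)
        ev = sample_source_events(cfg, T=100e3, dt=0.5, seed=1)
        expect = cfg.nu_S * 100e3
        for mu in range(3):
            assert abs(ev[mu].sum() - expect) < 3 * np.sqrt(expect)

    def test_zero_rate_gives_silence(self):
        cfg = SourceConfig(p=2, nu_S=0.0)
        assert sample_source_events(cfg, T=1e3, dt=0.1, seed=0).sum() == 0

    def test_sources_independent(self):
        cfg = SourceConfig(p=2)
        ev = sample_source_events(cfg, T=300e3, dt=1.0, seed=3).astype(float)
        r = np.corrcoef(ev)[0, 1]
        assert abs(r) < 3 / np.sqrt(ev.shape[1])

    def test_rate_error(self):
        with pytest.raises(ValueError):
            sample_source_events(SourceConfig(nu_S=0.5), T=10.0, dt=5.0)

    def test_reproducible(self):
        cfg = SourceConfig()
        a = sample_source_events(cfg, 1e3, 0.1, seed=7)
        b = sample_source_events(cfg, 1e3, 0.1, seed=7)
        assert np.array_equal(a, b)


class TestInputRates:
    def test_no_events_baseline_only(self):
        rm = build_Q("minor_source", L=40, L_a=10)
        cfg = SourceConfig(p=2)
        rates = input_rates(rm, np.zeros((2, 2000), dtype=np.uint8), cfg, dt=0.1)
        assert np.allclose(rates, rm.r_o[:, None])

    def test_single_event_bump_is_kernel(self):
        rm = ResponseMatrix(np.ones((1, 1)), nu_X=params.NU_S)  # q=1, r_o=0
        cfg = SourceConfig(p=1, theta_t=2.0)
        dt = 0.05
        ev = np.zeros((1, 4000), dtype=np.uint8)
        ev[0, 100] = 1
        rates = input_rates(rm, ev, cfg, dt=dt)
        t_rel = (np.arange(4000) - 100 + 0.5) * dt  # midpoint kernel sampling
        expected = np.where(t_rel > 0, response_kernel(np.clip(t_rel, 0, None),
                                                       2.0), 0.0)
        # the convolution window is truncated at 20*theta_t = 800 steps
        assert np.allclose(rates[0, :900], expected[:900], atol=1e-9)
        assert np.all(np.abs(rates[0, 900:]) < 1e-6)

    def test_mean_rate_is_nu_X(self):
        # time-averaged input rate equals the 10 Hz operating point by
        # construction of the baseline r_o, regardless of Q
        rm = build_Q("minor_source", L=40, L_a=10, q_A=0.6, q_B=0.5)
        cfg = SourceConfig(p=2)
        ev = sample_source_events(cfg, T=200e3, dt=0.5, seed=5)
        rates = input_rates(rm, ev, cfg, dt=0.5)
        assert np.allclose(rates.mean(axis=1), params.NU_X, atol=5e-4)


class TestInputSpikes:
    def test_zero_rate_silent(self):
        assert sample_input_spikes(np.zeros((3, 100)), 0.1, 0).sum() == 0

    def test_constant_rate_counts(self):
        rates = np.full((1, int(100e3 / 0.5)), 0.01)
        sp = sample_input_spikes(rates, 0.5, seed=2)
        assert abs(sp.sum() - 1000) < 3 * np.sqrt(1000)

    def test_rate_overflow_raises(self):
        with pytest.raises(ValueError):
            sample_input_spikes(np.full((1, 10), 30.0), 0.1)

    def test_negative_rates_clipped(self):
        sp = sample_input_spikes(np.full((2, 50), -5.0), 0.1, seed=0)
        assert sp.sum() == 0


class TestResponseMatrices:
    def test_minor_source_blocks(self):
        rm = build_Q("minor_source", q_A=0.6, q_B=0.5, L=400, L_a=100)
        assert np.all(rm.Q[:100, 0] == 0.6) and np.all(rm.Q[:100, 1] == 0)
        assert np.all(rm.Q[100:200, 1] == 0.5) and np.all(rm.Q[100:200, 0] == 0)
        assert np.all(rm.Q[200:] == 0)

    def test_crosstalk_reduces_to_disjoint(self):
        a = build_Q("crosstalk", q_S=0.6, q_N=0.0, L=40, L_a=10)
        b = build_Q("minor_source", q_A=0.6, q_B=0.6, L=40, L_a=10)
        assert np.allclose(a.Q, b.Q)

    def test_four_source_ring_correlations(self):
        q_S, q_N = 0.6, 0.1
        rm = build_Q("four_source", L=40, L_a=10, q_S=q_S, q_N=q_N)
        C = correlation_matrix(rm, by_group=True)
        expected = np.array(
            [
                [q_S**2 + 2 * q_N**2, 2 * q_S * q_N, 2 * q_N**2, 2 * q_S * q_N],
                [2 * q_S * q_N, q_S**2 + 2 * q_N**2, 2 * q_S * q_N, 2 * q_N**2],
                [2 * q_N**2, 2 * q_S * q_N, q_S**2 + 2 * q_N**2, 2 * q_S * q_N],
                [2 * q_S * q_N, 2 * q_N**2, 2 * q_S * q_N, q_S**2 + 2 * q_N**2],
            ]
        )
        assert np.allclose(C, expected)

    def test_correlation_strengths(self):
        rm = build_Q("minor_source", q_A=0.6, q_B=0.5)
        C = correlation_matrix(rm, by_group=True)
        assert np.isclose(C[0, 0], 0.36)
        assert np.isclose(C[1, 1], 0.25)
        assert np.allclose(correlation_matrix(
            ResponseMatrix(np.zeros((8, 2)))), 0.0)

    def test_psd_and_symmetry(self):
        rm = build_Q("four_source", L=40, L_a=10, q_S=0.5, q_N=0.2)
        C = correlation_matrix(rm)
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-12

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError):
            build_Q("crosstalk", q_S=0.9, q_N=0.9, L=20, L_a=10)
        with pytest.raises(ValueError):
            ResponseMatrix(np.full((4, 1), 1.5))

    def test_group_sizes_validated(self):
        with pytest.raises(ValueError):
            build_Q("four_source", L=30, L_a=10)


class TestAuditoryScene:
    def test_frequency_grid_endpoints(self):
        scene = AuditoryScene()
        f = scene.freq_grid()
        assert np.isclose(f[-1], 4500.0)
        assert np.all(np.diff(f) > 0)
        assert np.allclose(np.diff(np.log(f)), np.diff(np.log(f))[0])

    def test_spectrum_peaks_at_harmonics(self):
        scene = AuditoryScene()
        f = np.linspace(400, 3000, 20000)
        spec = scene.spectrum(0, f)
        # local maxima near the first harmonics of both fundamentals
        for f0 in (523.3, 784.0, 2 * 523.3):
            window = (f > f0 - 60) & (f < f0 + 60)
            peak = f[window][np.argmax(spec[window])]
            assert abs(peak - f0) < 25.0

    def test_envelope_positive_and_periodic(self):
        scene = AuditoryScene()
        t = np.linspace(0, 10, 5001)  # seconds
        env = scene.envelope(1, t)
        assert np.all(env >= 0)
        # source 0 frequencies (0.4, 5, 10, 40, 88 Hz) share a 5 s period
        period = 5.0
        e1 = scene.envelope(0, t)
        e2 = scene.envelope(0, t + period)
        assert np.allclose(e1, e2, rtol=1e-9)

    def test_response_probabilities_clipped(self):
        scene = AuditoryScene(L=50)
        out = synth_auditory_scene(scene, T=500.0, dt_env=1.0)
        q = out["q_t"]
        assert q.shape == (50, 500)
        assert q.min() >= 0.0 and q.max() <= 1.0

    def test_waveform_synthesis(self):
        scene = AuditoryScene(L=30)
        out = synth_auditory_scene(scene, T=50.0, waveform=True)
        assert np.all(np.isfinite(out["audio"]))
        assert out["audio"].size == len(out["t_audio"])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(theta=st.floats(0.3, 6.0),
       kind=st.sampled_from(["gamma3", "exponential"]))
def test_kernel_area_property(theta, kind):
    t = np.linspace(0, 60 * theta, 200001)
    area = np.trapezoid(response_kernel(t, theta, kind), t)
    assert abs(area - 1.0) < 1e-4


def test_spike_text_roundtrip(tmp_path):
    ids = np.array([3, 1, 2])
    ts = np.array([0.05, 12.3, 999.9])
    path = tmp_path / "spikes.txt"
    stimuli.write_spikes_text(path, ids, ts)
    ids2, ts2 = stimuli.read_spikes_text(path)
    assert np.array_equal(ids, ids2)
    assert np.allclose(ts, ts2)
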