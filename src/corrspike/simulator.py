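"""Clock-driven network simulation.

The output layer (M excitatory linear-Poisson neurons) is driven by L
input neurons through plastic feedforward weights W_X and inhibited by N
lateral interneurons through W_Z; the interneurons are excited by the
output layer through W_Y. PSPs are unit-area double exponentials; every
synapse has its own axonal (and, feedforward only, dendritic) delay.
Neurons fire as Bernoulli(g(u)*dt) given the membrane potential u, with
linear gains g_E(u) = gain_E*u, g_I(u) = gain_I*u rectified at zero for
spike generation (membrane traces are recorded unrectified).

A conductance-based leaky integrate-and-fire backend with the same wiring
and plasticity hooks is provided for cross-checking the linear-Poisson
results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import params
from ._engine import run_lif_core, run_poisson_core
from .plasticity import STDPConfig

__all__ = [
    "NetworkConfig",
    "LIFConfig",
    "SimResult",
    "make_epsp_kernel",
    "wire_lateral",
    "run_poisson",
    "run_lif",
    "psth",
]

_RULE_CODES = {
    None: 0,
    "static": 0,
    "log_stdp": 1,
    "hebbian": 2,
    "anti_hebbian": 3,
    "corr_detector": 4,
    "anti_corr_detector": 5,
}


def make_epsp_kernel(tauA: float, tauB: float):
    """Unit-area double-exponential PSP kernel.

    eps(r) = (e^{-r/tauA} - e^{-r/tauB}) / (tauA - tauB), r >= 0. Equal
    time constants are rejected (the alpha-function limit is not used).
    """
    if tauA <= 0 or tauB <= 0:
        raise ValueError("time constants must be positive")
    if tauA == tauB:
        raise ValueError("tauA must differ from tauB")

    def eps(r):
        r = np.asarray(r, dtype=float)
        out = (np.exp(-r / tauA) - np.exp(-r / tauB)) / (tauA - tauB)
        return np.where(r >= 0, out, 0.0)

    eps.peak_time = tauA * tauB / (tauA - tauB) * np.log(tauA / tauB)
    return eps


def wire_lateral(
    mode: str,
    *,
    M: int = params.M,
    N: int = params.N,
    M_a: int = params.M_A,
    N_a: int = params.N_A,
    w_Y: float = params.W_O_Y,
    w_Z: float = params.W_O_Z,
    seed=None,
):
    """Lateral weight matrices (W_Y: N x M E-to-I, W_Z: M x N I-to-E).

    ``structured``: each inhibitory group is excited by its own output
    group (block diagonal W_Y) and inhibits all *other* output groups
    (block anti-diagonal W_Z) — mutual inhibition between groups.
    ``random``: every entry present independently with probability 0.5 at
    the same weight values.
    """
    if M % M_a or N % N_a:
        raise ValueError("group sizes must divide the layer sizes")
    if M // M_a != N // N_a:
        raise ValueError("output and inhibitory layers need equal group counts")
    if mode == "structured":
        out_group = np.arange(M) // M_a
        inh_group = np.arange(N) // N_a
        W_Y = w_Y * (inh_group[:, None] == out_group[None, :])
        W_Z = w_Z * (out_group[:, None] != inh_group[None, :])
    elif mode == "random":
        rng = np.random.default_rng(seed)
        W_Y = w_Y * (rng.random((N, M)) < 0.5)
        W_Z = w_Z * (rng.random((M, N)) < 0.5)
    else:
        raise ValueError(f"unknown wiring mode {mode!r}")
    return W_Y.astype(float), W_Z.astype(float)


@dataclass
class NetworkConfig:
    """Wiring, weights, delays and PSP shapes of the full network."""

    W_X: np.ndarray          # (M, L) feedforward weights
    W_Y: np.ndarray          # (N, M) E-to-I weights
    W_Z: np.ndarray          # (M, N) I-to-E weights
    d_Xa: np.ndarray         # (M, L) feedforward axonal delays (ms)
    d_Xd: np.ndarray         # (M, L) feedforward dendritic delays (ms)
    d_Y: np.ndarray          # (N, M) lateral axonal delays (ms)
    d_Z: np.ndarray          # (M, N) feedback axonal delays (ms)
    tau_X: tuple = (params.TAU_A_X, params.TAU_B_X)
    tau_Y: tuple = (params.TAU_A_Y, params.TAU_B_Y)
    tau_Z: tuple = (params.TAU_A_Z, params.TAU_B_Z)
    gain_E: float = params.GAIN_E
    gain_I: float = params.GAIN_I
    M_a: int = params.M_A
    N_a: int = params.N_A

    def __post_init__(self) -> None:
        self.W_X = np.ascontiguousarray(self.W_X, dtype=np.float64)
        self.W_Y = np.ascontiguousarray(self.W_Y, dtype=np.float64)
        self.W_Z = np.ascontiguousarray(self.W_Z, dtype=np.float64)
        M, L = self.W_X.shape
        N = self.W_Y.shape[0]
        if self.W_Y.shape != (N, M) or self.W_Z.shape != (M, N):
            raise ValueError("inconsistent layer sizes")
        for W in (self.W_X, self.W_Y, self.W_Z):
            if np.any(W < 0):
                raise ValueError("weights must be non-negative")
        for tau in (self.tau_X, self.tau_Y, self.tau_Z):
            if not tau[0] > tau[1] > 0:
                raise ValueError("need tau_A > tau_B > 0")

    @property
    def shape(self):
        M, L = self.W_X.shape
        return L, M, self.W_Y.shape[0]


@dataclass(frozen=True)
class LIFConfig:
    """Conductance-based LIF parameters (potentials in mV, times in ms)."""

    V_L: float = -70.0
    V_E: float = 0.0
    V_I: float = -80.0
    V_ref: float = -60.0
    V_th: float = -50.0
    tau_m_E: float = 20.0
    tau_m_I: float = 10.0
    tau_s_EE: float = 5.0
    tau_s_EI: float = 2.5
    tau_s_IE: float = 4.0
    tau_s_II: float = 5.0
    t_ref: float = 1.0
    w_scale_X: float = 0.001 / params.W_O_X   # conductance per unit weight
    w_scale_Y: float = 0.008 / params.W_O_Y
    w_scale_Z: float = 0.008 / params.W_O_Z
    w_II: float = 0.005
    r_o_II: float = 1000.0 / params.MS_PER_S  # background inh. rate (1/ms)

    def __post_init__(self) -> None:
        if not (self.V_I <= self.V_ref < self.V_th):
            raise ValueError("need V_I <= V_ref < V_th")


@dataclass
class SimResult:
    """Spikes, weight snapshots and membrane traces from one run."""

    dt: float
    T: float
    out_spikes: np.ndarray      # (n, 2): neuron id, time ms
    inh_spikes: np.ndarray
    in_spikes: np.ndarray | None
    w_times: np.ndarray         # weight-snapshot times (ms)
    W_X_trace: np.ndarray       # (n_snap, M, L) or group means (n_snap, G, Gin)
    W_X_final: np.ndarray
    W_Y_final: np.ndarray
    W_Z_final: np.ndarray
    u_times: np.ndarray
    u_E: np.ndarray             # (n_rec, M) membrane traces (unrectified)
    source_events: np.ndarray | None = None
    clamp_fraction: float = 0.0

    def spike_trains(self, layer: str = "out"):
        sp = {"out": self.out_spikes, "inh": self.inh_spikes,
              "in": self.in_spikes}[layer]
        return sp[:, 0].astype(int), sp[:, 1]


def _delays_to_steps(d: np.ndarray, dt: float) -> np.ndarray:
    steps = np.rint(np.asarray(d, float) / dt).astype(np.int64)
    if np.any(steps < 0):
        raise ValueError("negative delay")
    return steps


def _prepare_stdp(stdp_X: STDPConfig | None,
                  stdp_Y: STDPConfig | None,
                  stdp_Z: STDPConfig | None):
    """Pack STDP configs into the flat float64[16] layout of the engine."""
    from .plasticity import _amplitudes

    def pack(cfg):
        if cfg is None:
            return np.zeros(16)
        (a_p, a_d), (b_p, b_d) = _amplitudes(cfg, 0.0)
        return np.array([
            _RULE_CODES[cfg.rule], cfg.eta, cfg.tau_p, cfg.tau_d,
            a_p, a_d, b_p, b_d,
            cfg.sigma_stdp, cfg.w_max,
            cfg.C_p, cfg.C_d, cfg.alpha, cfg.beta, cfg.w_o, 0.0,
        ])

    return pack(stdp_X), pack(stdp_Y), pack(stdp_Z)


def run_poisson(
    net: NetworkConfig,
    input_spikes,
    T: float,
    dt: float = params.DT,
    seed: int = 0,
    stdp_X: STDPConfig | None = None,
    stdp_Y: STDPConfig | None = None,
    stdp_Z: STDPConfig | None = None,
    stimulus: dict | None = None,
    w_o_X: float = params.W_O_X,
    record_u_stride: int = 0,
    record_w_every: float = 1000.0,
    record_input_spikes: bool = False,
) -> SimResult:
    """Simulate the linear-Poisson network.

    ``input_spikes`` is either a pre-generated (L, n_steps) binary array
    or None, in which case ``stimulus`` must carry the generative model:
    either source-driven (keys ``Q`` (L, p), ``r_o`` (L,), ``nu_S``,
    ``theta_t``, ``kernel``), with input spikes generated on the fly by
    streaming the Bernoulli source events through the response kernel, or
    rate-table-driven (keys ``Q``, ``r_o``, ``env`` (p, n_env),
    ``env_dt``), with rate_i(t) = r_o_i + sum_mu Q[i,mu]*env[mu, t]
    (used by the auditory task). Plasticity hooks (``stdp_X`` for
    feedforward log-STDP, ``stdp_Y``/``stdp_Z`` for lateral rules) are
    applied at the at-synapse spike times, including the per-synapse
    axonal/dendritic shifts. Reproducible for a given seed.
    """
    L, M, N = net.shape
    n_steps = int(round(T / dt))
    nu_S, theta_t, kernel_kind = 0.0, 1.0, 0
    env = np.zeros((1, 1))
    env_stride = 1
    g_members = np.zeros((1, 1), dtype=np.int64)
    g_sizes = np.zeros(1, dtype=np.int64)
    Qg = np.zeros((1, 1))
    r_og = np.zeros(1)
    if input_spikes is not None:
        input_spikes = np.ascontiguousarray(input_spikes, dtype=np.uint8)
        if input_spikes.shape[0] != L:
            raise ValueError("input spike array has wrong neuron count")
        n_steps = input_spikes.shape[1]
        Q = np.zeros((L, 1))
        r_o = np.zeros(L)
        in_mode = 0
    else:
        if stimulus is None:
            raise ValueError("need input_spikes or a stimulus description")
        Q = np.ascontiguousarray(stimulus["Q"], dtype=np.float64)
        r_o = np.ascontiguousarray(stimulus["r_o"], dtype=np.float64)
        input_spikes = np.zeros((1, 1), dtype=np.uint8)
        if "env" in stimulus:
            in_mode = 2
            env = np.ascontiguousarray(stimulus["env"], dtype=np.float64)
            env_stride = max(1, int(round(stimulus.get("env_dt", dt) / dt)))
        else:
            in_mode = 1
            nu_S = float(stimulus.get("nu_S", params.NU_S))
            theta_t = float(stimulus.get("theta_t", params.THETA_T))
            kernel_kind = 0 if stimulus.get("kernel", "gamma3") == "gamma3" else 1
            # equal-rate input groups (identical Q row and baseline) are
            # drawn by one binomial count per step instead of L Bernoullis
            key = np.round(np.column_stack([Q, r_o]), 12)
            _, g_of = np.unique(key, axis=0, return_inverse=True)
            n_groups = int(g_of.max()) + 1
            g_sizes = np.bincount(g_of, minlength=n_groups).astype(np.int64)
            g_members = np.full((n_groups, int(g_sizes.max())), -1, np.int64)
            fill = np.zeros(n_groups, dtype=np.int64)
            for i, g in enumerate(g_of):
                g_members[g, fill[g]] = i
                fill[g] += 1
            Qg = np.ascontiguousarray(
                np.stack([Q[g_members[g, 0]] for g in range(n_groups)]))
            r_og = np.ascontiguousarray(
                np.array([r_o[g_members[g, 0]] for g in range(n_groups)]))

    sx, sy, sz = _prepare_stdp(stdp_X, stdp_Y, stdp_Z)
    res = run_poisson_core(
        int(seed), n_steps, dt,
        in_mode, input_spikes, Q, r_o, nu_S, theta_t, kernel_kind,
        g_members, g_sizes, Qg, r_og, env, env_stride,
        net.W_X.copy(), net.W_Y.copy(), net.W_Z.copy(),
        _delays_to_steps(net.d_Xa, dt), _delays_to_steps(net.d_Xd, dt),
        _delays_to_steps(net.d_Y, dt), _delays_to_steps(net.d_Z, dt),
        net.tau_X[0], net.tau_X[1], net.tau_Y[0], net.tau_Y[1],
        net.tau_Z[0], net.tau_Z[1],
        net.gain_E, net.gain_I,
        sx, sy, sz, w_o_X,
        int(record_u_stride), max(1, int(round(record_w_every / dt))),
        record_input_spikes,
    )
    (out_sp, inh_sp, in_sp, w_times, wx_trace, WX, WY, WZ,
     u_times, uE, src_ev, clamp_frac) = res
    if clamp_frac > 0:
        warnings.warn(
            f"firing probability clamped at 1 in {clamp_frac:.2%} of draws",
            stacklevel=2,
        )
    return SimResult(
        dt=dt, T=n_steps * dt,
        out_spikes=out_sp, inh_spikes=inh_sp,
        in_spikes=in_sp if record_input_spikes else None,
        w_times=w_times, W_X_trace=wx_trace,
        W_X_final=WX, W_Y_final=WY, W_Z_final=WZ,
        u_times=u_times, u_E=uE,
        source_events=src_ev if in_mode == 1 else None,
        clamp_fraction=clamp_frac,
    )


def run_lif(
    lif: LIFConfig,
    net: NetworkConfig,
    input_spikes,
    T: float,
    dt: float = params.DT,
    seed: int = 0,
    stdp_X: STDPConfig | None = None,
    stimulus: dict | None = None,
    w_o_X: float = params.W_O_X,
    record_u_stride: int = 0,
    record_w_every: float = 1000.0,
) -> SimResult:
    """Simulate the conductance-based LIF backend (same wiring/plasticity)."""
    L, M, N = net.shape
    n_steps = int(round(T / dt))
    if input_spikes is not None:
        input_spikes = np.ascontiguousarray(input_spikes, dtype=np.uint8)
        n_steps = input_spikes.shape[1]
        Q = np.zeros((L, 1)); r_o = np.zeros(L)
        nu_S, theta_t, kernel_kind = 0.0, 1.0, 0
        gen_inputs = False
    else:
        if stimulus is None:
            raise ValueError("need input_spikes or a stimulus description")
        Q = np.ascontiguousarray(stimulus["Q"], dtype=np.float64)
        r_o = np.ascontiguousarray(stimulus["r_o"], dtype=np.float64)
        nu_S = float(stimulus.get("nu_S", params.NU_S))
        theta_t = float(stimulus.get("theta_t", params.THETA_T))
        kernel_kind = 0 if stimulus.get("kernel", "gamma3") == "gamma3" else 1
        input_spikes = np.zeros((1, 1), dtype=np.uint8)
        gen_inputs = True

    # LIF log-STDP uses a stronger LTD balance and steeper weight dependence
    if stdp_X is not None and stdp_X.rule == "log_stdp":
        sx = _prepare_stdp(stdp_X, None, None)[0]
    else:
        sx = np.zeros(10)
    res = run_lif_core(
        int(seed), n_steps, dt,
        gen_inputs, input_spikes, Q, r_o, nu_S, theta_t, kernel_kind,
        net.W_X.copy(), net.W_Y.copy(), net.W_Z.copy(),
        _delays_to_steps(net.d_Xa, dt), _delays_to_steps(net.d_Xd, dt),
        _delays_to_steps(net.d_Y, dt), _delays_to_steps(net.d_Z, dt),
        lif.V_L, lif.V_E, lif.V_I, lif.V_ref, lif.V_th,
        lif.tau_m_E, lif.tau_m_I,
        lif.tau_s_EE, lif.tau_s_EI, lif.tau_s_IE, lif.tau_s_II,
        lif.w_scale_X, lif.w_scale_Y, lif.w_scale_Z,
        lif.w_II, lif.r_o_II, int(round(lif.t_ref / dt)),
        sx, w_o_X,
        int(record_u_stride), max(1, int(round(record_w_every / dt))),
    )
    (out_sp, inh_sp, w_times, wx_trace, WX, u_times, uE, src_ev, nan_flag) = res
    if nan_flag:
        raise FloatingPointError("LIF membrane potential became NaN")
    return SimResult(
        dt=dt, T=n_steps * dt,
        out_spikes=out_sp, inh_spikes=inh_sp, in_spikes=None,
        w_times=w_times, W_X_trace=wx_trace,
        W_X_final=WX, W_Y_final=net.W_Y, W_Z_final=net.W_Z,
        u_times=u_times, u_E=uE,
        source_events=src_ev if gen_inputs else None,
    )


def psth(trace_times, traces, event_times, window=(-20.0, 80.0)):
    """Event-aligned average of (membrane or rate) traces.

    ``traces`` is (n_rec,) or (n_rec, k); the average over events of the
    trace in ``window`` (ms, relative to each event) is returned together
    with its time axis.
    """
    event_times = np.asarray(event_times, float)
    if event_times.size == 0:
        raise ValueError("need at least one event")
    traces = np.asarray(traces, float)
    if traces.ndim == 1:
        traces = traces[:, None]
    dt = trace_times[1] - trace_times[0]
    i0, i1 = int(round(window[0] / dt)), int(round(window[1] / dt))
    rel = np.arange(i0, i1) * dt
    acc = np.zeros((i1 - i0, traces.shape[1]))
    n = 0
    for te in event_times:
        k = int(round((te - trace_times[0]) / dt))
        if k + i0 < 0 or k + i1 > traces.shape[0]:
            continue
        acc += traces[k + i0 : k + i1]
        n += 1
    if n == 0:
        raise ValueError("no event fits inside the recorded traces")
    return rel, acc / n
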