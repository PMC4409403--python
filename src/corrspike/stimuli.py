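"""Generation of everything upstream of the output layer.

Hidden sources are independent Bernoulli event trains on the simulation
grid. Input-layer neurons are rate-modulated Poisson units: each source
event is filtered through a response kernel phi(t) (an Erlang/gamma density
of shape 3 by default) and scaled by the neuron's response probability
q_imu; a constant baseline r_i^o tops the mean rate up to nu_X so that all
input neurons fire at the same average rate regardless of how strongly
they are driven by sources.

The module also builds the block response matrices Q for the standard
tasks (minor-source detection, crosstalk noise, four mixed sources) and
synthesizes the artificial auditory scenes used for blind source
separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from . import params

__all__ = [
    "SourceConfig",
    "ResponseMatrix",
    "AuditoryScene",
    "response_kernel",
    "sample_source_events",
    "input_rates",
    "sample_input_spikes",
    "build_Q",
    "correlation_matrix",
    "synth_auditory_scene",
    "write_spikes_text",
    "read_spikes_text",
]


@dataclass(frozen=True)
class SourceConfig:
    """Hidden-source statistics.

    Parameters
    ----------
    p : number of independent sources.
    nu_S : event rate of each source (1/ms; 0.01 == 10 Hz).
    theta_t : correlation timescale of the response kernel (ms).
    kernel : ``"gamma3"`` (Erlang shape-3, broad correlations) or
        ``"exponential"`` (sharply peaked correlations).
    """

    p: int = 2
    nu_S: float = params.NU_S
    theta_t: float = params.THETA_T
    kernel: str = "gamma3"

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("need at least one source")
        if self.nu_S < 0:
            raise ValueError("nu_S must be non-negative")
        if self.theta_t <= 0:
            raise ValueError("theta_t must be positive")
        if self.kernel not in ("gamma3", "exponential"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass(frozen=True)
class ResponseMatrix:
    """Response probabilities Q (L x p) plus per-neuron baseline rates.

    The baseline r_i^o = nu_X - sum_mu q_imu * nu_S keeps every input
    neuron's mean rate at nu_X. Configurations that would require a
    negative baseline are rejected.
    """

    Q: np.ndarray
    nu_X: float = params.NU_X
    group_size: int | None = None
    r_o: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim != 2:
            raise ValueError("Q must be 2-d (L x p)")
        if np.any(Q < 0) or np.any(Q > 1):
            raise ValueError("response probabilities must lie in [0, 1]")
        object.__setattr__(self, "Q", Q)
        r_o = self.nu_X - Q.sum(axis=1) * params.NU_S
        if np.any(r_o < -1e-12):
            raise ValueError(
                "negative baseline rate: sum_mu q_imu*nu_S exceeds nu_X"
            )
        object.__setattr__(self, "r_o", np.clip(r_o, 0.0, None))

    @property
    def L(self) -> int:
        return self.Q.shape[0]

    @property
    def p(self) -> int:
        return self.Q.shape[1]


def response_kernel(t, theta_t: float = params.THETA_T, kind: str = "gamma3"):
    """Response kernel phi(t) of input neurons to a source event (1/ms).

    ``gamma3``: phi(t) = t^2 e^{-t/theta} / (2 theta^3), the Erlang density
    of shape 3 — unit area, mode at 2*theta. ``exponential``:
    phi_e(t) = e^{-t/theta}/theta.
    """
    if theta_t <= 0:
        raise ValueError("theta_t must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel is causal; t must be >= 0")
    if kind == "gamma3":
        return t**2 * np.exp(-t / theta_t) / (2.0 * theta_t**3)
    if kind == "exponential":
        return np.exp(-t / theta_t) / theta_t
    raise ValueError(f"unknown kernel {kind!r}")


def sample_source_events(
    cfg: SourceConfig, T: float, dt: float = params.DT, seed=None
) -> np.ndarray:
    """Independent Bernoulli(nu_S*dt) event trains, shape (p, n_steps) uint8."""
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be positive")
    if cfg.nu_S * dt >= 1.0:
        raise ValueError("nu_S*dt >= 1: reduce dt")
    rng = np.random.default_rng(seed)
    n = int(round(T / dt))
    return (rng.random((cfg.p, n)) < cfg.nu_S * dt).astype(np.uint8)


def _kernel_on_grid(cfg: SourceConfig, dt: float, trunc: float) -> np.ndarray:
    n_k = int(np.ceil(trunc * cfg.theta_t / dt))
    tk = (np.arange(n_k) + 0.5) * dt
    ker = response_kernel(tk, cfg.theta_t, cfg.kernel)
    # mass-loss check of the truncated tail
    lost = 1.0 - ker.sum() * dt
    if lost > 1e-6:
        raise ValueError(
            f"kernel truncation loses {lost:.2e} mass; widen the window"
        )
    return ker


def input_rates(
    rm: ResponseMatrix,
    events: np.ndarray,
    cfg: SourceConfig,
    dt: float = params.DT,
    trunc: float = 20.0,
) -> np.ndarray:
    """Instantaneous input rates (L, n_steps), in 1/ms.

    rate_i(t) = r_i^o + sum_mu q_imu (phi * s_mu)(t), with the kernel
    truncated at ``trunc * theta_t`` (midpoint-sampled on the grid).
    """
    events = np.asarray(events, dtype=float)
    if events.shape[0] != rm.p:
        raise ValueError("events and Q disagree on the number of sources")
    ker = _kernel_on_grid(cfg, dt, trunc)
    conv = np.empty_like(events)
    for mu in range(rm.p):
        conv[mu] = fftconvolve(events[mu], ker)[: events.shape[1]]
    return rm.r_o[:, None] + rm.Q @ conv


def sample_input_spikes(rates: np.ndarray, dt: float = params.DT, seed=None):
    """Bernoulli(rate*dt) thinning per bin; negative rates are clipped to 0."""
    rates = np.asarray(rates, dtype=float)
    rates = np.clip(rates, 0.0, None)
    if np.any(rates * dt >= 1.0):
        raise ValueError("rate*dt >= 1 somewhere: reduce dt")
    rng = np.random.default_rng(seed)
    return (rng.random(rates.shape) < rates * dt).astype(np.uint8)


def build_Q(
    task: str,
    *,
    L: int = params.L,
    L_a: int = params.L_A,
    q_A: float = 0.6,
    q_B: float = 0.5,
    q_S: float = 0.6,
    q_N: float = 0.0,
    Q: np.ndarray | None = None,
    nu_X: float = params.NU_X,
) -> ResponseMatrix:
    """Block response matrices for the standard tasks.

    ``minor_source``
        two sources: rows 0..L_a-1 respond to source A with q_A, the next
        L_a rows to source B with q_B, remaining rows are background.
    ``crosstalk``
        two sources with off-diagonal response q_N (crosstalk noise).
    ``four_source``
        four sources on a ring; each input group responds to its own
        source with q_S and to the two neighbours with q_N, so that
        C = QQ^t has diagonal q_S^2 + 2 q_N^2.
    ``custom``
        pass an explicit Q.
    """
    if task == "custom":
        if Q is None:
            raise ValueError("custom task needs an explicit Q")
        return ResponseMatrix(np.asarray(Q, float), nu_X=nu_X, group_size=L_a)

    n_groups = {"minor_source": 2, "crosstalk": 2, "four_source": 4}.get(task)
    if n_groups is None:
        raise ValueError(f"unknown task {task!r}")
    if L_a <= 0 or n_groups * L_a > L:
        raise ValueError("group size inconsistent with L")

    Qm = np.zeros((L, n_groups))
    if task == "minor_source":
        Qm[:L_a, 0] = q_A
        Qm[L_a : 2 * L_a, 1] = q_B
    elif task == "crosstalk":
        Qm[:L_a, 0] = q_S
        Qm[:L_a, 1] = q_N
        Qm[L_a : 2 * L_a, 0] = q_N
        Qm[L_a : 2 * L_a, 1] = q_S
    else:  # four_source ring
        for g in range(4):
            rows = slice(g * L_a, (g + 1) * L_a)
            Qm[rows, g] = q_S
            Qm[rows, (g - 1) % 4] = q_N
            Qm[rows, (g + 1) % 4] = q_N
    return ResponseMatrix(Qm, nu_X=nu_X, group_size=L_a)


def correlation_matrix(rm: ResponseMatrix, by_group: bool = False) -> np.ndarray:
    """Input correlation-strength matrix C = Q Q^t.

    With ``by_group=True`` the matrix is reduced to one row/column per
    input group of size ``rm.group_size`` (taking the representative row
    of each block), matching the compact form used in the two-source and
    four-source task descriptions.
    """
    Q = rm.Q
    if by_group:
        if not rm.group_size:
            raise ValueError("response matrix has no group structure")
        Q = Q[:: rm.group_size]
        # keep only groups, drop background remainder rows of zeros beyond
        n_groups = int(np.ceil(rm.L / rm.group_size))
        Q = Q[:n_groups]
    return Q @ Q.T


# --------------------------------------------------------------------------
# auditory scenes for blind source separation
# --------------------------------------------------------------------------

# four artificial sources: fundamental frequencies (Hz), their amplitudes,
# harmonic weights, envelope oscillation frequencies (Hz), amplitudes and
# phase delays (s)
_F_H = [[523.3, 784.0], [587.4, 880.0], [650.0, 830.6], [698.5, 932.4]]
_A_H = [[0.6, 0.4], [0.3, 0.7], [0.5, 0.5], [0.9, 0.3]]
_B_H = [
    [1.0, 0.5, 0.2, 0.1],
    [1.0, 0.5, 0.3, 0.2],
    [1.0, 0.1, 1.0, 0.8],
    [1.0, 0.8, 0.1, 0.1],
]
_F_L = [
    [0.4, 5.0, 10.0, 40.0, 88.0],
    [0.6, 6.0, 8.0, 42.0, 86.0],
    [0.2, 4.0, 7.5, 44.0, 84.0],
    [0.3, 6.0, 7.0, 46.0, 82.0],
]
_A_L = [
    [0.3, 0.4, 0.2, 0.5, 0.5],
    [0.25, 0.5, 0.2, 0.5, 0.5],
    [0.24, 0.3, 0.4, 0.5, 0.5],
    [0.61, 0.2, 0.2, 0.5, 0.5],
]
_D_L = [
    [1.0, 0.25, 0.65, 0.17, 0.01],
    [3.0, 0.12, 0.32, 0.13, 0.02],
    [7.8, 0.55, 0.40, 0.11, 0.03],
    [4.5, 0.22, 0.71, 0.07, 0.05],
]


@dataclass(frozen=True)
class AuditoryScene:
    """Parameters of the synthetic auditory mixture.

    Each source q has a harmonic spectrum a_h^q(f) (sum of Gaussians of
    width sigma_hf*k centred on harmonics k*f_h) and a slowly varying
    non-negative envelope a_l^q(t) (exponential of a sum of cosines).
    Input neuron i prefers frequency f_i on a log-spaced grid; its
    response probability is q_i(t) = q_o * sum_q a_l^q(t) a_h^q(f_i).
    """

    f_h: tuple = tuple(map(tuple, _F_H))
    a_h: tuple = tuple(map(tuple, _A_H))
    b_h: tuple = tuple(map(tuple, _B_H))
    sigma_hf: float = 20.0
    f_l: tuple = tuple(map(tuple, _F_L))
    a_l: tuple = tuple(map(tuple, _A_L))
    delta_l: tuple = tuple(map(tuple, _D_L))
    beta_l: float = 5.0
    Z_l: float = 27.24
    f_min: float = 500.0
    f_max: float = 4500.0
    L: int = params.L
    q_o: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        if len(self.f_h) != len(self.f_l):
            raise ValueError("inconsistent source counts")

    @property
    def n_sources(self) -> int:
        return len(self.f_h)

    def freq_grid(self) -> np.ndarray:
        """Log-spaced preferred frequencies f_i, i = 1..L (Hz)."""
        i = np.arange(1, self.L + 1)
        return np.exp(
            i / self.L * (np.log(self.f_max) - np.log(self.f_min))
            + np.log(self.f_min)
        )

    def spectrum(self, q: int, f) -> np.ndarray:
        """Harmonic spectrum a_h^q(f): Gaussians at k*f_h with width k*sigma."""
        f = np.asarray(f, dtype=float)
        out = np.zeros_like(f)
        for fh, ah in zip(self.f_h[q], self.a_h[q]):
            for k, bk in enumerate(self.b_h[q], start=1):
                sig = k * self.sigma_hf
                out += (
                    ah
                    * bk
                    / (np.sqrt(2 * np.pi) * sig)
                    * np.exp(-((f - k * fh) ** 2) / (2 * sig**2))
                )
        return out

    def envelope(self, q: int, t) -> np.ndarray:
        """Low-frequency envelope a_l^q(t) >= 0, t in seconds."""
        t = np.asarray(t, dtype=float)
        arg = np.zeros_like(t)
        for fl, al, dl in zip(self.f_l[q], self.a_l[q], self.delta_l[q]):
            arg += al * np.cos(2 * np.pi * fl * (t - dl))
        return np.exp(self.beta_l * arg) / self.Z_l


def synth_auditory_scene(
    scene: AuditoryScene,
    T: float,
    dt_env: float = 1.0,
    dt_audio: float = 0.025,
    waveform: bool = False,
):
    """Synthesize the auditory mixture.

    Parameters
    ----------
    T : duration in ms.
    dt_env : grid step (ms) for envelopes and response probabilities.
    dt_audio : grid step (ms) for the mixed waveform (only if requested).
    waveform : also synthesize the audio-rate mixture a(t).

    Returns a dict with the envelope matrix ``env`` (n_sources, n_t), the
    spectra sampled on the neuron frequency grid ``spec`` (n_sources, L),
    the response probabilities ``q_t`` (L, n_t) clipped to [0, 1], the
    envelope time axis ``t`` (ms), and optionally ``audio``/``t_audio``.
    """
    rng = np.random.default_rng(scene.seed)
    # per-source carrier delay, uniform on [0, 1/f_min] (seconds)
    delta_f = rng.uniform(0.0, 1.0 / scene.f_min, size=scene.n_sources)

    t_ms = np.arange(0.0, T, dt_env)
    t_s = t_ms / params.MS_PER_S
    env = np.stack([scene.envelope(q, t_s) for q in range(scene.n_sources)])
    f_i = scene.freq_grid()
    spec = np.stack([scene.spectrum(q, f_i) for q in range(scene.n_sources)])

    q_t = scene.q_o * (spec.T @ env)  # (L, n_t)
    if np.any(q_t > 1.0):
        warnings.warn("response probabilities clipped at 1", stacklevel=2)
    q_t = np.clip(q_t, 0.0, 1.0)

    out = {"t": t_ms, "env": env, "spec": spec, "q_t": q_t, "delta_f": delta_f}
    if waveform:
        ta_s = np.arange(0.0, T, dt_audio) / params.MS_PER_S
        envs_a = np.stack(
            [scene.envelope(q, ta_s) for q in range(scene.n_sources)]
        )
        audio = np.zeros_like(ta_s)
        for q in range(scene.n_sources):
            carrier = spec[q] @ np.cos(
                2 * np.pi * f_i[:, None] * (ta_s[None, :] - delta_f[q])
            )
            audio += envs_a[q] * carrier
        out["audio"] = audio
        out["t_audio"] = ta_s * params.MS_PER_S
    return out


# --------------------------------------------------------------------------
# plain-text spike I/O
# --------------------------------------------------------------------------

def write_spikes_text(path, neuron_ids, times_ms, header: bool = True) -> None:
    """Write spikes as two-column text: neuron_id time_ms."""
    arr = np.column_stack([np.asarray(neuron_ids), np.asarray(times_ms)])
    hdr = "neuron_id time_ms" if header else ""
    np.savetxt(path, arr, fmt=["%d", "%.4f"], header=hdr)


def read_spikes_text(path):
    arr = np.loadtxt(path, ndmin=2)
    if arr.size == 0:
        return np.empty(0, int), np.empty(0, float)
    return arr[:, 0].astype(int), arr[:, 1]
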