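"""Analytic layer: correlation kernels, g-coefficients and the mean field.

Input neurons that share a hidden source have a cross-correlation
C_il(s) = nu_S * sum_mu q_imu q_lmu * h(s), where h is the autocorrelation
of the response kernel phi. Filtering h through the PSP kernels, the
synaptic delays and the STDP window yields scalar coefficients that
measure how input correlation drives mean synaptic drift:

* G1X(w): direct feedforward route (input -> output, one EPSP).
* G2X(w): the route through the inhibitory loop (input -> output ->
  inhibitory -> output); it enters with a minus sign, so positive G2X
  means correlation routed through lateral inhibition causes LTD.
* g1Y, g1Z: the corresponding coefficients for the lateral E-to-I and
  feedback I-to-E connections under a weight-independent STDP window.

Because the log-STDP window factorizes as F(w, s) = f_p(w) e^{-s/tau_p}
(s >= 0) and f_d(w) e^{s/tau_d} (s < 0), each G(w) is an exact linear
combination f_p(w) * I_p + f_d(w) * I_d of two weight-independent
integrals, which this module evaluates once on a fine grid.

The two-source mean field reduces the network to four group weights
(w_1A, w_1B, w_2A, w_2B). Lateral inhibition enters the reduced system
only through the dimensionless loop gain

    P = g_E * g_I * M_a * w_Y * N_a * w_Z   (P < 1),

the gain of the output -> inhibitory -> output feedback loop. Under the
package's linear-gain convention (g_E = g_I = 1e-3) the I/E weight ratio
N_a w_Z / (L w_o^X) expressed in percent equals 100 * P.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.signal import fftconvolve

from . import params
from .plasticity import STDPConfig, lateral_window, log_stdp_fd, log_stdp_fp
from .simulator import make_epsp_kernel

__all__ = [
    "TheoryConfig",
    "KernelCoefficients",
    "MeanFieldParams",
    "FixedPoint",
    "h_closed_form",
    "chi1X",
    "chi2X",
    "G1X",
    "G2X",
    "kernel_coefficients",
    "g1Y",
    "g1Z",
    "Fbar",
    "meanfield_rhs",
    "inhibitory_rates",
    "find_fixed_points",
    "bistability_sweep",
    "multistability_onset",
    "specialization_index",
]


def h_closed_form(tau, theta_t: float = params.THETA_T, kind: str = "gamma3"):
    """Input cross-correlation density h(tau) (1/ms): autocorrelation of phi.

    gamma3 kernel: h = (tau^2 + 3 theta|tau| + 3 theta^2) e^{-|tau|/theta}
    / (16 theta^3); exponential kernel: h = e^{-|tau|/theta} / (2 theta).
    Symmetric with unit integral.
    """
    if theta_t <= 0:
        raise ValueError("theta_t must be positive")
    a = np.abs(np.asarray(tau, dtype=float))
    if kind == "gamma3":
        return (a**2 + 3 * theta_t * a + 3 * theta_t**2) * np.exp(-a / theta_t) / (
            16 * theta_t**3
        )
    if kind == "exponential":
        return np.exp(-a / theta_t) / (2 * theta_t)
    raise ValueError(f"unknown kernel {kind!r}")


# --------------------------------------------------------------------------
# grid functions
# --------------------------------------------------------------------------

class _GridFun:
    """A sampled function on a uniform time grid, supporting convolution."""

    __slots__ = ("t0", "dt", "v")

    def __init__(self, t0: float, dt: float, v: np.ndarray):
        self.t0, self.dt, self.v = float(t0), float(dt), np.asarray(v, float)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.v))

    def conv(self, other: "_GridFun") -> "_GridFun":
        v = fftconvolve(self.v, other.v) * self.dt
        return _GridFun(self.t0 + other.t0, self.dt, v)

    def flip(self) -> "_GridFun":
        t_end = self.t0 + self.dt * (len(self.v) - 1)
        return _GridFun(-t_end, self.dt, self.v[::-1])

    def shift(self, s: float) -> "_GridFun":
        return _GridFun(self.t0 + s, self.dt, self.v)

    def __call__(self, t):
        return np.interp(np.asarray(t, float), self.t, self.v, left=0.0, right=0.0)

    def weighted_integral(self, weight) -> float:
        return float(np.trapezoid(weight(self.t) * self.v, dx=self.dt))

    def window_integral(self, window) -> float:
        """Integral of window(t) * self(t) for a window with a jump at 0.

        Integrates the two branches separately with an interpolated sample
        exactly at t = 0, avoiding the trapezoid bias across the jump.
        """
        t, v = self.t, self.v
        v0 = float(np.interp(0.0, t, v))
        pos = t > 0
        neg = t < 0
        t_pos = np.concatenate(([0.0], t[pos]))
        v_pos = np.concatenate(([v0], v[pos]))
        t_neg = np.concatenate((t[neg], [0.0]))
        v_neg = np.concatenate((v[neg], [v0]))
        # evaluate the negative branch limit just below zero
        t_neg_eval = np.where(t_neg == 0.0, -1e-12, t_neg)
        return float(np.trapezoid(window(t_pos) * v_pos, t_pos)
                     + np.trapezoid(window(t_neg_eval) * v_neg, t_neg))


@dataclass(frozen=True)
class TheoryConfig:
    """Kernel-level parameters entering the analytic coefficients.

    Delays are the scalar (midpoint) values used in the analytics; the
    full per-synapse delay distributions matter only for simulation.
    """

    theta_t: float = params.THETA_T
    kernel: str = "gamma3"
    tauA_X: float = params.TAU_A_X
    tauB_X: float = params.TAU_B_X
    tauA_Y: float = params.TAU_A_Y
    tauB_Y: float = params.TAU_B_Y
    tauA_Z: float = params.TAU_A_Z
    tauB_Z: float = params.TAU_B_Z
    d_Xd: float = 0.5 * (params.D_XD_MIN + params.D_XD_MAX)
    d_Y: float = 0.5 * (params.D_Y_MIN + params.D_Y_MAX)
    d_Z: float = 0.5 * (params.D_Z_MIN + params.D_Z_MAX)
    stdp: STDPConfig = field(default_factory=STDPConfig)
    dt_grid: float = 0.02
    span_factor: float = 30.0

    @property
    def D(self) -> float:
        """Total loop delay 2 d_Xd + d_Y + d_Z of the inhibition route."""
        return 2 * self.d_Xd + self.d_Y + self.d_Z


def _normalized(g: _GridFun) -> tuple[_GridFun, float]:
    """Rescale a unit-area kernel grid to exact unit trapezoid mass.

    Returns the normalized grid and the pre-normalization mass deviation
    (truncation tail + quadrature bias at the onset kink)."""
    mass = float(np.trapezoid(g.v, dx=g.dt))
    return _GridFun(g.t0, g.dt, g.v / mass), abs(mass - 1.0)


def _eps_grid(cfg: TheoryConfig, tauA, tauB) -> tuple[_GridFun, float]:
    t_max = cfg.span_factor * tauA
    t = np.arange(0.0, t_max, cfg.dt_grid)
    return _normalized(_GridFun(0.0, cfg.dt_grid, make_epsp_kernel(tauA, tauB)(t)))


def _h_grid(cfg: TheoryConfig) -> tuple[_GridFun, float]:
    t_max = cfg.span_factor * cfg.theta_t
    t = np.arange(-t_max, t_max + cfg.dt_grid / 2, cfg.dt_grid)
    return _normalized(
        _GridFun(t[0], cfg.dt_grid, h_closed_form(t, cfg.theta_t, cfg.kernel))
    )


@dataclass(frozen=True)
class KernelCoefficients:
    """Weight-independent integrals behind G1X(w) and G2X(w).

    G1X(w) = f_p(w) I1_p + f_d(w) I1_d; G2X likewise with I2_*. ``g1X``
    and ``g2X`` are the values at the reference weight w_o, and
    kappa = g2X / g1X.
    """

    I1_p: float
    I1_d: float
    I2_p: float
    I2_d: float
    stdp: STDPConfig
    mass_err: float

    def G1X(self, w):
        return (
            log_stdp_fp(w, self.stdp.w_o, self.stdp.beta, self.stdp.C_p) * self.I1_p
            + log_stdp_fd(w, self.stdp.w_o, self.stdp.alpha, self.stdp.C_d) * self.I1_d
        )

    def G2X(self, w):
        return (
            log_stdp_fp(w, self.stdp.w_o, self.stdp.beta, self.stdp.C_p) * self.I2_p
            + log_stdp_fd(w, self.stdp.w_o, self.stdp.alpha, self.stdp.C_d) * self.I2_d
        )

    @property
    def g1X(self) -> float:
        return float(self.G1X(self.stdp.w_o))

    @property
    def g2X(self) -> float:
        return float(self.G2X(self.stdp.w_o))

    @property
    def kappa(self) -> float:
        return self.g2X / self.g1X


def _pd_integrals(A: _GridFun, tau_p: float, tau_d: float):
    """(I_p, I_d): A integrated against the two exponential window branches.

    Each branch is integrated on its own side of zero, with an interpolated
    sample exactly at zero (the STDP window is discontinuous there).
    """
    t, v = A.t, A.v
    v0 = float(np.interp(0.0, t, v))
    pos, neg = t > 0, t < 0
    t_pos = np.concatenate(([0.0], t[pos]))
    v_pos = np.concatenate(([v0], v[pos]))
    t_neg = np.concatenate((t[neg], [0.0]))
    v_neg = np.concatenate((v[neg], [v0]))
    I_p = float(np.trapezoid(np.exp(-t_pos / tau_p) * v_pos, t_pos))
    I_d = float(np.trapezoid(np.exp(t_neg / tau_d) * v_neg, t_neg))
    return I_p, I_d


def kernel_coefficients(cfg: TheoryConfig = TheoryConfig()) -> KernelCoefficients:
    """Evaluate the feedforward correlation-kernel integrals on the grid."""
    eps_X, e1 = _eps_grid(cfg, cfg.tauA_X, cfg.tauB_X)
    eps_Y, e2 = _eps_grid(cfg, cfg.tauA_Y, cfg.tauB_Y)
    eps_Z, e3 = _eps_grid(cfg, cfg.tauA_Z, cfg.tauB_Z)
    h, e4 = _h_grid(cfg)

    # pre-normalization mass deviation of the truncated grids
    mass_err = max(e1, e2, e3, e4)
    if mass_err > 1e-3:
        raise RuntimeError(f"kernel grid too short: mass error {mass_err:.2e}")

    # A1(s) = int eps_X(r) h(r - s + 2 d_Xd) dr = (eps_X * h)(s - 2 d_Xd)
    # (h is even, so correlation against h equals convolution with h)
    A1 = eps_X.conv(h).shift(2 * cfg.d_Xd)
    # A2(s) = int psi(v) h(v - s + D) dv with psi = eps_X * eps_Y * eps_Z
    psi = eps_X.conv(eps_Y).conv(eps_Z)
    A2 = psi.conv(h).shift(cfg.D)

    I1_p, I1_d = _pd_integrals(A1, cfg.stdp.tau_p, cfg.stdp.tau_d)
    I2_p, I2_d = _pd_integrals(A2, cfg.stdp.tau_p, cfg.stdp.tau_d)
    return KernelCoefficients(I1_p, I1_d, I2_p, I2_d, cfg.stdp, mass_err)


def _window_pieces(cfg: TheoryConfig, w: float):
    st = cfg.stdp
    fp = float(log_stdp_fp(w, st.w_o, st.beta, st.C_p))
    fd = float(log_stdp_fd(w, st.w_o, st.alpha, st.C_d))
    return fp, fd, st.tau_p, st.tau_d


def chi1X(tau, w: float, cfg: TheoryConfig = TheoryConfig()):
    """Direct correlation kernel chi_1^X(tau; w).

    chi_1 weights the input correlation at lag tau by the STDP window
    after one feedforward EPSP and twice the dendritic delay:
    chi_1(tau) = int_0^inf eps_X(u) F(w, u - tau + 2 d_Xd) du.
    """
    eps_X, _ = _eps_grid(cfg, cfg.tauA_X, cfg.tauB_X)
    fp, fd, tau_p, tau_d = _window_pieces(cfg, w)
    tau = np.atleast_1d(np.asarray(tau, float))
    u = eps_X.t
    out = np.empty_like(tau)
    for i, tv in enumerate(tau):
        s = u - tv + 2 * cfg.d_Xd
        F = np.where(s >= 0, fp * np.exp(-s / tau_p), fd * np.exp(s / tau_d))
        out[i] = np.trapezoid(eps_X.v * F, dx=eps_X.dt)
    return out if out.size > 1 else float(out[0])


def chi2X(tau, w: float, cfg: TheoryConfig = TheoryConfig()):
    """Loop correlation kernel chi_2^X(tau; w) (enters learning as -chi_2).

    Same as chi_1 but the correlation travels through the full inhibitory
    loop: the EPSP cascade eps_X * eps_Y * eps_Z delayed by
    D = 2 d_Xd + d_Y + d_Z.
    """
    eps_X, _ = _eps_grid(cfg, cfg.tauA_X, cfg.tauB_X)
    eps_Y, _ = _eps_grid(cfg, cfg.tauA_Y, cfg.tauB_Y)
    eps_Z, _ = _eps_grid(cfg, cfg.tauA_Z, cfg.tauB_Z)
    psi = eps_X.conv(eps_Y).conv(eps_Z)
    fp, fd, tau_p, tau_d = _window_pieces(cfg, w)
    tau = np.atleast_1d(np.asarray(tau, float))
    out = np.empty_like(tau)
    for i, tv in enumerate(tau):
        s = psi.t - tv + cfg.D
        F = np.where(s >= 0, fp * np.exp(-s / tau_p), fd * np.exp(s / tau_d))
        out[i] = np.trapezoid(psi.v * F, dx=psi.dt)
    return out if out.size > 1 else float(out[0])


def G1X(w, cfg: TheoryConfig = TheoryConfig(),
        coeffs: KernelCoefficients | None = None):
    """Direct correlation coefficient G_1^X(w) = int chi_1(tau; w) h(tau) dtau."""
    coeffs = coeffs or kernel_coefficients(cfg)
    return coeffs.G1X(w)


def G2X(w, cfg: TheoryConfig = TheoryConfig(),
        coeffs: KernelCoefficients | None = None):
    """Loop correlation coefficient G_2^X(w) = int chi_2(tau; w) h(tau) dtau."""
    coeffs = coeffs or kernel_coefficients(cfg)
    return coeffs.G2X(w)


def _lateral_coeff(cfg: TheoryConfig, window, route: str) -> float:
    """Common machinery for g1Y / g1Z.

    Both coefficients integrate h over a lag distribution built from PSP
    kernels, windowed by the lateral STDP rule F^Q(s).
    """
    eps_X, _ = _eps_grid(cfg, cfg.tauA_X, cfg.tauB_X)
    eps_Y, _ = _eps_grid(cfg, cfg.tauA_Y, cfg.tauB_Y)
    # m(b): density of (u + r') - r with u ~ eps_Y, r', r ~ eps_X
    rho = eps_Y.conv(eps_X)
    m = rho.conv(eps_X.flip())
    h, _ = _h_grid(cfg)
    if route == "Y":
        # g1Y = int ds F^Y(s) int m(b) h(b - s) db = int F(s) (m*h)(s) ds
        B = m.conv(h)
    elif route == "Z":
        # g1Z uses the reversed lag shifted by the loop delay d_Y + d_Z
        B = m.flip().conv(h).shift(-(cfg.d_Y + cfg.d_Z))
    else:
        raise ValueError(route)
    return B.window_integral(window)


def g1Y(cfg: TheoryConfig = TheoryConfig(), rule: str = "hebbian",
        tau_p: float = params.TAU_PD_LATERAL, tau_d: float = params.TAU_PD_LATERAL,
        gamma: float = params.GAMMA_Y) -> float:
    """E-to-I correlation coefficient; positive favours feature-selective
    inhibitory neurons, negative favours unstructured E-to-I weights."""
    return _lateral_coeff(cfg, lateral_window(rule, tau_p, tau_d, gamma), "Y")


def g1Z(cfg: TheoryConfig = TheoryConfig(), rule: str = "hebbian",
        tau_p: float = params.TAU_PD_LATERAL, tau_d: float = params.TAU_PD_LATERAL,
        gamma: float = params.GAMMA_Z) -> float:
    """I-to-E correlation coefficient; negative favours non-reciprocal wiring
    (mutual inhibition between output groups), positive favours reciprocal."""
    return _lateral_coeff(cfg, lateral_window(rule, tau_p, tau_d, gamma), "Z")


def Fbar(w, stdp: STDPConfig = STDPConfig()):
    """Area of the STDP window, F̄(w) = f_p(w) tau_p + f_d(w) tau_d.

    This is the homeostatic drift per pre-post rate product: positive at
    small weights, negative beyond the balance point.
    """
    return (
        log_stdp_fp(w, stdp.w_o, stdp.beta, stdp.C_p) * stdp.tau_p
        + log_stdp_fd(w, stdp.w_o, stdp.alpha, stdp.C_d) * stdp.tau_d
    )


# --------------------------------------------------------------------------
# two-source mean field
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanFieldParams:
    """Reduced parameters of the two-source mean field.

    The state is (w_1A, w_1B, w_2A, w_2B): mean feedforward weights from
    the A/B input groups onto output groups 1 and 2. Background weights
    stay at w_o. Lateral inhibition enters only through the loop gain
    ``P = gain_E*gain_I*M_a*w_Y*N_a*w_Z``; ``with_loop_gain`` builds a
    parameter set whose per-synapse w_Z realizes a requested P.
    """

    coeffs: KernelCoefficients
    q_A: float = 0.6
    q_B: float = 0.5
    L_a: int = params.L_A
    n_bg_groups: int = 2
    w_o_X: float = params.W_O_X
    nu_S: float = params.NU_S
    nu_X: float = params.NU_X
    M_a: int = params.M_A
    N_a: int = params.N_A
    w_Y: float = params.W_O_Y
    w_Z: float = params.W_O_Z
    gain_E: float = params.GAIN_E
    gain_I: float = params.GAIN_I

    @property
    def loop_gain(self) -> float:
        return self.gain_E * self.gain_I * self.M_a * self.w_Y * self.N_a * self.w_Z

    @property
    def L(self) -> int:
        return self.L_a * (2 + self.n_bg_groups)

    def with_loop_gain(self, P: float) -> "MeanFieldParams":
        w_Z = P / (self.gain_E * self.gain_I * self.M_a * self.w_Y * self.N_a)
        return replace(self, w_Z=w_Z)

    @property
    def ie_ratio_percent(self) -> float:
        """I/E weight balance N_a w_Z / (L w_o^X), in percent."""
        return 100.0 * self.N_a * self.w_Z / (self.L * self.w_o_X)


def inhibitory_rates(w, mf: MeanFieldParams):
    """Closed-form inhibitory group rates (nu_1^Z, nu_2^Z), in 1/ms.

    Solves the two-group balance: each inhibitory group is driven by its
    output group, which is excited by the inputs and inhibited by the
    other inhibitory group. Rates are rectified at 0; |P| == 1 is
    singular and perturbed by machine epsilon.
    """
    w1A, w1B, w2A, w2B = np.asarray(w, float)
    P = mf.loop_gain
    if abs(1.0 - P * P) < 1e-12:
        P *= 1.0 - 1e-9
    S1 = mf.L_a * (w1A + w1B + mf.n_bg_groups * mf.w_o_X)
    S2 = mf.L_a * (w2A + w2B + mf.n_bg_groups * mf.w_o_X)
    pref = mf.gain_I * mf.gain_E * mf.M_a * mf.w_Y * mf.nu_X / (1.0 - P * P)
    nu1 = pref * (S1 - P * S2)
    nu2 = pref * (S2 - P * S1)
    return max(nu1, 0.0), max(nu2, 0.0)


def meanfield_rhs(w, mf: MeanFieldParams):
    """Mean weight velocity (dw_1A, dw_1B, dw_2A, dw_2B)/dt.

    Three contributions per weight: direct correlation drive
    (L_a nu_S c_nu G1(w) w), correlation routed through the inhibitory
    loop (-P L_a nu_S c_nu G2(w) w_other-group), and the homeostatic
    STDP drift F̄(w) * nu_X^2 * L_a * (S_mu - P S_mubar)/(1 - P^2). The
    overall learning rate and the output gain factor scale time only and
    are omitted.
    """
    w_raw = np.asarray(w, float)
    w = np.clip(w_raw, 0.0, None)  # weights are rectified at zero
    c = np.array([mf.q_A**2, mf.q_B**2])
    P = mf.loop_gain
    if abs(1.0 - P * P) < 1e-12:
        P *= 1.0 - 1e-9
    S = np.array(
        [
            w[0] + w[1] + mf.n_bg_groups * mf.w_o_X,
            w[2] + w[3] + mf.n_bg_groups * mf.w_o_X,
        ]
    )
    out = np.empty(4)
    for mu in range(2):
        for nu in range(2):
            i = 2 * mu + nu
            j = 2 * (1 - mu) + nu
            corr = mf.L_a * mf.nu_S * c[nu] * (
                mf.coeffs.G1X(w[i]) * w[i] - P * mf.coeffs.G2X(w[i]) * w[j]
            )
            homeo = (
                Fbar(w[i], mf.coeffs.stdp)
                * mf.nu_X**2
                * mf.L_a
                * (S[mu] - P * S[1 - mu])
                / (1.0 - P * P)
            )
            out[i] = corr + homeo
    # restoring pull toward the admissible region for root searches that
    # step below zero; vanishes for w >= 0
    out += np.minimum(w_raw, 0.0)
    return out


@dataclass(frozen=True)
class FixedPoint:
    w: np.ndarray
    stable: bool
    eigvals: np.ndarray

    @property
    def w_SI(self) -> int:
        return specialization_index(*self.w)


def _jacobian(fun, x, eps=1e-6):
    x = np.asarray(x, float)
    J = np.empty((x.size, x.size))
    for k in range(x.size):
        dx = np.zeros_like(x)
        dx[k] = eps * max(1.0, abs(x[k]))
        J[:, k] = (fun(x + dx) - fun(x - dx)) / (2 * dx[k])
    return J


def find_fixed_points(
    mf: MeanFieldParams,
    grid=None,
    w_max: float = 25.0,
    dedup_tol: float = 1e-3,
) -> list[FixedPoint]:
    """All fixed points of the mean field found by multi-start root search.

    Starts are taken from a coarse grid over the four weights (symmetric,
    specialized and mixed patterns), polished with a hybrid Newton solver,
    deduplicated, and labelled stable when every Jacobian eigenvalue has a
    negative real part.
    """
    if grid is None:
        grid = np.array([0.5, 2.0, 5.0, 9.0, 13.0, 17.0, 22.0])
    fun = lambda w: meanfield_rhs(w, mf)

    starts = []
    for a, b in itertools.product(grid, repeat=2):
        starts.append((a, b, a, b))   # symmetric
        starts.append((a, b, b, a))   # anti-symmetric
    for a, b, cc in itertools.product(grid[::2], repeat=3):
        starts.append((a, b, cc, a))
    roots: list[np.ndarray] = []
    for s in starts:
        sol = optimize.root(fun, np.asarray(s, float), method="hybr",
                            options={"xtol": 1e-12})
        if not sol.success:
            continue
        w = sol.x
        if np.any(w < -1e-6) or np.any(w > 10 * w_max):
            continue
        if np.max(np.abs(fun(w))) > 1e-9:
            continue
        if any(np.linalg.norm(w - r) < dedup_tol * (1 + np.linalg.norm(r))
               for r in roots):
            continue
        roots.append(w)

    fps = []
    for w in roots:
        eig = np.linalg.eigvals(_jacobian(fun, w))
        fps.append(FixedPoint(w=w, stable=bool(np.all(eig.real < 0)), eigvals=eig))
    fps.sort(key=lambda f: (f.w[0] - f.w[2]))
    return fps


def specialization_index(w1A, w1B, w2A, w2B) -> int:
    """Sign of (w_1A - w_1B)(w_2B - w_2A): +1 winners-share-all (the two
    output groups specialize on different sources), -1 winner-take-all,
    0 at exact ties."""
    s = (w1A - w1B) * (w2B - w2A)
    return 0 if s == 0 else int(np.sign(s))


def _classify(fps: list[FixedPoint]) -> str:
    stable_idx = {fp.w_SI for fp in fps if fp.stable}
    has_S = +1 in stable_idx
    has_T = (-1 in stable_idx) or (0 in stable_idx)
    if has_S and has_T:
        return "bistable"
    if has_S:
        return "S_only"
    if has_T:
        return "T_only"
    return "none"


def bistability_sweep(mf: MeanFieldParams, P_values) -> list[dict]:
    """Classify the learning regime along a sweep of the loop gain P.

    Returns one record per P with the regime label ('T_only', 'bistable',
    'S_only'), the fixed points, and the I/E ratio in percent.
    """
    out = []
    for P in np.asarray(P_values, float):
        m = mf.with_loop_gain(P)
        fps = find_fixed_points(m)
        out.append(
            {
                "P": float(P),
                "ie_ratio_percent": m.ie_ratio_percent,
                "regime": _classify(fps),
                "fixed_points": fps,
            }
        )
    return out


def multistability_onset(
    mf: MeanFieldParams, lo: float = 0.02, hi: float = 0.5, tol: float = 5e-4
) -> float:
    """Smallest loop gain P at which stable winners-share-all states exist,
    located by bisection on the sweep classification."""
    def has_S(P):
        fps = find_fixed_points(mf.with_loop_gain(P))
        return any(fp.stable and fp.w_SI == +1 for fp in fps)

    if has_S(lo):
        return lo
    if not has_S(hi):
        raise RuntimeError("no multistability found below hi")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_S(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
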