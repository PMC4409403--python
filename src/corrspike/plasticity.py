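"""Synaptic learning rules.

Feedforward synapses use pairwise log-STDP: every (pre, post) spike pair
contributes an exponentially time-decayed weight change whose amplitude
depends on the current weight — LTP shrinks exponentially with w while the
LTD magnitude grows logarithmically, which keeps the weight distribution
long-tailed and the dynamics self-limiting.

Lateral (E-to-I and I-to-E) synapses use weight-independent windows:
Hebbian, anti-Hebbian, and (anti-)correlation-detector variants.

Spike times entering a rule are *at-synapse* times: pre spikes are shifted
by the axonal delay and post spikes by the dendritic delay before pairing.
All-pairs pairing is used throughout; the online pre/post-trace
implementation is mathematically identical to the explicit double sum for
exponential windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import params

__all__ = [
    "STDPConfig",
    "log_stdp_fp",
    "log_stdp_fd",
    "pair_update",
    "lateral_stdp_update",
    "lateral_window",
    "window_function",
    "LATERAL_RULES",
]

LATERAL_RULES = ("hebbian", "anti_hebbian", "corr_detector", "anti_corr_detector")
RULES = ("log_stdp",) + LATERAL_RULES


@dataclass(frozen=True)
class STDPConfig:
    """Parameters of one STDP rule.

    ``C_d`` defaults to ``gamma * C_p * tau_p / tau_d`` so that the areas
    under the LTP and LTD branches of the (weight-independent part of the)
    window cancel; gamma != 1 tilts that balance.
    """

    rule: str = "log_stdp"
    eta: float = params.ETA_X_FACTOR * params.W_O_X
    tau_p: float = params.TAU_P
    tau_d: float = params.TAU_D
    C_p: float = 1.0
    C_d: float | None = None
    alpha: float = params.ALPHA
    beta: float = params.BETA
    sigma_stdp: float = 0.0
    gamma: float = 1.0
    w_o: float = params.W_O_X
    w_min: float = 0.0
    w_max: float = 20.0 * params.W_O_X

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown STDP rule {self.rule!r}")
        if min(self.tau_p, self.tau_d) <= 0 or self.eta <= 0:
            raise ValueError("time constants and eta must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")
        if self.C_d is None:
            object.__setattr__(
                self, "C_d", self.gamma * self.C_p * self.tau_p / self.tau_d
            )


def _noise_factor(cfg: STDPConfig, rng) -> float:
    """Multiplicative amplitude noise (1 + sigma*xi), xi clipped at 1/sigma.

    The clip keeps the factor non-negative so noise never flips the sign
    of an update.
    """
    if cfg.sigma_stdp <= 0 or rng is None:
        return 1.0
    xi = np.clip(rng.standard_normal(), -1 / cfg.sigma_stdp, 1 / cfg.sigma_stdp)
    return 1.0 + cfg.sigma_stdp * xi


def log_stdp_fp(w, w_o: float = params.W_O_X, beta: float = params.BETA,
                C_p: float = 1.0, xi: float = 0.0, sigma: float = 0.0):
    """LTP amplitude f_p(w) = C_p (1 + sigma*xi) e^{-w/(beta*w_o)}."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return C_p * (1.0 + sigma * xi) * np.exp(-w / (beta * w_o))


def log_stdp_fd(w, w_o: float = params.W_O_X, alpha: float = params.ALPHA,
                C_d: float = 0.5, xi: float = 0.0, sigma: float = 0.0):
    """LTD amplitude f_d(w) = -C_d (1 + sigma*xi) log(1+alpha w/w_o)/log(1+alpha)."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return -C_d * (1.0 + sigma * xi) * np.log1p(alpha * w / w_o) / np.log1p(alpha)


def _amplitudes(cfg: STDPConfig, w: float):
    """(a_p, a_d) amplitude pair of the rule at weight w, noise-free.

    a_p/a_d multiply exp(-|dt|/tau_p) and exp(-|dt|/tau_d) on the
    post-after-pre side; (b_p, b_d) on the pre-after-post side. Returned
    as ((a_p, a_d), (b_p, b_d)).
    """
    if cfg.rule == "log_stdp":
        fp = float(log_stdp_fp(w, cfg.w_o, cfg.beta, cfg.C_p))
        fd = float(log_stdp_fd(w, cfg.w_o, cfg.alpha, cfg.C_d))
        return (fp, 0.0), (0.0, fd)
    if cfg.rule == "hebbian":
        return (cfg.C_p, 0.0), (0.0, -cfg.C_d)
    if cfg.rule == "anti_hebbian":
        # Hebbian with both branch signs flipped (and the LTP/LTD time
        # constants swapped role-for-role, as printed)
        return (0.0, -cfg.C_p), (cfg.gamma * cfg.tau_d / cfg.tau_p, 0.0)
    if cfg.rule == "corr_detector":
        r = cfg.tau_p / cfg.tau_d
        return (cfg.C_p, -cfg.C_p * r), (cfg.gamma * cfg.C_p, -cfg.gamma * cfg.C_p * r)
    if cfg.rule == "anti_corr_detector":
        r = cfg.tau_p / cfg.tau_d
        return (-cfg.C_p, cfg.C_p * r), (-cfg.gamma * cfg.C_p, cfg.gamma * cfg.C_p * r)
    raise ValueError(cfg.rule)


def window_function(cfg: STDPConfig, w: float = None) -> Callable:
    """The STDP window F(s): weight change density at pre->post lag s (ms).

    s > 0 means the post (at-synapse) spike follows the pre spike. The
    learning rate eta is not included. For ``log_stdp`` the current weight
    must be supplied.
    """
    if cfg.rule == "log_stdp" and w is None:
        raise ValueError("log_stdp window needs the current weight")
    (a_p, a_d), (b_p, b_d) = _amplitudes(cfg, w if w is not None else 0.0)

    def F(s):
        s = np.asarray(s, dtype=float)
        pos = a_p * np.exp(-s / cfg.tau_p) + a_d * np.exp(-s / cfg.tau_d)
        neg = b_p * np.exp(s / cfg.tau_p) + b_d * np.exp(s / cfg.tau_d)
        return np.where(s >= 0, pos, neg)

    return F


def lateral_window(rule: str, tau_p: float = params.TAU_PD_LATERAL,
                   tau_d: float = params.TAU_PD_LATERAL, gamma: float = 1.0,
                   C_p: float = 1.0) -> Callable:
    """Weight-independent lateral STDP window F^Q(s) for theory use."""
    cfg = STDPConfig(rule=rule, eta=1.0, tau_p=tau_p, tau_d=tau_d,
                     C_p=C_p, gamma=gamma)
    return window_function(cfg)


def pair_update(pre_times_syn, post_times_syn, cfg: STDPConfig, w: float,
                rng=None) -> float:
    """Total weight change from all (pre, post) pairs, at fixed weight w.

    ``pre_times_syn``/``post_times_syn`` are at-synapse spike times (ms),
    i.e. already shifted by the axonal/dendritic delays. Simultaneous
    at-synapse spikes pair as LTP. Implemented with online exponential
    traces (identical to the explicit all-pairs double sum); the caller
    clips ``w + dw`` to [w_min, w_max].

    With ``sigma_stdp > 0`` and an ``rng``, one multiplicative noise factor
    is drawn per pairing event (per spike that triggers an update), not
    per pair.
    """
    pre = np.sort(np.asarray(pre_times_syn, dtype=float))
    post = np.sort(np.asarray(post_times_syn, dtype=float))
    (a_p, a_d), (b_p, b_d) = _amplitudes(cfg, w)

    # merged event stream; pre events first at ties so that a tie pairs as LTP
    # (the pre spike is already in the trace when the post event fires) and
    # never as LTD (the post trace is updated after the pre's LTD step).
    events = [(t, 0) for t in pre] + [(t, 1) for t in post]
    events.sort(key=lambda e: (e[0], e[1]))

    tr_pre_p = tr_pre_d = 0.0   # pre traces at tau_p and tau_d
    tr_post_p = tr_post_d = 0.0
    t_last = -np.inf
    dw = 0.0
    for t, kind in events:
        if np.isfinite(t_last):
            decay = t - t_last
            tr_pre_p *= np.exp(-decay / cfg.tau_p)
            tr_pre_d *= np.exp(-decay / cfg.tau_d)
            tr_post_p *= np.exp(-decay / cfg.tau_p)
            tr_post_d *= np.exp(-decay / cfg.tau_d)
        t_last = t
        if kind == 0:  # pre at synapse: pair with earlier posts, then store
            dw += cfg.eta * _noise_factor(cfg, rng) * (
                b_p * tr_post_p + b_d * tr_post_d
            )
            tr_pre_p += 1.0
            tr_pre_d += 1.0
        else:          # post at synapse: pair with earlier (or tied) pres
            dw += cfg.eta * _noise_factor(cfg, rng) * (
                a_p * tr_pre_p + a_d * tr_pre_d
            )
            tr_post_p += 1.0
            tr_post_d += 1.0
    return dw


def lateral_stdp_update(rule: str, pre_times_syn, post_times_syn,
                        cfg: STDPConfig, rng=None) -> float:
    """Weight change at a lateral synapse under the given rule."""
    if rule not in LATERAL_RULES:
        raise ValueError(f"unknown lateral rule {rule!r}")
    if cfg.rule != rule:
        cfg = STDPConfig(rule=rule, eta=cfg.eta, tau_p=cfg.tau_p,
                         tau_d=cfg.tau_d, C_p=cfg.C_p, gamma=cfg.gamma,
                         sigma_stdp=cfg.sigma_stdp, w_max=cfg.w_max)
    return pair_update(pre_times_syn, post_times_syn, cfg, w=0.0, rng=rng)
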