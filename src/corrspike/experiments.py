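"""End-to-end experiment drivers.

Each driver binds stimuli -> simulator -> plasticity -> metrics for one
figure-level protocol, at two scales. ``full`` uses the long-run study
conditions (400 input neurons, 20+20 lateral neurons, 3000-4000 s).
``desk`` keeps the full network (per-synapse inhibitory weights, and with
them the shot-noise statistics of the feedback loop, depend on the layer
sizes, so shrinking the network changes the operating regime) but
compresses the slow learning dynamics: 1/10 of the duration at 10x the
learning rate preserves the expected total weight drift.

Every driver is deterministic given its seed and returns a plain dict of
artifacts; ``run_experiment`` optionally writes them to disk (config
snapshot, spike text files, metrics JSON, weight arrays).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import metrics, params, stimuli
from .bayes_ica import ICAState, run_learning, sample_discrete_stream
from .plasticity import STDPConfig
from .simulator import (
    LIFConfig,
    NetworkConfig,
    SimResult,
    run_lif,
    run_poisson,
    wire_lateral,
)
from .theory import (
    MeanFieldParams,
    TheoryConfig,
    bistability_sweep,
    kernel_coefficients,
    specialization_index,
)

__all__ = [
    "ExperimentSpec",
    "init_weights",
    "init_delays",
    "build_network",
    "run_experiment",
    "EXPERIMENTS",
    "group_mean_weights",
    "wz_for_loop_gain",
]

# lateral loop gains of the named inhibition levels (see theory module):
# with the full-size network these correspond to per-synapse w_Z = 10,
# 21.5 and 50
LOOP_GAINS = {"weak": 0.1, "moderate": 0.215, "strong": 0.5}

FULL_SIZES = dict(L=params.L, L_a=params.L_A, M=params.M, N=params.N,
                  M_a=params.M_A, N_a=params.N_A)
DESK_SIZES = dict(FULL_SIZES)


@dataclass(frozen=True)
class ExperimentSpec:
    """Name + scale + seed + parameter overrides of one protocol run."""

    name: str
    scale: str = "desk"
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("desk", "full"):
            raise ValueError("scale must be 'desk' or 'full'")

    def get(self, key, default=None):
        return self.overrides.get(key, default)


def init_weights(w_o: float, sigma_init: float, shape, seed=None,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Initial weights w_o (1 + sigma * zeta), zeta ~ N(0,1), clipped at 0."""
    rng = np.random.default_rng(seed)
    W = w_o * (1.0 + sigma_init * rng.standard_normal(shape))
    W = np.clip(W, 0.0, None)
    if mask is not None:
        W = W * mask
    return W


def init_delays(d_min: float, d_max: float, shape, seed=None) -> np.ndarray:
    """Per-synapse delays uniform on [d_min, d_max]."""
    if not 0 <= d_min <= d_max:
        raise ValueError("need 0 <= d_min <= d_max")
    rng = np.random.default_rng(seed)
    return d_min + (d_max - d_min) * rng.random(shape)


def wz_for_loop_gain(P: float, M_a: int, N_a: int,
                     w_Y: float = params.W_O_Y) -> float:
    """Per-synapse I-to-E weight realizing lateral loop gain P."""
    return P / (params.GAIN_E * params.GAIN_I * M_a * w_Y * N_a)


def build_network(
    seed: int,
    *,
    L: int = params.L,
    M: int = params.M,
    N: int = params.N,
    M_a: int = params.M_A,
    N_a: int = params.N_A,
    w_o_X: float = params.W_O_X,
    w_Y: float = params.W_O_Y,
    w_Z: float = params.W_O_Z,
    lateral_mode: str = "structured",
    sigma_init: float = params.SIGMA_W_INIT,
    lateral_random_init: bool = False,
    **_ignored,
) -> NetworkConfig:
    """Assemble a NetworkConfig with randomized weights and delays."""
    ss = np.random.SeedSequence(seed)
    s_w, s_d, s_l = ss.spawn(3)
    W_X = init_weights(w_o_X, sigma_init, (M, L), s_w)
    if lateral_random_init:
        # dense lateral wiring with randomized weights (plastic-lateral runs)
        rng = np.random.default_rng(s_l)
        W_Y = np.clip(w_Y * (1 + sigma_init * rng.standard_normal((N, M))), 0, None)
        W_Z = np.clip(w_Z * (1 + sigma_init * rng.standard_normal((M, N))), 0, None)
    else:
        W_Y, W_Z = wire_lateral(lateral_mode, M=M, N=N, M_a=M_a, N_a=N_a,
                                w_Y=w_Y, w_Z=w_Z, seed=s_l)
    rng_d = np.random.default_rng(s_d)
    d_Xa = init_delays(params.D_XA_MIN, params.D_XA_MAX, (M, L), rng_d)
    d_Xd = init_delays(params.D_XD_MIN, params.D_XD_MAX, (M, L), rng_d)
    d_Y = init_delays(params.D_Y_MIN, params.D_Y_MAX, (N, M), rng_d)
    d_Z = init_delays(params.D_Z_MIN, params.D_Z_MAX, (M, N), rng_d)
    return NetworkConfig(W_X=W_X, W_Y=W_Y, W_Z=W_Z,
                         d_Xa=d_Xa, d_Xd=d_Xd, d_Y=d_Y, d_Z=d_Z,
                         M_a=M_a, N_a=N_a)


def group_mean_weights(W_X: np.ndarray, M_a: int, L_a: int,
                       n_in_groups: int = 2) -> np.ndarray:
    """Block means of W_X: (output groups, first n_in_groups input groups)."""
    M = W_X.shape[0]
    out = np.empty((M // M_a, n_in_groups))
    for g in range(M // M_a):
        for a in range(n_in_groups):
            out[g, a] = W_X[g * M_a : (g + 1) * M_a,
                            a * L_a : (a + 1) * L_a].mean()
    return out


def _conditions(spec: ExperimentSpec, T_full: float = 3000.0e3):
    """(sizes, T_ms, eta_scale) for the requested scale."""
    if spec.scale == "full":
        sizes = dict(FULL_SIZES)
        T = float(spec.get("T_ms", T_full))
        eta_scale = 1.0
    else:
        sizes = dict(DESK_SIZES)
        T = float(spec.get("T_ms", 300.0e3))
        eta_scale = float(spec.get("eta_scale", 10.0))
    sizes.update({k: spec.overrides[k] for k in FULL_SIZES if k in spec.overrides})
    return sizes, T, eta_scale


def _stdp_X(eta_scale: float, sigma: float = params.SIGMA_STDP) -> STDPConfig:
    return STDPConfig(rule="log_stdp",
                      eta=params.ETA_X_FACTOR * params.W_O_X * eta_scale,
                      sigma_stdp=sigma)


def _source_metrics(res: SimResult, p: int, M_a: int, bin_ms: float = 10.0,
                    tau_D: float = 14.0):
    """Cross-correlation and MI between source events and output groups."""
    n_steps = res.source_events.shape[1]
    T = n_steps * res.dt
    steps_per_bin = int(round(bin_ms / res.dt))
    K = n_steps // steps_per_bin
    s_binned = res.source_events[:, : K * steps_per_bin].reshape(
        p, K, steps_per_bin).sum(axis=2).astype(float)
    ids, ts = res.spike_trains("out")
    M = res.W_X_final.shape[0]
    counts = metrics.bin_spikes(ids, ts, M, T, bin_ms)[:, :K]
    y_groups = metrics.group_counts(counts, M_a)
    c = metrics.cross_correlation(s_binned, y_groups, tau_D, bin_ms)
    mi = metrics.mutual_information(s_binned, y_groups)
    return c, mi


# --------------------------------------------------------------------------
# figure-level protocols
# --------------------------------------------------------------------------

def fig2_minor_source(spec: ExperimentSpec) -> dict:
    """Minor-source detection with structured lateral inhibition."""
    sizes, T, eta_scale = _conditions(spec)
    q_A = spec.get("q_A", 0.6)
    q_B = spec.get("q_B", 0.5)
    P = spec.get("loop_gain", LOOP_GAINS[spec.get("inhibition", "strong")])
    w_Z = wz_for_loop_gain(P, sizes["M_a"], sizes["N_a"])
    rm = stimuli.build_Q("minor_source", L=sizes["L"], L_a=sizes["L_a"],
                         q_A=q_A, q_B=q_B)
    net = build_network(spec.seed, w_Z=w_Z, **sizes)
    res = run_poisson(
        net, None, T=T, seed=spec.seed,
        stdp_X=_stdp_X(eta_scale),
        stimulus={"Q": rm.Q, "r_o": rm.r_o,
                  "theta_t": spec.get("theta_t", params.THETA_T)},
        record_u_stride=spec.get("record_u_stride", 0),
        record_w_every=T / 50.0,
    )
    gm = group_mean_weights(res.W_X_final, sizes["M_a"], sizes["L_a"])
    w_si = specialization_index(gm[0, 0], gm[0, 1], gm[1, 0], gm[1, 1])
    c, mi = _source_metrics(res, rm.p, sizes["M_a"])
    return {"result": res, "sizes": sizes, "group_means": gm, "w_SI": w_si,
            "cross_correlation": c, "mutual_information": mi,
            "metrics": {"w_SI": w_si, "cross_correlation": c,
                        "mutual_information": mi,
                        "group_means": gm.tolist()}}


def fig2_minor_source_lif(spec: ExperimentSpec) -> dict:
    """LIF cross-check of the minor-source protocol."""
    sizes, T, eta_scale = _conditions(spec)
    rm = stimuli.build_Q("minor_source", L=sizes["L"], L_a=sizes["L_a"],
                         q_A=spec.get("q_A", 0.6), q_B=spec.get("q_B", 0.5))
    net = build_network(spec.seed, w_Z=params.W_O_Z, **sizes)
    # LIF log-STDP: stronger LTD balance and steeper LTD weight dependence
    stdp = STDPConfig(rule="log_stdp",
                      eta=params.ETA_X_FACTOR * params.W_O_X * eta_scale,
                      C_d=1.8 * params.TAU_P / params.TAU_D, alpha=50.0,
                      sigma_stdp=params.SIGMA_STDP)
    res = run_lif(LIFConfig(), net, None, T=T, seed=spec.seed, stdp_X=stdp,
                  stimulus={"Q": rm.Q, "r_o": rm.r_o},
                  record_w_every=T / 20.0)
    gm = group_mean_weights(res.W_X_final, sizes["M_a"], sizes["L_a"])
    w_si = specialization_index(gm[0, 0], gm[0, 1], gm[1, 0], gm[1, 1])
    return {"result": res, "sizes": sizes, "group_means": gm, "w_SI": w_si,
            "metrics": {"w_SI": w_si, "group_means": gm.tolist()}}


def fig3_sweep(spec: ExperimentSpec) -> dict:
    """Mean-field regime map over the lateral loop gain."""
    coeffs = kernel_coefficients(TheoryConfig())
    mf = MeanFieldParams(coeffs=coeffs, q_A=spec.get("q_A", 0.6),
                         q_B=spec.get("q_B", 0.5))
    P_values = spec.get("P_values", np.arange(0.05, 0.55, 0.05))
    records = bistability_sweep(mf, P_values)
    return {"sweep": records,
            "metrics": {"regimes": [(r["P"], r["regime"]) for r in records]}}


def fig4_noise(spec: ExperimentSpec) -> dict:
    """Noise tolerance at different correlation timescales.

    ``noise='random'``: equal sources q_S, extra source-independent
    background rate on all input neurons. ``noise='crosstalk'``: zero
    background, off-diagonal response probability q_N.
    """
    sizes, T, eta_scale = _conditions(spec)
    theta_t = spec.get("theta_t", 0.5)
    noise = spec.get("noise", "random")
    q_S = spec.get("q_S", 0.6)
    if noise == "random":
        extra = spec.get("noise_rate", 10.0 / params.MS_PER_S)
        rm = stimuli.build_Q("crosstalk", L=sizes["L"], L_a=sizes["L_a"],
                             q_S=q_S, q_N=0.0, nu_X=params.NU_X + extra)
    elif noise == "crosstalk":
        q_N = spec.get("q_N", 0.3)
        rm = stimuli.build_Q("crosstalk", L=sizes["L"], L_a=sizes["L_a"],
                             q_S=q_S, q_N=q_N,
                             nu_X=(q_S + q_N) * params.NU_S)  # r_o = 0
    else:
        raise ValueError(f"unknown noise kind {noise!r}")
    P = spec.get("loop_gain", LOOP_GAINS["strong"])
    net = build_network(spec.seed,
                        w_Z=wz_for_loop_gain(P, sizes["M_a"], sizes["N_a"]),
                        **sizes)
    res = run_poisson(
        net, None, T=T, seed=spec.seed, stdp_X=_stdp_X(eta_scale),
        stimulus={"Q": rm.Q, "r_o": rm.r_o, "theta_t": theta_t},
        record_w_every=T / 20.0,
    )
    gm = group_mean_weights(res.W_X_final, sizes["M_a"], sizes["L_a"])
    c, mi = _source_metrics(res, rm.p, sizes["M_a"])
    return {"result": res, "sizes": sizes, "group_means": gm,
            "cross_correlation": c, "mutual_information": mi,
            "metrics": {"cross_correlation": c, "mutual_information": mi,
                        "theta_t": theta_t, "noise": noise}}


def _lateral_stdp_cfgs(eta_scale: float, rule_Y: str, rule_Z: str):
    eta = params.ETA_X_FACTOR * params.W_O_X * eta_scale
    cfg_Y = STDPConfig(rule=rule_Y,
                       eta=0.3 * eta * params.W_O_Y_PLASTIC / params.W_O_X,
                       tau_p=params.TAU_PD_LATERAL, tau_d=params.TAU_PD_LATERAL,
                       gamma=params.GAMMA_Y, sigma_stdp=params.SIGMA_STDP,
                       w_max=params.W_MAX_Y)
    cfg_Z = STDPConfig(rule=rule_Z,
                       eta=0.3 * eta * params.W_O_Z_PLASTIC / params.W_O_X,
                       tau_p=params.TAU_PD_LATERAL, tau_d=params.TAU_PD_LATERAL,
                       gamma=params.GAMMA_Z, sigma_stdp=params.SIGMA_STDP,
                       w_max=params.W_MAX_Z)
    return cfg_Y, cfg_Z


def _lateral_phis(W_X, W_Y, W_Z, L_a):
    groups = [np.arange(L_a), np.arange(L_a, 2 * L_a)]
    assign = metrics.assign_output_groups(W_X, groups, alpha_th=1.0 + 1e-9)
    omega_A = np.where(assign == 0)[0]
    omega_B = np.where(assign == 1)[0]
    phi_Z = metrics.mutual_inhibition_phiZ(W_Y, W_Z)
    if omega_A.size == 0 or omega_B.size == 0:
        return {"phi_Y": 0.0, "phi_Z": phi_Z}
    return {"phi_Y": metrics.feature_selectivity_phiY(W_Y, omega_A, omega_B),
            "phi_Z": phi_Z}


def fig5_lateral_stdp(spec: ExperimentSpec) -> dict:
    """Lateral-structure learning with plastic E-to-I and I-to-E synapses."""
    sizes, T, eta_scale = _conditions(spec, T_full=4000.0e3)
    q = spec.get("q_A", 0.6)
    rm = stimuli.build_Q("minor_source", L=sizes["L"], L_a=sizes["L_a"],
                         q_A=q, q_B=spec.get("q_B", q))
    net = build_network(spec.seed, w_Y=params.W_O_Y_PLASTIC,
                        w_Z=params.W_O_Z_PLASTIC, lateral_random_init=True,
                        **sizes)
    cfg_Y, cfg_Z = _lateral_stdp_cfgs(eta_scale, spec.get("rule_Y", "hebbian"),
                                      spec.get("rule_Z", "hebbian"))
    phi_before = _lateral_phis(net.W_X, net.W_Y, net.W_Z, sizes["L_a"])
    res = run_poisson(
        net, None, T=T, seed=spec.seed,
        stdp_X=_stdp_X(eta_scale), stdp_Y=cfg_Y, stdp_Z=cfg_Z,
        stimulus={"Q": rm.Q, "r_o": rm.r_o},
        record_w_every=T / 20.0,
    )
    phi_after = _lateral_phis(res.W_X_final, res.W_Y_final, res.W_Z_final,
                              sizes["L_a"])
    return {"result": res, "sizes": sizes, "phi_before": phi_before,
            "phi_after": phi_after,
            "metrics": {"phi_before": phi_before, "phi_after": phi_after}}


def fig6_stdp_variants(spec: ExperimentSpec) -> dict:
    """Minor-source detection under different I-to-E STDP rules."""
    out = {}
    for rule in spec.get("rules", ("hebbian", "anti_hebbian")):
        sub = ExperimentSpec(spec.name, spec.scale, spec.seed,
                             {**spec.overrides, "rule_Z": rule,
                              "q_A": spec.get("q_A", 0.6),
                              "q_B": spec.get("q_B", 0.5)})
        r = fig5_lateral_stdp(sub)
        L_a = r["sizes"]["L_a"]
        groups = [np.arange(L_a), np.arange(L_a, 2 * L_a)]
        assign = metrics.assign_output_groups(r["result"].W_X_final, groups)
        out[rule] = {"minor_fraction": float(np.mean(assign == 1)),
                     "assignments": assign}
    return {"by_rule": out,
            "metrics": {r: v["minor_fraction"] for r, v in out.items()}}


def fig7_ica_compare(spec: ExperimentSpec) -> dict:
    """Sampled Bayesian ICA vs the ideal observer on a 4-source stream."""
    dt_bin = spec.get("dt_bin", 5.0)
    T = spec.get("T_ms", 500.0e3 if spec.scale == "desk" else 4000.0e3)
    K = int(T / dt_bin)
    L_a = spec.get("L_a", 10)
    rm = stimuli.build_Q("four_source", L=4 * L_a, L_a=L_a,
                         q_S=spec.get("q_S", 0.6), q_N=spec.get("q_N", 0.1))
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    S, X = sample_discrete_stream(rm.Q, rm.r_o, K, dt_bin=dt_bin, seed=ss[0])
    rng = np.random.default_rng(ss[1])
    Qt0 = rng.uniform(0.05, 0.25, rm.Q.shape)
    out = {}
    for mode in ("sampled", "ideal"):
        st = ICAState(Qt=Qt0.copy(), r_o=rm.r_o, dt_bin=dt_bin,
                      eta=spec.get("eta", 0.001))
        r = run_learning(st, X, mode=mode,
                         seed=int(ss[2].generate_state(1)[0] % 2**31),
                         Q_true=rm.Q)
        c = metrics.cross_correlation(S.astype(float), r.Y.astype(float),
                                      tau_D=0.0, bin_ms=dt_bin)
        out[mode] = {"result": r, "cross_correlation": c}
    return {"by_mode": out, "Q_true": rm.Q, "S": S, "X": X,
            "metrics": {m: v["cross_correlation"] for m, v in out.items()}}


def fig8_bss(spec: ExperimentSpec) -> dict:
    """Blind source separation of four synthetic auditory signals.

    Input neurons fire as inhomogeneous Bernoulli processes at a rate
    proportional to the scene's response probabilities q_i(t); the
    proportionality is set so the population-mean rate is nu_X. Output
    group rates are compared against the source envelopes.
    """
    sizes, T, eta_scale = _conditions(spec)
    T = float(spec.get("T_ms", 120.0e3 if spec.scale == "desk" else 3000.0e3))
    L = params.L
    scene = stimuli.AuditoryScene(seed=spec.seed, L=L)
    syn = stimuli.synth_auditory_scene(scene, T, dt_env=1.0)
    # factorized time-varying rates: rate_i(t) = scale * q_o
    #   * sum_q spec[q, i] * env[q, t], normalized to a nu_X mean
    Q_rate = scene.q_o * syn["spec"].T               # (L, n_sources)
    mean_q = (Q_rate @ syn["env"].mean(axis=1)).mean()
    rate_scale = params.NU_X / max(mean_q, 1e-12)
    # four output groups
    M_a = sizes["M_a"]
    M = N = 4 * M_a
    P = spec.get("loop_gain", 0.8)  # strong inhibition for 4 groups
    net = build_network(spec.seed, L=L, M=M, N=N, M_a=M_a, N_a=M_a,
                        w_Z=wz_for_loop_gain(P / 3.0, M_a, M_a))
    res = run_poisson(net, None, T=T, seed=spec.seed + 1,
                      stdp_X=_stdp_X(eta_scale),
                      stimulus={"Q": rate_scale * Q_rate,
                                "r_o": np.zeros(L),
                                "env": syn["env"], "env_dt": 1.0},
                      record_w_every=T / 10.0)
    ids, ts = res.spike_trains("out")
    counts = metrics.bin_spikes(ids, ts, M, T, 10.0)
    y_groups = metrics.group_counts(counts, M_a)
    K = counts.shape[1]
    t_env = (np.arange(K) + 0.5) * 10.0
    env = np.stack([np.interp(t_env, syn["t"], syn["env"][q])
                    for q in range(scene.n_sources)])
    c = metrics.cross_correlation(env, y_groups, tau_D=10.0, bin_ms=10.0)
    return {"result": res, "scene": syn, "cross_correlation": c,
            "metrics": {"cross_correlation": c}}


EXPERIMENTS = {
    "fig2_minor_source": fig2_minor_source,
    "fig2_minor_source_lif": fig2_minor_source_lif,
    "fig3_sweep": fig3_sweep,
    "fig4_noise": fig4_noise,
    "fig5_lateral_stdp": fig5_lateral_stdp,
    "fig6_stdp_variants": fig6_stdp_variants,
    "fig7_ica_compare": fig7_ica_compare,
    "fig8_bss": fig8_bss,
}


def run_experiment(spec: ExperimentSpec, out_dir=None) -> dict:
    """Run one protocol; optionally persist its artifact bundle."""
    if spec.name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {spec.name!r}; "
                         f"choose from {sorted(EXPERIMENTS)}")
    out = EXPERIMENTS[spec.name](spec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "config.yaml", "w") as f:
            yaml.safe_dump({"name": spec.name, "scale": spec.scale,
                            "seed": spec.seed,
                            "overrides": _jsonable(spec.overrides)}, f)
        with open(out_dir / "metrics.json", "w") as f:
            json.dump(_jsonable(out.get("metrics", {})), f, indent=2)
        res = out.get("result")
        if isinstance(res, SimResult):
            ids, ts = res.spike_trains("out")
            stimuli.write_spikes_text(out_dir / "out_spikes.txt", ids, ts)
            np.savez_compressed(out_dir / "weights.npz",
                                W_X=res.W_X_final, W_Y=res.W_Y_final,
                                W_Z=res.W_Z_final, w_times=res.w_times,
                                W_X_trace=res.W_X_trace)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
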