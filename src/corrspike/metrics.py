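"""Evaluation statistics.

Performance of source learning is measured by the delay-optimized mean
cross-correlation between hidden-source event counts and output-group
population counts (maximized over source <-> group assignments), and by
the plug-in mutual information between the binarized source and output
state vectors. Structure of learned weights is quantified by the
specialization index, the output-group assignment rule, the inhibitory
feature-selectivity index phi_Y and the mutual-inhibition index phi_Z.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

__all__ = [
    "bin_spikes",
    "group_counts",
    "cross_correlation",
    "mutual_information",
    "assign_output_groups",
    "feature_selectivity_phiY",
    "mutual_inhibition_phiZ",
]

log = logging.getLogger(__name__)

DEFAULT_BIN_MS = 10.0


def bin_spikes(neuron_ids, times_ms, n_neurons: int, T: float,
               bin_ms: float = DEFAULT_BIN_MS) -> np.ndarray:
    """Spike-count matrix (n_neurons, n_bins) from (id, time) pairs."""
    n_bins = int(np.floor(T / bin_ms))
    counts = np.zeros((n_neurons, n_bins))
    neuron_ids = np.asarray(neuron_ids, int)
    k = (np.asarray(times_ms, float) / bin_ms).astype(int)
    ok = (k >= 0) & (k < n_bins)
    np.add.at(counts, (neuron_ids[ok], k[ok]), 1.0)
    return counts


def group_counts(counts: np.ndarray, group_size: int) -> np.ndarray:
    """Sum counts within consecutive groups of ``group_size`` neurons."""
    n, k = counts.shape
    if n % group_size:
        raise ValueError("group size must divide the neuron count")
    return counts.reshape(n // group_size, group_size, k).sum(axis=1)


def _pair_corr(s: np.ndarray, y: np.ndarray) -> float:
    s = s - s.mean()
    y = y - y.mean()
    denom = np.sqrt((s**2).sum() * (y**2).sum())
    if denom == 0:
        log.debug("zero-variance series; pair contributes 0")
        return 0.0
    return float((s * y).sum() / denom)


def cross_correlation(source_counts, output_counts, tau_D: float = 0.0,
                      bin_ms: float = DEFAULT_BIN_MS,
                      return_assignment: bool = False):
    """Delay-optimized mean source/output cross-correlation c(tau_D).

    ``source_counts`` (p, K) and ``output_counts`` (G, K) are binned
    series; the output is shifted by the readout delay ``tau_D`` (ms)
    before the Pearson correlation of each (source, group) pair is
    computed, and the mean is maximized over all one-to-one assignments
    of sources to groups.
    """
    s = np.asarray(source_counts, float)
    y = np.asarray(output_counts, float)
    p, G = s.shape[0], y.shape[0]
    if p > 8:
        raise ValueError("permutation search only supports p <= 8")
    lag = int(round(tau_D / bin_ms))
    if lag > 0:
        s_al, y_al = s[:, : s.shape[1] - lag], y[:, lag:]
    elif lag < 0:
        s_al, y_al = s[:, -lag:], y[:, : y.shape[1] + lag]
    else:
        s_al, y_al = s, y
    C = np.array([[_pair_corr(s_al[mu], y_al[nu]) for nu in range(G)]
                  for mu in range(p)])
    best, best_psi = -np.inf, None
    for psi in itertools.permutations(range(G), p):
        v = np.mean([C[mu, psi[mu]] for mu in range(p)])
        if v > best:
            best, best_psi = v, psi
    if return_assignment:
        return best, best_psi
    return best


def _binarize(counts: np.ndarray) -> np.ndarray:
    """1 where the series exceeds mean + SD, else 0 (per row)."""
    c = np.asarray(counts, float)
    thr = c.mean(axis=1, keepdims=True) + c.std(axis=1, keepdims=True)
    return (c > thr).astype(np.int64)


def mutual_information(source_counts, output_counts) -> float:
    """Plug-in mutual information (bits) between binarized state vectors.

    Each time bin contributes one joint observation of the binary source
    state vector and the binary output state vector; MI is computed from
    the empirical joint distribution. Degenerate (single-state) series
    give 0. The plug-in estimator is biased upward by O(#states/#bins).
    """
    s = _binarize(source_counts)
    y = _binarize(output_counts)
    K = s.shape[1]
    s_code = np.zeros(K, dtype=np.int64)
    for row in s:
        s_code = 2 * s_code + row
    y_code = np.zeros(K, dtype=np.int64)
    for row in y:
        y_code = 2 * y_code + row
    joint = {}
    for a, b in zip(s_code, y_code):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    ps, py = {}, {}
    for (a, b), c in joint.items():
        ps[a] = ps.get(a, 0) + c
        py[b] = py.get(b, 0) + c
    mi = 0.0
    for (a, b), c in joint.items():
        pab = c / K
        mi += pab * np.log2(pab / (ps[a] / K * py[b] / K))
    return float(max(mi, 0.0))


def assign_output_groups(W_X: np.ndarray, input_groups,
                         alpha_th: float = 1.5) -> np.ndarray:
    """Assign each output neuron to the source whose input group drives it.

    Neuron j belongs to group mu iff its mean weight from mu's input
    neurons strictly exceeds ``alpha_th`` times the best competing
    group's mean weight; otherwise it stays unassigned (-1).
    """
    W_X = np.asarray(W_X, float)
    means = np.stack([W_X[:, idx].mean(axis=1) for idx in input_groups])
    out = np.full(W_X.shape[0], -1, dtype=int)
    for j in range(W_X.shape[0]):
        order = np.argsort(means[:, j])[::-1]
        best, second = order[0], order[1] if len(order) > 1 else order[0]
        if means[best, j] > alpha_th * means[second, j]:
            out[j] = best
    return out


def feature_selectivity_phiY(W_Y: np.ndarray, omega_A, omega_B,
                             signed: bool = False) -> float:
    """Feature selectivity of inhibitory neurons from their E-to-I weights.

    Per inhibitory neuron: (mean weight from A-coding outputs - mean
    weight from B-coding outputs) / (mean weight from all outputs).
    Aggregated as the mean of per-neuron absolute values (a symmetric,
    perfectly clustered network scores 2); ``signed=True`` keeps the raw
    signed mean instead. Neurons with zero total weight are skipped.
    """
    W_Y = np.asarray(W_Y, float)
    omega_A = np.asarray(omega_A, int)
    omega_B = np.asarray(omega_B, int)
    if omega_A.size == 0 or omega_B.size == 0:
        raise ValueError("both output groups must be non-empty")
    vals = []
    for k in range(W_Y.shape[0]):
        tot = W_Y[k].mean()
        if tot == 0:
            log.debug("inhibitory neuron %d has zero row sum; skipped", k)
            continue
        sel = (W_Y[k, omega_A].mean() - W_Y[k, omega_B].mean()) / tot
        vals.append(sel if signed else abs(sel))
    return float(np.mean(vals)) if vals else 0.0


def mutual_inhibition_phiZ(W_Y: np.ndarray, W_Z: np.ndarray) -> float:
    """Degree of non-reciprocity between E-to-I and I-to-E profiles.

    For each inhibitory neuron k, compare its normalized incoming-E
    profile (row k of W_Y) with its normalized outgoing-I profile
    (column k of W_Z) by the L1 distance; average over k. 0 means
    perfectly reciprocal wiring, 2 means disjoint profiles (inhibition
    avoids the neurons that excite the interneuron — mutual inhibition
    between groups).
    """
    W_Y = np.asarray(W_Y, float)
    W_Z = np.asarray(W_Z, float)
    N = W_Y.shape[0]
    vals = []
    for k in range(N):
        sy, sz = W_Y[k].sum(), W_Z[:, k].sum()
        if sy == 0 or sz == 0:
            log.debug("inhibitory neuron %d has a zero profile; skipped", k)
            continue
        vals.append(np.abs(W_Y[k] / sy - W_Z[:, k] / sz).sum())
    return float(np.mean(vals)) if vals else 0.0
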