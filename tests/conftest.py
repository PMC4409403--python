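"""Shared fixtures.

The expensive artifacts (analytic kernel coefficients, mean-field fixed
points, the desk-scale specialization sweep, the ICA recovery runs) are
computed once per session and shared between the unit tests and the
acceptance tests.
"""

import numpy as np
import pytest

from corrspike import theory
from corrspike.experiments import ExperimentSpec, fig2_minor_source


@pytest.fixture(scope="session")
def coeffs():
    return theory.kernel_coefficients(theory.TheoryConfig())


@pytest.fixture(scope="session")
def meanfield(coeffs):
    return theory.MeanFieldParams(coeffs=coeffs, q_A=0.6, q_B=0.5)


@pytest.fixture(scope="session")
def fixed_points_by_gain(meanfield):
    """Fixed points at the weak / moderate / strong inhibition settings."""
    return {
        P: theory.find_fixed_points(meanfield.with_loop_gain(P))
        for P in (0.1, 0.215, 0.4)
    }


@pytest.fixture(scope="session")
def fig2_sweep():
    """Desk-scale minor-source runs: 5 seeds at strong and weak inhibition."""
    out = {}
    for inh in ("strong", "weak"):
        out[inh] = [
            fig2_minor_source(
                ExperimentSpec("fig2_minor_source", "desk", seed,
                               {"inhibition": inh})
            )
            for seed in range(1, 6)
        ]
    return out


@pytest.fixture(scope="session")
def ica_recovery_runs():
    """Sampled-mode Bayesian ICA on matched 2-source streams, 5 seeds."""
    import itertools

    from corrspike import stimuli
    from corrspike.bayes_ica import ICAState, run_learning, sample_discrete_stream

    rm = stimuli.build_Q("crosstalk", L=40, L_a=20, q_S=0.6, q_N=0.0)
    K = int(2000e3 / 5.0)  # 2000 s of 5 ms bins
    runs = []
    for seed in range(5):
        S, X = sample_discrete_stream(rm.Q, rm.r_o, K, seed=100 + seed)
        rng = np.random.default_rng(seed)
        st = ICAState(Qt=rng.uniform(0.05, 0.25, rm.Q.shape), r_o=rm.r_o)
        res = run_learning(st, X, mode="sampled", seed=200 + seed)
        err = min(
            float(np.abs(res.Qt[:, perm] - rm.Q).max())
            for perm in itertools.permutations(range(rm.p))
        )
        runs.append({"S": S, "X": X, "result": res, "max_abs_err": err,
                     "Q_true": rm.Q})
    return runs
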