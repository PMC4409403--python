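"""Default model parameters for the correlated-input network.

These are the standard operating conditions used across the package:
population sizes, PSP time constants, synaptic delay ranges, firing rates
and STDP constants. Times are in milliseconds and rates in events/ms
(so 10 Hz == 0.01/ms) unless a name says otherwise.
"""

from __future__ import annotations

MS_PER_S = 1000.0

# populations
L, M, N = 400, 20, 20
L_A, M_A, N_A = 100, 10, 10

# PSP double-exponential time constants (ms): feedforward X, lateral E->I Y,
# feedback I->E Z
TAU_A_X, TAU_B_X = 5.0, 1.0
TAU_A_Y, TAU_B_Y = 4.0, 0.8
TAU_A_Z, TAU_B_Z = 2.5, 0.5

# synaptic weights (reference / initial values)
W_O_X, W_O_Y, W_O_Z = 2.5, 100.0, 50.0
# reference lateral weights when lateral connections are themselves plastic
W_O_Y_PLASTIC, W_O_Z_PLASTIC = 50.0, 25.0
W_MAX_Y, W_MAX_Z = 100.0, 50.0

# delay ranges (ms): feedforward axonal / dendritic, lateral axonal
D_XA_MIN, D_XA_MAX = 2.0, 4.0
D_XD_MIN, D_XD_MAX = 0.5, 1.5
D_Y_MIN, D_Y_MAX = 0.2, 1.2
D_Z_MIN, D_Z_MAX = 0.2, 1.2

# input statistics
THETA_T = 2.0                 # correlation timescale (ms)
NU_S = 10.0 / MS_PER_S        # source event rate (1/ms)
NU_X = 10.0 / MS_PER_S        # target mean input rate (1/ms)

# feedforward log-STDP
ETA_X_FACTOR = 0.05           # eta^X = 0.05 * w_o^X
TAU_P, TAU_D = 17.0, 34.0
ALPHA, BETA = 20.0, 50.0
SIGMA_STDP = 0.3
SIGMA_W_INIT = 0.1

# lateral STDP
GAMMA_Y, GAMMA_Z = 1.4, 0.7
TAU_PD_LATERAL = 20.0         # tau_p^Y = tau_d^Y = tau_p^Z = tau_d^Z

# simulation grid
DT = 0.05                     # ms

# linear-Poisson gain scale: g_E(u) = GAIN_E * u, g_I(u) = GAIN_I * u.
# Chosen so that with Table-like weights (L*w_o^X = 1000, M_a*w_Y = 1000)
# output and inhibitory rates come out near the 10 Hz operating point, and
# the lateral loop gain P = GAIN_E*GAIN_I*M_a*w_Y*N_a*w_Z stays below 1.
GAIN_E = 1.0e-3
GAIN_I = 1.0e-3
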