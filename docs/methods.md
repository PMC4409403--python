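# Methods

## Model

The network has four stages. Hidden **sources** are independent Bernoulli
event trains at rate ν_S (default 10 Hz) on the simulation grid. **Input
neurons** (L = 400, in groups of L_a = 100) are rate-modulated Poisson
units: neuron *i* fires at

    rate_i(t) = r_i^o + Σ_μ q_iμ (φ ⋆ s_μ)(t),

where φ is the response kernel — by default the Erlang/gamma density of
shape 3, φ(t) = t² e^(−t/θ_t) / 2θ_t³, whose timescale θ_t (default 2 ms)
sets the width of the spike correlations; an exponential kernel is
available for comparison. The baseline r_i^o = ν_X − Σ_μ q_iμ ν_S pins
every input neuron's mean rate at ν_X = 10 Hz, so information lives only
in correlations. Two input neurons sharing sources have cross-correlation
C_il(s) = ν_S Σ_μ q_iμ q_lμ h(s), with h the autocorrelation of φ
(closed form in `theory.h_closed_form`).

**Output neurons** (M = 20) and **lateral inhibitory interneurons**
(N = 20) are linear Poisson units: membrane potential = delayed,
PSP-filtered weighted sum of inputs (unit-area double-exponential kernels
per connection class), spike probability per 0.05 ms step =
max(0, g(u))·dt. Feedforward synapses carry independent axonal
(2–4 ms) and dendritic (0.5–1.5 ms) delays; lateral synapses are purely
axonal (0.2–1.2 ms). A conductance-based leaky integrate-and-fire backend
with the same wiring cross-checks the linear-Poisson results.

### Gain convention and the lateral loop gain

The literal weight magnitudes (w_o^X = 2.5 per synapse with 400 inputs at
10 Hz) produce membrane potentials far above any sensible firing rate if
g(u) = u is taken at face value, so the package fixes linear gains
g_E(u) = 10⁻³·u and g_I(u) = 10⁻³·u. This puts output and interneuron
rates near the 10 Hz operating point, and makes the
output→inhibitory→output feedback loop's dimensionless gain

    P = g_E·g_I·M_a·w_Y·N_a·w_Z

the single number through which lateral inhibition enters the reduced
dynamics. With w_Y = 100 the named inhibition levels weak / moderate /
strong correspond to per-synapse w_Z = 10 / 21.5 / 50, i.e. P = 0.1 /
0.215 / 0.5, and the inhibition/excitation weight balance
N_a·w_Z/(L·w_o^X) in percent equals 100·P. P < 1 is required for a
stable loop.

## Plasticity

Feedforward synapses follow pairwise **log-STDP**: every (pre, post) pair,
evaluated at the *at-synapse* times (pre + axonal delay, post + dendritic
delay), contributes

    Δw = η f_p(w) e^(−Δt/τ_p)   (post after pre; τ_p = 17 ms)
    Δw = η f_d(w) e^(−Δt/τ_d)   (pre after post; τ_d = 34 ms)

with f_p(w) = C_p e^(−w/βw_o) and f_d(w) = −C_d log(1+αw/w_o)/log(1+α),
α = 20, β = 50, C_p = 1, C_d = C_p τ_p/τ_d (areas balanced at small w).
Amplitudes carry multiplicative noise (1 + σξ), σ = 0.3, ξ clipped at
±1/σ so updates never flip sign; one draw per pairing event. All-pairs
pairing is implemented by online exponential traces (identical to the
double sum); exact pre/post ties count as LTP — a fixed convention for a
measure-zero event. Weights are clipped to [0, 20·w_o^X]; the cap is far
above every fixed point and exists only as a numerical guard, since
log-STDP is self-limiting.

Lateral E→I and I→E synapses use weight-independent windows — Hebbian,
anti-Hebbian, correlation-detector and its sign flip — with
τ_p = τ_d = 20 ms, LTD/LTP balance factors γ^Y = 1.4, γ^Z = 0.7,
learning rates η^Q = 0.3·η·w_o^Q/w_o^X, reference weights w_o^Y = 50,
w_o^Z = 25 and caps w^Y ≤ 100, w^Z ≤ 50 in plastic-lateral runs.

## Analytic layer

Averaging the pairwise rule over the Poisson statistics turns mean weight
drift into scalar coefficients: the input correlation h, filtered through
PSP kernels, delays and the STDP window. The direct route gives
G1X(w), the route through the inhibitory loop (three PSP stages, total
delay D = 2d_Xd + d_Y + d_Z with midpoint delays 1.0/0.7/0.7 ms) gives
G2X(w), which enters with a minus sign (loop-routed correlation is
depressing). Because the window factorizes in w, each coefficient is an
exact linear combination f_p(w)·I_p + f_d(w)·I_d of two w-independent
integrals, evaluated by FFT convolution of the kernels on a 0.02 ms grid
(grids renormalized to unit mass; pre-normalization deviation checked
< 10⁻³). The analogous coefficients g1Y, g1Z for lateral windows predict
lateral structure formation: g1Y > 0 → feature-selective interneurons,
g1Z < 0 → mutual inhibition.

The **two-source mean field** reduces the network to four group weights
(w_1A, w_1B, w_2A, w_2B) with background weights fixed at w_o^X:

    dw_μν/dt = L_a ν_S c_ν [G1X(w_μν) w_μν − P·G2X(w_μν) w_μ̄ν]
             + F̄(w_μν) ν_X² L_a (S_μ − P·S_μ̄)/(1 − P²),

c_A = q_A², c_B = q_B², S_μ = w_μA + w_μB + 2w_o^X, and
F̄(w) = f_p(w)τ_p + f_d(w)τ_d the homeostatic window area. The
inhibitory-rate elimination keeps the one-loop truncation of the printed
derivation; the overall learning rate and output gain scale time only and
are dropped. Fixed points come from ~160 multi-start hybrid-Newton
searches on a coarse 4-d grid (dedup radius 10⁻³, stability from
finite-difference Jacobian eigenvalues); weights are rectified at zero
with a linear restoring penalty below zero so searches stay in the
admissible region. The multistability onset is located by bisection (to
5·10⁻⁴ in P) on the existence of stable winners-share-all points.

At the standard parameters this system has: a unique stable
winner-take-all point at P = 0.1 (w_2A = 9.67); three stable + two
unstable points at P = 0.215 (share-all w_2A = 12.57, symmetric middle
point w_1A = w_2A = 9.51); share-all-only stability at P = 0.4. The
saddle-node birth of share-all states sits at P = 0.209, an I/E balance
of 20.9%.

## Simulation engine

Clock-driven at dt = 0.05 ms. Linear filters are integrated by exact
exponential propagation (the Erlang cascade for the response kernel, two
exponential traces per PSP class, the exponential-integrator update for
the LIF membrane equation), which is exact for impulse inputs at this
step size; delays are rounded to the grid. Spike arrivals and STDP
pairing events are event-driven through ring buffers of per-step
increments; per-synapse STDP traces decay lazily (updated only when a
spike reaches the synapse). Input groups with identical response rows
are sampled by one binomial count per step instead of per-neuron
Bernoulli draws — statistically identical and ~4× faster. Runs are
bit-reproducible for a given seed. Firing probabilities g(u)·dt are
clamped at 1 with a logged clamp fraction; membrane traces are recorded
unrectified so event-aligned averages can show hyperpolarization.

## Bayesian ICA learner

Time is discretized into 5 ms bins. The per-bin source prior is
Bernoulli(ν_S·Δt); input neuron *i* spikes with probability

    p_i^k = 1 − (1 − r_i^o Δt) Π_μ [1 − q̃_iμ Σ_k' φ_k' s_μ^(k−k')],

with φ_k the response kernel sampled at bin midpoints times Δt — a
dimensionless per-bin response probability, consistent with the r_oΔt
baseline (Σφ_k ≈ 1.08 at 5 ms bins; the slight overweighting of the
kernel peak sharpens per-bin evidence and is kept as the canonical
discretization). At every bin the joint source configuration is sampled
exactly from its 2^p-state posterior given the current inputs and the
previously sampled history (p ≤ 12 guard), and q̃ takes a stochastic
gradient step (η = 0.001) along the exact per-bin likelihood gradient;
the posterior normalizer is absorbed into η. The update conditions on
the current sample (switchable). In `ideal` mode the configuration is
sampled under the true Q — the ideal-observer baseline. A matched
generative sampler (`sample_discrete_stream`) produces (S, X) streams
from this same discrete model for studying the learner in isolation; on
such streams the sampled learner recovers a 2-source Q (q_S = 0.6,
L = 40, 2000 s) to better than 0.1 per entry in the median over seeds.

## Metrics

Performance is the delay-optimized mean cross-correlation between binned
(10 ms) source events and output-group population counts, maximized over
source↔group assignments, plus plug-in mutual information between the
binarized (mean + SD threshold) state vectors. Structure is quantified
by the specialization index w_SI = sign[(w_1A−w_1B)(w_2B−w_2A)], the
α_th = 1.5 group-assignment rule, the inhibitory feature-selectivity
index φ^Y and the mutual-inhibition index φ^Z. Two printed formulas are
under-determined and are implemented with documented conventions, both
switchable: φ^Y aggregates per-interneuron |selectivity| (the literal
signed mean cancels to zero for a perfectly clustered symmetric network),
and φ^Z sums the absolute normalized difference between each
interneuron's incoming-E profile and outgoing-I profile over the free
output index (an L1 distance in [0, 2]).

## Scales, synthetic data, and what the tests show

`full` presets use the long-run conditions (3000–4000 s; M = N = 40 and
w_o^Z = 80 for the four-source tasks). `desk` presets keep the full
network — per-synapse inhibitory weights set the shot-noise statistics of
the feedback loop, so shrinking layers changes the operating regime — but
run 1/10 of the duration at 10× the learning rate, preserving expected
total drift at √10-larger plasticity noise. Desk runs reproduce the
regime structure (share-all under strong inhibition, take-all under weak,
in 5/5 seeds each at the defaults) but sit farther from the mean-field
fixed points than converged full runs would.

The auditory scenes are parametric: harmonic Gaussian spectra and
exponential-of-cosines envelopes, mixed into per-neuron response
probabilities on a log-spaced frequency grid (f_L = 4.5 kHz). The
blind-source-separation driver converts these to inhomogeneous input
rates normalized to a 10 Hz population mean; the per-source carrier
delay is drawn once per scene, uniform on [0, 1/f_min] (constant across
frequencies — the frequency-resolved alternative is a scene parameter
away). Synthetic stimuli emulate stationary correlation structure only:
no adaptation, no rate nonstationarity beyond the scripted envelopes, no
cochlear processing. Passing tests therefore demonstrate the learning
mechanics under the model's own assumptions, not robustness on recorded
neural or audio data.

## Numerical choices and limitations

- Kernel truncation: convolution windows at 20·θ_t with a < 10⁻⁶
  mass-loss check; analytic grids span 30× the slowest time constant.
- Delay heterogeneity is replaced by midpoint delays in the analytics;
  simulations draw per-synapse delays uniformly from the printed ranges
  (low + (high−low)·ξ).
- The mean-field warm-up/readout conventions: metrics exclude no warm-up
  by default at desk scale (runs are short); the evaluation-window length
  is a parameter of the metrics, defaulting to the full recording.
- The LIF backend uses steeper LTD (C_d factor 1.8, α = 50) per its own
  parameter set and an exponential-integrator membrane update rather than
  explicit Runge–Kutta; for piecewise-constant conductances this is at
  least as accurate at the same step.
- Known limitations: the sequential sampler is a filtering approximation
  (no smoothing), so its source estimates — and with them the learned
  q̃ — are mildly attenuated relative to the true response probabilities;
  higher-order lateral kernel corrections (beyond g1Y, g1Z) are omitted;
  stability analysis is linear (Jacobian eigenvalues), not stochastic.
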