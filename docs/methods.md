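# Methods

`synpair` simulates pairs of synaptically connected neurons growing
through a microchannel between two wells of a microelectrode array, and
infers the pair's biophysical parameters from the spiking statistics such
recordings provide.  This note documents the model, the estimators, the
numerical choices, and what the synthetic data do and do not establish.

## Biophysical model

Each neuron is a ball-and-stick cable: a cylindrical soma (10 um x 10 um)
and 100 axonal segments of 19.9 um sharing one diameter d in [0.2, 5] um.
The presynaptic soma spans z = 0-10 um with its axon reaching z = 2000 um;
the postsynaptic neuron is identical but shifted 1000 um along z.
Per-segment membrane dynamics are Hodgkin-Huxley (fast Na, delayed-
rectifier K, leak) with rate functions carrying a global voltage offset
V_T = -30.4 mV and temperature scaling phi = 3^((T-37)/10); the reference
values (r_a = 100 Ohm cm, c_m = 1 uF/cm2, g_Na = 0.05, g_K = 0.005,
g_L = 0.0003 S/cm2, E_L = -39.2, E_Na = 70, E_K = -80 mV, T = 37 C) were
tuned elsewhere to match NGN2-neuron electrophysiology; the depolarized
E_L makes the resting potential ~ -39 mV with broad, slowly
repolarizing spikes, which several numerical choices below respond to.

Synapses are conductance-based with a peak-normalized beta profile
(difference of exponentials; tau_peak = tau1 tau2/(tau2-tau1) ln(tau2/tau1)).
The pre->post connection has an AMPA (0.1/0.3 ms) and an NMDA (10/30 ms)
component sharing each activation event, each with a per-event weight
drawn from a normal truncated below at 0.  Spontaneous activity is a
Poisson train of excitatory events (0.2/0.4 ms kinetics) onto the initial
axon segment, with weight law 0.02*d +/- 0.02*d so efficacy is
diameter-independent.  Transmission is event-based: when the presynaptic
segment nearest z_syn crosses 0 mV upward (2 ms refractory), both
components activate in the postsynaptic segment nearest z_syn.

**Weight units.**  The variable weight parameters (mu_AMPA in [0, 0.002]
etc.) are read in mS, the published unit of G_syn, and converted to the
internal uS at the simulator boundary.  Under a uS reading the strongest
allowed AMPA weight (2 nS) stays an order of magnitude below the local
spike threshold of the postsynaptic axon (~0.03-0.1 uS at d = 1 um,
scaling roughly with d^1.5), the connection would be inert, and neither
the saturating p_syn dose-response nor the significance-filtered training
set could exist.  The mS reading also makes the spontaneous drive do what
it is for: essentially every Poisson event elicits a spike.

## Numerics

Internal units: mV, ms, um, Ohm cm, S/cm2, uF/cm2, nA, uS (all
conversions in `constants.py`).  The voltage update is Crank-Nicolson
with a tridiagonal (Thomas) solve; axial conductances between segment
centers come from the series sum of half axial resistances
4 r_a (L/2)/(pi d^2).  Gating uses Rush-Larsen exponential updates with
x_inf and exp(-dt/tau) interpolated from dense voltage tables (0.02 mV
grid) rebuilt per (parameters, dt).  Default dt = 0.1 ms; the scheme is
unconditionally stable there, including under the ~20-100 uS spontaneous
conductance transients, and spike times converge at second order in dt.

Synaptic conductances are *not* resolved by per-event window sums:
because the beta profile is exactly a difference of two decaying
exponentials, each kinetics keeps two scalar accumulators that decay by
exp(-dt/tau) per step and receive w/norm at each event, pre-decayed by
the event's sub-step residual time.  This is algebraically identical to
summing all past beta profiles, exact to machine precision, O(1) per
step, and makes the sampled conductance independent of dt.

Spike detection (0 mV upward crossing, sub-dt linear interpolation, 2 ms
refractory) uses a Schmitt trigger: after a detection the detector
re-arms only once V falls 10 mV below threshold.  Without it, the
Crank-Nicolson two-step micro-oscillation around the ~0 mV repolarization
plateau of these broad spikes produces spurious doublet detections at
dt = 0.1 ms.

Initialization: V uniform at E_L, gating at steady state, followed by a
200 ms silent settling run excluded from all outputs.  Numerical
blow-up aborts the run and flags the result invalid with the failing
step/segment; batch stages count such draws as attrition, never dropping
them silently.

Extracellular potentials use the line-source kernel of each segment
(closed form via asinh) in a homogeneous medium of 0.3 S/m.  The
published electrode points (0,0,60) and (0,0,1060) lie on the z axis
where every line source also lies and the kernel diverges; default
electrodes keep those z positions but sit 5 um (half a soma diameter)
off-axis.

Randomness: one root seed per simulation, split into named independent
streams (pre-spontaneous, post-spontaneous, AMPA weights, NMDA weights)
via `SeedSequence.spawn`; every stage is bit-reproducible given its seed.

## Summary statistics

x = (f_pre, f_post, v_pre, v_post, p_syn, lag).  Rates are somatic spike
counts over duration.  Conduction speeds divide the site separation by
the mean latency of matched spikes (pre: z = 200 to z_syn - 100; post:
z_syn + 100 to 3000); matching is order-preserving one-to-one with
latency in (0, 30] ms, maximum cardinality and then minimal total latency
(exact dynamic program).  The coupling lag is the transfer-entropy-
maximizing source lag.  p_syn counts postsynaptic spikes in
[t_pre + lag - dt, t_pre + lag + dt], each credited to at most one
(nearest) presynaptic spike, normalized by the presynaptic spike count
and clipped to [0, 1]; dt defaults to 0.5 ms for simulated pairs and
1 ms for recorded-style point-process pairs.  A vector with any undefined
component is rejected and logged, not filled with sentinels.

## Transfer entropy

Spike trains are binned at 1 ms into binary occupancy.  Bivariate TE is
the plug-in conditional mutual information I(X_t; Y_{t-delta} | X-past of
length k), maximized over delta in [1, 10] ms and k in [1, 5] ms (ties to
the smallest delta).  Significance uses circular-shift surrogates of the
source (minimum shift 10 bins, 200 permutations by default); the
surrogate statistic is the same grid maximum as the observed one, so the
selection step does not bias the p-value, and the plug-in bias is shared
by construction.  p = (1 + #{TE_surr >= TE_obs})/(1 + n_perm).
Candidate directed pairs are corrected by Benjamini-Hochberg at
alpha = 0.05; survivors are re-tested with multivariate TE (source
history fixed at one bin at the stage-1 lag, target history searched to
10 ms, conditioned on one past bin of the other significant sources into
the same target).  Note the permutation floor 1/(n_perm+1): a lone
discovery among m directed pairs is only resolvable when that floor is
below alpha/m, which holds for the two-unit networks this pipeline
targets but requires raising n_perm for larger ensembles.

## Simulation-based inference

The prior is the uniform box over the nine variable parameters.  Training
pairs (theta, x) come from prior draws simulated forward; only
simulations whose pre->post TE passes its surrogate test at alpha = 0.05
enter the training set (the same filter the experimental pipeline
applies), with attrition recorded.  The conditional density q(theta | x)
is a mixture density network: 10 diagonal-Gaussian components whose
weights, means and log-sigmas are produced by a two-hidden-layer (64
units, tanh) network from the z-scored summary vector.  Training
minimizes the negative log-likelihood with Adam at default
hyperparameters (lr 1e-3, batch 256), 10 % validation split, early
stopping with patience 20, deterministic given the seed.  The MDN and
its gradients are implemented directly in numpy (the GPU-oriented SBI
stacks are deliberately not dependencies); the implementation is
validated against a conjugate linear-Gaussian oracle and by
simulation-based calibration on that toy.

Two structural choices matter for bounded parameters.  First, the
estimator works in the prior box's logit coordinates
(z = logit((theta-low)/(high-low)), z-scored): posteriors over a uniform
box press flat against its faces, a shape a Gaussian mixture in raw
coordinates cannot represent (and which made its calibration ranks
grossly non-uniform); in logit coordinates samples are inside the box by
construction, so no posterior mass leaks past the prior's support.
Density evaluations include the change-of-variables Jacobian and are
reported in theta units.  Second, each component's standard deviation is
capped at the training marginal's own scale (standardized sigma <= 1): a
conditional component broader than the marginal is never needed, and
without the cap near-flat posteriors acquire spurious edge mass.

The MAP estimate draws 10,000 samples, keeps the 200 best, runs 100
gradient-ascent steps (1e-2 in standardized coordinates, analytic
mixture gradient) and returns the best endpoint, never below the best
initializing sample.  The ascended objective is the density in the
unbounded coordinates — the posterior density relative to the uniform
prior's natural parameterization — because the raw-coordinate density of
a box-transformed mixture develops integrable spikes at the box faces
(the logit Jacobian diverges there) that are estimator artifacts, not
posterior features; the unbounded-coordinate mode tracks the posterior
bulk.

**Desk scale.**  The study-scale run (122,000 simulations of 10 s) is a
configuration, not a test requirement.  The shipped tests train on ~400
significance-filtered pairs out of 1,000 prior draws simulated for 4 s,
and calibrate on ~100 held-out filtered draws.  At this scale the
axon-diameter marginals achieve nominal coverage and the pooled
simulation-based-calibration ranks are uniform; what does not survive
the scale reduction is the sharpness of the synaptic-weight conditionals
(see Limitations).

## Synthetic data

The point-process generator emulates what sorted microchannel recordings
exhibit: a presynaptic Poisson train, and a postsynaptic train that is
baseline Poisson plus lagged (jittered, probabilistic) copies of
presynaptic spikes, merged at 1 ms resolution.  It reproduces the
generative lag exactly through the TE scan and p_transmit through p_syn
(+/- 0.05).  It does not emulate raw waveforms, sorting errors, bursting
statistics, or nonstationarity.  Condition-shift experiments scatter a
base parameter vector by 5 % of each prior range per pair ("before"),
then re-simulate with identical seeds and named multiplicative shifts
("after"), so condition differences are paired and purely parametric.
A green shift test therefore establishes sensitivity of the inference to
a stated parametric change under matched noise — not robustness to the
many experimental differences between real pre/post-stimulation
recordings.

## Limitations

- Identifiability of the synaptic weight parameters is weak: across the
  significance-filtered prior population the correlation between p_syn
  and mu_AMPA is ~0.08, because most of the AMPA range is suprathreshold
  for most postsynaptic diameters (the dose-response saturates early)
  and NMDA-driven bursting dominates many pairs.  At desk-scale training
  (~400 filtered pairs) the posterior over mu_AMPA is therefore close to
  the filtered marginal, its mode responds only weakly (and not
  monotonically) to p_syn, and a +50 % shift in the generative mu_AMPA
  shows up in inferred MAPs as elevated KS distance and positive skew
  but does not reach significance at 16 pairs per condition.  The
  corresponding end-to-end test is left failing rather than enlarging
  the effect or the compute budget.
- The weakly identified dimensions' posterior spread can exceed the
  uniform prior's standard deviation by up to ~20 % (edge-heavy
  marginals of the logit-space mixture at this training scale); the
  strongly identified parameters (diameters) always contract.
- No voltage-dependent NMDA magnesium block, short-term plasticity,
  dendrites, myelination, channel noise, or ion-concentration dynamics.
- Electrode model omits filtering, noise, and boundary effects of the
  channel walls.
- The discrete TE estimator is maximum-likelihood with surrogate-matched
  bias; continuous estimators (KSG) and large-network greedy source
  selection are out of scope.
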