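# Methods

This note documents the model equations, the parameter choices that
matter, the numerical scheme, and what the shipped defaults do and do
not establish.

## Units and conventions

Conductances in nS, currents in pA, capacitance in pF, voltage in mV,
time in ms (`nS·mV = pA`, `pA/pF = mV/ms`). Intracellular Ca is in
arbitrary concentration units scaled so the SK half-activation is order
one. Every ionic and synaptic current is written `g·(gates)·(V − E)`
(outward positive) and subtracted in `dV/dt`; injected stimulus and
noise currents are added. This is stated once here and in
`hvcnet.params` to avoid double-negation mistakes.

## Cell models

Single-compartment Hodgkin–Huxley models with the class-specific current
sets listed in the README. Gating steady states are Boltzmann sigmoids
`x∞(V) = 1/(1+exp(−(V−V_half)/k))`; time constants are either sigmoidal
in V, constant, or the published low-threshold-Ca/anomalous-rectifier
forms (scaled): the T-type activation uses the Huguenard–McCormick
relay-cell τ_m form and the H current the corresponding τ_r form. Na and
CaL activation (X/INT), the fast A-current activation, and the SK Ca
gate are instantaneous; everything else is dynamic. The per-class state
counts are exactly 6 (RA: V, h, n, s, e, Ca), 8 (X: V, h, n, mT, hT,
rf, rs, Ca) and 7 (INT: V, h, n, mT, hT, r, Ca). The X sag relaxes with
fast and slow H components (shared steady state, τ_slow = 5·τ_fast,
65% fast); INT uses a single component.

Three deliberately structural choices:

- **RA burst generator.** RA's L-type activation gate `s` is *slow*
  (τ = 5 ms, half −40 mV). A triggered RA therefore develops a Ca
  plateau that sustains a stereotyped 4–6-spike burst largely
  independent of the exact drive, and the burst terminates when Ca
  accumulated through CaL activates SK. This yields the tight burst
  statistics seen in vivo and makes relays reproducible; with an
  instantaneous CaL gate the relayed burst shrinks link by link.
- **Rebound machinery.** The T-current inactivation gate uses a
  sigmoidal τ_h (10–28 ms) rather than the published relay-cell
  piecewise form, whose recovery is far too slow (~100–300 ms) for the
  brief inhibition episodes this network produces: X neurons must
  de-inactivate within a 20–60 ms inhibitory epoch and then inactivate
  within a burst. E_GABA is −85 mV so inhibition can actually
  de-inactivate CaT below the X resting potential (−68 mV).
- **INT undershoot.** The interneuron's delayed-rectifier gate closes
  slowly (τ amplitude 1.5 ms), producing the deep spike
  afterhyperpolarization (below rest) that identifies interneurons in
  vitro, without changing its fast tonic firing.

Calcium follows `dCa/dt = −k·(I_CaL + I_CaT) − (Ca − Ca_rest)/τ_Ca` with
per-class influx and clearance; baseline Ca is near zero so SK is off at
rest. SK activation is a Hill function of Ca (coefficient 2, kd = 1).

Fixed parameters (C_m, g_Na, g_K, g_CaL, leak) were calibrated once so
that each class reproduces its current-clamp signature: delayed
plateau bursts (RA), sag + rebound bursts and SK adaptation (X), fast
tonic firing with undershoot (INT). Only the four key conductances
(g_SK, g_H, g_A, g_CaT) and the synaptic conductances are considered
variable; they are exactly the quantities the perturbation and
variability experiments manipulate.

## Synapses and noise

Two-state transmitter kinetics with a sigmoidal release function of the
presynaptic voltage (threshold −20 mV, slope 2 mV). AMPA: α = 2.5/ms,
τ_decay ≈ 3.3 ms, E = 0 mV. GABA_A: α = 1/ms, τ_decay ≈ 5.6 ms,
E = −85 mV. Conductances are drawn per edge, uniformly from per-pair
ranges (defaults in `params/defaults.yaml`); the RA→RA default of ~10 nS
matches the values used in the published delay experiments.

The background noise current is `I = σ·ξ(t)` per neuron, ξ unit-variance
Gaussian white noise, discretized as `σ·ξ_k/√dt` per step
(Euler–Maruyama), so its statistics are dt-independent. σ is configured
as a percentage of the network-wide mean synaptic conductance and
converted to pA at a 60 mV reference driving force; this conversion rule
is a documented interpretation, changeable in one place
(`NoiseConfig.sigma_pA`). Noise enters the voltage equation as a current
(numerator), frozen over each step, deterministic given the noise seed.

## Network construction

Pools (120/50/50) are partitioned into 20 circuits by rejection sampling
of iid uniform counts conditioned on the pool totals (RA 3–10, INT 1–4,
X 1–4 per circuit), so all feasible compositions are equally likely.
Within-circuit RA chains are uniformly random permutations; circuits are
linked last-RA(i)→first-RA(i+1). Each INT draws 3–8 AMPA afferents from
the whole RA pool and sends 2–4 GABA edges to RA neurons outside its
circuit and 1–2 GABA edges to X neurons inside it; each X excites 1–3
INT inside its circuit. Conductances are drawn from the per-pair ranges.
Everything is deterministic given (config, seed), and `validate_graph`
re-checks every rule by brute force.

Two construction refinements beyond the verbal rules:

- **X coverage.** The X partition is conditioned on the INT partition
  (x_i ≤ 2·int_i per circuit) and INT→X target selection prefers
  still-uninhibited X neurons. Without this, some X neurons receive no
  inhibition at all and can never fire their rebound bursts.
- **Engagement guard band.** An INT bursts at its donors' time slots, so
  its inhibitory targets are kept a couple of circuits away from every
  donor's circuit (relaxed stepwise when the network is small). This
  implements the stated intent of the engagement rules — no inhibition
  while a target elicits its burst — which the own-circuit exclusion
  alone does not guarantee at this model's short per-link delays.

## Numerics

Production integrator: fixed-step RK4 (dt = 0.01 ms) over the joint
neuron+synapse state, with stimulus and noise currents frozen within
each step; compiled with numba. Spike times are detected online at
upward crossings of −20 mV (linear interpolation between steps, 1 ms
refractory). A noiseless adaptive reference (scipy LSODA, rtol 1e-6, on
the independent numpy implementation of the same equations) is kept for
cross-checks; fixed-step and reference first-spike times agree to
< 0.5 ms, and halving dt moves first-spike times by < 0.1 ms. Initial
conditions are per-class resting states (relaxed 2 s, Newton-polished to
derivative norm < 1e-8) with synapse gates at zero; a parameter set with
no stable rest (e.g. a pathologically perturbed cell) is initialized at
−70 mV with gates at steady state and simply fires from the start.

Default motif duration is 500 ms: the 120-link chain completes in
roughly 350 ms at the calibrated per-link delay of ~2.5–3 ms, which is
faster than the real song tempo; the duration is a config knob, chosen
long enough for all 20 circuits plus the trailing X rebounds. The kick
is 0.5 nA for 8 ms to the first RA (the calibration-pulse magnitude); a
weaker, longer kick produces a straggly first burst.

## Analysis definitions

Bursts are maximal spike runs with ISIs ≤ 15 ms (minimum 2 spikes); an
*RA* burst must additionally reach 3 spikes — the lower bound of the in
vivo burst code — so a doublet left over from a suppressed burst does
not count as sequence propagation. `sequence_complete` requires every RA
neuron to emit exactly one such burst with onsets non-decreasing along
the chain. X criteria: 1–4 bursts of 4–9 spikes. INT tonicity is
operationalized as ≥ 2 bursts and no silent gap longer than 200 ms
within the active span (published interneuron records show quiescent
stretches of this order, and no numeric criterion is published).
Across-seed onset jitter is reported, not gated, as no quantitative
time-locking criterion is published.

The population-variability experiment classifies a run as *disrupted* if
the sequence breaks or the validator reports clearly more violations
than the unperturbed baseline (more than max(2×, +8)); an absolute
zero-violation standard would misclassify the baseline itself, which
carries a handful of marginal flags.

## What the defaults establish — and what they do not

With the shipped defaults, a seeded full-size build propagates a
complete, ordered RA sequence with mean burst duration ≈ 8.6–8.9 ms and
≈ 5.0 spikes/burst (within the published mean ± SD bands), X neurons
fire ≈ 2 rebound bursts of ≈ 5 spikes, interneurons stay active
throughout, background noise up to 5% of the mean synaptic conductance
is tolerated while 50% destroys propagation, and all five
paired-recording polarities (including the DC sag) are reproduced.

Known limitations:

- A minority of X neurons produce occasional rebound bursts of 2–3
  spikes (below the 4–9 band) or one burst outside the 1–4 count band in
  any given seeded run; the population means sit comfortably inside the
  bands, but per-neuron universality of the X criteria is not achieved.
- Single-neuron up-regulation of RA's g_A or g_SK (×25) eliminates that
  neuron's burst and breaks the sequence, as published. The
  interneuron/X-pathway perturbations (INT g_CaT/g_H ×10, X g_H ×10,
  g_CaT ×15, g_SK → 0) disturb the perturbed cells' firing but do *not*
  halt the RA sequence here: at any INT→RA conductance strong enough for
  one tonically active interneuron to veto its target's burst,
  physiological transient inhibition episodes break healthy propagation
  somewhere among the 120 relays. Conductance-based excitation grows
  with hyperpolarization, so inhibitory blockade requires a ~2× shunt
  that healthy INT bursts also reach for tens of milliseconds. The
  defaults are healthy-first (INT→RA 1.5–3 nS), and this gap is a
  documented property of the present calibration rather than of the
  architecture.
- The model omits NMDA and GABA_B currents, dendrites, brainstem
  feedback, temperature dependence, and silent-gap circuits; each model
  neuron stands for a synchronous population, so single-cell redundancy
  arguments are outside its scope.
- The synthetic network *is* the study object (there is no external
  data); passing tests show internal consistency with the published
  firing statistics and protocols, not goodness-of-fit to recordings.
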