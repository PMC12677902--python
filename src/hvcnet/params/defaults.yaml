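# Default parameters for the HVC network model.
#
# Units: nS, pA, pF, mV, ms.  Intracellular Ca in arbitrary concentration
# units scaled so the SK half-activation (kd) is order one.
#
# Gating convention: x_inf(V) = 1 / (1 + exp(-(V - half) / k)),
# k > 0 activation, k < 0 inactivation.  Tau kinds are documented in
# hvcnet.params.GateSpec.

reversal_potentials:
  E_Na: 50.0
  E_K: -90.0
  E_Ca: 120.0
  E_H: -43.0

kinetics:
  na:
    m: {half: -30.0, k: 9.5, exp: 3, tau: {kind: instant}}
    h: {half: -45.0, k: -7.0, exp: 1,
        tau: {kind: sigmoid, min: 0.1, amp: 0.75, half: -40.5, k: -6.0}}
  k:
    n: {half: -35.0, k: 10.0, exp: 4,
        tau: {kind: sigmoid, min: 0.1, amp: 0.5, half: -27.0, k: -15.0}}
  cal:
    s: {half: -13.0, k: 10.0, exp: 2, tau: {kind: instant}}
  cat:
    m: {half: -57.0, k: 5.5, exp: 2, tau: {kind: hm_cat_m, scale: 0.4}}
    h: {half: -75.0, k: -3.5, exp: 1,
        tau: {kind: sigmoid, min: 10.0, amp: 18.0, half: -65.0, k: -6.0}}
  h:
    r: {half: -75.0, k: -5.5, exp: 1, tau: {kind: hm_h, scale: 0.1}}
    fast_frac: 0.65      # HVC_X only: fast/slow H components
    slow_factor: 5.0     # slow-component tau multiple
  a:
    a: {half: -40.0, k: 6.0, exp: 1, tau: {kind: const, min: 0.5}}
    e: {half: -60.0, k: -6.0, exp: 1, tau: {kind: const, min: 10.0}}
  sk:
    kd: 1.0

cells:
  RA:
    C_m: 20.0
    E_L: -68.0
    conductances: {L: 2.2, Na: 1200.0, K: 250.0, CaL: 5.0, A: 10.0, SK: 7.0}
    calcium: {influx: 0.0024, tau: 40.0, rest: 0.02}
    # RA bursts are Ca-plateau driven: the L-type window activates just
    # below spike threshold so a triggered burst is regenerative and is
    # terminated by SK as Ca accumulates.
    kinetics_overrides:
      cal:
        s: {half: -40.0, k: 6.0, exp: 2, tau: {kind: const, min: 5.0}}
      a:
        a: {half: -40.0, k: 6.0, exp: 1, tau: {kind: instant}}
      na:
        h: {half: -45.0, k: -7.0, exp: 1,
            tau: {kind: sigmoid, min: 0.1, amp: 0.5, half: -40.5, k: -6.0}}
      k:
        n: {half: -35.0, k: 10.0, exp: 4,
            tau: {kind: sigmoid, min: 0.1, amp: 0.3, half: -27.0, k: -15.0}}
  X:
    C_m: 40.0
    E_L: -80.0
    conductances: {L: 2.7, Na: 1200.0, K: 450.0, CaL: 1.5, CaT: 55.0, SK: 5.0, H: 5.0}
    calcium: {influx: 0.0005, tau: 40.0, rest: 0.02}
  INT:
    C_m: 20.0
    E_L: -70.0
    conductances: {L: 2.5, Na: 600.0, K: 300.0, CaL: 1.0, CaT: 5.0, H: 3.0}
    calcium: {influx: 0.001, tau: 50.0, rest: 0.02}
    # slower K-gate closure gives the deep spike undershoot interneurons
    # show in vitro
    kinetics_overrides:
      k:
        n: {half: -35.0, k: 10.0, exp: 4,
            tau: {kind: sigmoid, min: 0.1, amp: 1.5, half: -27.0, k: -15.0}}

synapses:
  release_threshold: -20.0   # mV on the presynaptic membrane
  release_slope: 2.0         # mV; smooth transmitter sigmoid
  kinds:
    AMPA:   {alpha: 2.5, beta: 0.3,  E_rev: 0.0}
    GABA_A: {alpha: 1.0, beta: 0.18, E_rev: -85.0}
  pair_kinetics: {}
  # Per-pair maximal-conductance ranges (nS); per-edge values are drawn
  # uniformly from [lo, hi].  "default" is the midpoint used for
  # single-motif calibration runs.
  conductances:
    RA_RA:  {lo: 9.5, hi: 10.5, default: 10.0}
    RA_INT: {lo: 6.0, hi: 12.0, default: 9.0}
    X_INT:  {lo: 4.0, hi: 8.0, default: 6.0}
    INT_RA: {lo: 1.5, hi: 3.0, default: 2.25}
    INT_X:  {lo: 12.0, hi: 17.0, default: 14.5}

network:
  pools: {RA: 120, INT: 50, X: 50}
  n_circuits: 20
  ra_per_circuit: [3, 10]
  int_per_circuit: [1, 4]
  x_per_circuit: [1, 4]
  ra_to_int_in: [3, 8]     # AMPA afferents per INT, donors from full RA pool
  int_to_ra_out: [2, 4]    # GABA targets per INT, never in own circuit
  x_to_int_out: [1, 3]     # AMPA targets per X, same circuit only
  int_to_x_out: [1, 2]     # GABA targets per INT, same circuit only
  max_retries: 1000

solver:
  method: fixed_rk4_em
  dt: 0.01
  record_stride: 10
  duration: 500.0
  rel_tol: 1.0e-6
  abs_tol: 1.0e-8

stimulus:
  kick_amplitude_nA: 0.5
  kick_width_ms: 8.0
  kick_onset_ms: 5.0

noise:
  sigma_percent: 0.0
  reference_driving_force_mV: 60.0

analysis:
  spike_threshold: -20.0
  refractory: 1.0
  isi_threshold: 15.0
  min_burst_spikes: 2
  ra_spikes_per_burst: [3, 6]
  ra_max_burst_duration: 10.0
  x_bursts: [1, 4]
  x_spikes_per_burst: [4, 9]
  int_window_ms: 200.0
  int_min_bursts: 2

experiments:
  # Admissible single-conductance ranges used by the population-variability
  # experiment (our own calibrated analogue of the published box plots).
  # Admissible single-conductance ranges for the X population, derived
  # with conductance_range_search on the full default network (the range
  # is widened until the desired network activity fails).
  x_variation_ranges:
    g_CaT: [55.0, 120.0]
    g_SK: [2.3, 6.5]
    g_H: [2.3, 11.0]
  perturbation_fold_default: 25.0
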