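# hvcnet

A conductance-based network model of temporal sequence propagation in the
songbird premotor nucleus HVC.

During singing, the zebra finch HVC produces one of the most stereotyped
neural sequences known: each RA-projecting neuron fires a single sparse
burst (a handful of spikes in under 10 ms) at one precise moment per song
motif, X-projecting neurons fire a few time-locked rebound bursts, and
interneurons fire densely throughout. `hvcnet` implements a
biophysically explicit account of how local HVC circuitry alone can
generate this pattern: Hodgkin–Huxley models of the three neuron classes,
AMPA and GABA_A synapses, and a feedforward chain of microcircuits with
structured feedback inhibition.

## The model

Each neuron is a single compartment obeying

```
C_m dV/dt = -I_L - I_K - I_Na - I_CaL [- I_CaT - I_H] [- I_A] [- I_SK]
            + I_stim + I_noise - I_syn
```

with the class-specific current complement

| class   | currents                                   | state variables |
|---------|--------------------------------------------|-----------------|
| HVC_RA  | L, K, Na, CaL, A, SK                       | 6               |
| HVC_X   | L, K, Na, CaL, CaT, SK, H                  | 8               |
| HVC_INT | L, K, Na, CaL, CaT, H                      | 7               |

Every ionic and synaptic current is `g · (gates) · (V − E)`; synapses are
two-state transmitter-gated conductances
`ds/dt = α·T(V_pre)(1−s) − β·s`, `I = g·s·(V − E_rev)`, restricted to the
five class pairs found in HVC (RA→RA, RA→INT, X→INT excitatory; INT→RA,
INT→X inhibitory).

The network partitions pools of 120 RA, 50 INT and 50 X neurons (2:1:1)
into 20 chained microcircuits. RA neurons form a chain within each
circuit and across circuits; each interneuron collects AMPA input from
RA neurons anywhere in the pool but inhibits RA neurons only *outside*
its own circuit, so inhibition never lands in a target's own time slot;
X neurons interact with interneurons only within their circuit, firing
post-inhibitory rebound bursts carried by the T-type Ca and H currents.
A brief current kick to the first RA neuron launches a wave of bursts
that traverses all 120 RA neurons in order.

Key mechanisms the model exposes: the A-type K current sets the delay to
burst onset between chain neighbors; an L-type Ca plateau makes each RA
burst stereotyped; SK (Ca-activated K) terminates bursts and sets spike
counts; CaT + H produce the X sag and rebound.

## A worked example

```
$ python examples/03_motif_run.py
network: 220 neurons, 709 synapses, 20 microcircuits
sequence complete: True
RA bursts: 8.65 +/- 0.39 ms, 5.01 +/- 0.09 spikes
X projectors: 2.22 rebound bursts/neuron, 5.14 spikes/burst
interneurons: 5.92 bursts/neuron, 1288 spikes total
```

Every RA neuron fired exactly one burst, in chain order ("sequence
complete"), with burst durations and spike counts in the range reported
for singing birds; each X neuron produced a few multi-spike rebound
bursts; interneurons stayed active throughout the motif. The other
scripts in `examples/` demonstrate the single-cell signatures, the
paired-recording calibration motifs, conductance perturbations that
break the sequence, and the noise/variability robustness scans.

The same functionality is available from a thin CLI:

```
hvcnet build --seed 1 --out runs/demo        # edge list + membership
hvcnet simulate --seed 1 --out runs/demo     # traces.h5 + spikes.csv
hvcnet analyze --run runs/demo               # desired-activity report
hvcnet calibrate / perturb / sweep / noise-scan
```

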