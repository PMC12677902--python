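"""The five paired-recording calibration motifs.

Reproduces the dual-intracellular-recording protocols used to calibrate
the synapses: driving one neuron with current pulses while recording the
postsynaptic potential of its partner.  Prints the polarity and amplitude
of each response; excitatory (AMPA) connections must depolarize, the
inhibitory (GABA_A) ones hyperpolarize, and sustained inhibition of an
X-projector shows the H-current sag.
"""
from hvcnet.experiments import paired_recording_suite

report = paired_recording_suite()
for motif, m in report.items():
    extra = f", sag={m['sag']}" if "sag" in m else ""
    print(f"{motif:24s} {m['polarity']:15s} amplitude {m['amplitude']:5.1f} mV"
          f"{extra}")
print("\nA depolarizing response means the connection excites its target;")
print("a hyperpolarizing one means it inhibits. Motif D's sag is the")
print("slow relaxation produced by the hyperpolarization-activated current.")
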