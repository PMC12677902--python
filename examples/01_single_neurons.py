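"""Current-clamp signatures of the three HVC neuron classes.

Builds one model neuron of each class, applies depolarizing and
hyperpolarizing current steps, and prints the responses that identify
each class in vitro: the delayed plateau burst of the RA-projector, the
sag and post-inhibitory rebound burst of the X-projector, and the fast
tonic firing (with spike undershoot) of the interneuron.
"""
import numpy as np

from hvcnet import CellGroup, SolverConfig, StimulusProtocol, simulate
from hvcnet import default_neuron_params, resting_state


def step(cls, amp_nA, width_ms, duration):
    params = default_neuron_params(cls)
    stim = StimulusProtocol(targets=[0], amplitude_nA=amp_nA,
                            pulse_width=width_ms, onsets=[50.0])
    res = simulate(CellGroup([params], []), stim,
                   SolverConfig(duration=duration))
    return res


for cls in ("RA", "X", "INT"):
    rest = resting_state(default_neuron_params(cls))
    print(f"{cls}: resting potential {rest.V:.1f} mV")

# RA: brief ~10 ms, 0.5 nA pulse -> a single stereotyped burst
res = step("RA", 0.5, 8.0, 120.0)
sp = res.spikes[0]
print(f"RA pulse: {len(sp)} spikes, burst duration "
      f"{sp[-1] - sp[0]:.1f} ms, onset delay {sp[0] - 50.0:.1f} ms")

# X: hyperpolarizing step -> sag during the step, rebound burst at release
res = step("X", -0.2, 250.0, 450.0)
sp = res.spikes[0]
reb = sp[sp > 300.0]
seg = res.V[0][(res.t > 50) & (res.t < 300)]
print(f"X hyperpolarizing step: minimum {seg.min():.1f} mV, "
      f"sag {seg[-1] - seg.min():.1f} mV, rebound spikes {len(reb)}")

# INT: depolarizing DC -> fast tonic train
res = step("INT", 0.15, 200.0, 300.0)
isis = np.diff(res.spikes[0])
print(f"INT 150 pA DC: {len(res.spikes[0])} spikes, "
      f"mean rate {1000.0 / isis.mean():.0f} Hz")
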