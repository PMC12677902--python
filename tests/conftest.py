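import numpy as np
import pytest

from hvcnet.analysis import sequence_metrics
from hvcnet.config import RunConfig
from hvcnet.engine import run_motif
from hvcnet.netbuild import wire_network


SMALL_NETWORK = {"pools": {"RA": 36, "INT": 15, "X": 15}, "n_circuits": 6}


@pytest.fixture(scope="session")
def default_cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced 6-circuit network used where the full one is unnecessary."""
    return RunConfig(network=SMALL_NETWORK, solver={"duration": 250.0})


@pytest.fixture(scope="session")
def small_net(small_cfg):
    return wire_network(small_cfg)


@pytest.fixture(scope="session")
def small_motif(small_cfg, small_net):
    res = run_motif(small_cfg, network=small_net)
    rep = sequence_metrics(res, small_net, small_cfg.analysis)
    return res, small_net, rep


@pytest.fixture(scope="session")
def default_motif(default_cfg):
    """One full default motif (120 RA), shared across tests."""
    net = wire_network(default_cfg)
    res = run_motif(default_cfg, network=net)
    rep = sequence_metrics(res, net, default_cfg.analysis)
    return res, net, rep


@pytest.fixture(scope="session")
def ra_burst_trace():
    """A single RA neuron driven by a brief pulse: (t, V, spikes)."""
    from hvcnet.engine import CellGroup, SolverConfig, StimulusProtocol, simulate
    from hvcnet.params import default_neuron_params

    grp = CellGroup([default_neuron_params("RA")], [])
    stim = StimulusProtocol(targets=[0], amplitude_nA=0.5, pulse_width=8,
                            onsets=[40.0])
    res = simulate(grp, stim, SolverConfig(duration=120.0, record_stride=2))
    return res.t, res.V[0], res.spikes[0]
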