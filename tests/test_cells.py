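"""Single-cell model: gating, currents, resting states, class signatures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hvcnet.cells import (
    NeuronState,
    gating_steady_state,
    gating_tau,
    ionic_current,
    membrane_rhs,
    resting_state,
    rhs_vector,
    state_from_vector,
    state_to_vector,
    steady_gates,
)
from hvcnet.engine import CellGroup, SolverConfig, StimulusProtocol, simulate
from hvcnet.params import (
    CLASS_CHANNELS,
    ConfigurationError,
    STATE_DIM,
    default_neuron_params,
)

CLASSES = ("RA", "X", "INT")


@pytest.fixture(scope="module")
def cells():
    return {c: default_neuron_params(c) for c in CLASSES}


@pytest.fixture(scope="module")
def rests(cells):
    return {c: resting_state(cells[c]) for c in CLASSES}


def _dc_run(params, amp_nA, width, dur, record_stride=5):
    grp = CellGroup([params], [])
    stim = StimulusProtocol(targets=[0], amplitude_nA=amp_nA,
                            pulse_width=width, onsets=[50.0])
    return simulate(grp, stim, SolverConfig(duration=dur,
                                            record_stride=record_stride))


# ---------------------------------------------------------------------------
# gating functions
# ---------------------------------------------------------------------------

@settings(max_examples=60, deadline=None)
@given(V=st.floats(min_value=-150.0, max_value=80.0))
def test_steady_states_bounded_and_taus_positive(V):
    """Every steady state maps finite V into [0,1]; taus stay positive."""
    for cls in CLASSES:
        p = default_neuron_params(cls)
        for chan in p.channels.values():
            for spec in chan.gate_specs:
                x = gating_steady_state(chan, spec.gate_id, V)
                assert 0.0 <= x <= 1.0
                if spec.tau_kind != "instant":
                    assert gating_tau(chan, spec.gate_id, V) > 0.0


@pytest.mark.parametrize("cls", CLASSES)
def test_steady_states_monotone_and_half_activation(cls):
    """Activation gates rise with V, inactivation gates fall; the value at
    the half-(in)activation voltage is exactly 0.5."""
    V = np.linspace(-120.0, 60.0, 400)
    p = default_neuron_params(cls)
    for chan in p.channels.values():
        for spec in chan.gate_specs:
            x = gating_steady_state(chan, spec.gate_id, V)
            d = np.diff(x)
            assert np.all(d >= 0) if spec.is_activation else np.all(d <= 0)
            assert gating_steady_state(chan, spec.gate_id, spec.half) == \
                pytest.approx(0.5)


def test_activation_saturates_low():
    """Any activation gate is essentially closed far below threshold."""
    p = default_neuron_params("X")
    assert gating_steady_state(p.channels["Na"], "m", -200.0) < 0.01
    assert gating_steady_state(p.channels["CaT"], "mT", -200.0) < 0.01


def test_cat_inactivation_at_minus50_matches_hand_formula():
    """T-type inactivation at -50 mV equals the Boltzmann value computed
    independently: 1/(1+exp((-50+75)/3.5)) = 7.8886e-4."""
    p = default_neuron_params("X")
    spec = p.channels["CaT"].gate("hT")
    expected = 1.0 / (1.0 + np.exp((-50.0 - spec.half) / -spec.k))
    assert gating_steady_state(p.channels["CaT"], "hT", -50.0) == \
        pytest.approx(expected, rel=1e-12)
    # frozen against the configured half/slope (-75 mV, 3.5 mV)
    assert gating_steady_state(p.channels["CaT"], "hT", -50.0) == \
        pytest.approx(7.8987e-4, rel=1e-3)


def test_unknown_gate_raises_configuration_error():
    p = default_neuron_params("RA")
    with pytest.raises(ConfigurationError, match="Na"):
        p.channels["Na"].gate("zz")


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------

def test_ionic_current_zero_conductance_and_reversal(cells, rests):
    for cls in CLASSES:
        p, st0 = cells[cls], rests[cls]
        for chan in p.channels.values():
            z = type(chan)(chan.channel_id, 0.0, chan.E_rev, chan.gate_specs)
            assert ionic_current(z, st0, params=p) == 0.0
            at_rev = st0.copy()
            at_rev.V = chan.E_rev
            assert ionic_current(chan, at_rev, params=p) == pytest.approx(0.0)


def test_delayed_rectifier_matches_hand_product():
    """I_K at -40 mV with n at steady state equals g*n^4*(V-E_K) computed
    by independent arithmetic."""
    p = default_neuron_params("INT")
    n_inf = 1.0 / (1.0 + np.exp(-(-40.0 + 35.0) / 10.0))  # 0.37754...
    st0 = NeuronState(V=-40.0, gates=dict(steady_gates(p, -40.0)), Ca=0.0)
    st0.gates["n"] = n_inf
    expected = 300.0 * n_inf ** 4 * (-40.0 - (-90.0))
    assert ionic_current(p.channels["K"], st0, params=p) == \
        pytest.approx(expected, rel=1e-12)


def test_membrane_rhs_all_conductances_zero(cells):
    for cls in CLASSES:
        p = cells[cls].copy()
        for chan in p.channels.values():
            chan.g_max = 0.0
        st0 = NeuronState(V=-55.0, gates=steady_gates(p, -55.0),
                          Ca=p.calcium.rest)
        d = membrane_rhs(p, st0)
        assert d.V == pytest.approx(0.0)


def test_leak_only_neuron_rests_at_EL():
    p = default_neuron_params("RA")
    for name, chan in p.channels.items():
        if name != "L":
            chan.g_max = 0.0
    st0 = NeuronState(V=p.channels["L"].E_rev,
                      gates=steady_gates(p, p.channels["L"].E_rev),
                      Ca=p.calcium.rest)
    d = membrane_rhs(p, st0)
    assert d.V == pytest.approx(0.0, abs=1e-12)
    # gates relax toward steady state from a displaced value
    st0.gates["h"] = 0.2
    d = membrane_rhs(p, st0)
    assert d.gates["h"] > 0.0
    rs = resting_state(p)
    assert rs.V == pytest.approx(p.channels["L"].E_rev, abs=1e-6)


# ---------------------------------------------------------------------------
# state dimensions and resting states
# ---------------------------------------------------------------------------

def test_state_dimensions_exactly_6_8_7(cells, rests):
    assert STATE_DIM == {"RA": 6, "X": 8, "INT": 7}
    for cls in CLASSES:
        vec = state_to_vector(cells[cls], rests[cls])
        assert vec.shape == (STATE_DIM[cls],)
        back = state_from_vector(cells[cls], vec)
        assert back.V == rests[cls].V


def test_channel_sets_match_class_lists():
    assert set(CLASS_CHANNELS["RA"]) == {"L", "K", "Na", "CaL", "A", "SK"}
    assert set(CLASS_CHANNELS["X"]) == {"L", "K", "Na", "CaL", "CaT", "SK", "H"}
    assert set(CLASS_CHANNELS["INT"]) == {"L", "K", "Na", "CaL", "CaT", "H"}
    with pytest.raises(ConfigurationError):
        default_neuron_params("RA").set_conductance("g_H", 1.0)


@pytest.mark.parametrize("cls", CLASSES)
def test_resting_state_is_fixed_point(cls, cells, rests):
    y = state_to_vector(cells[cls], rests[cls])
    assert np.linalg.norm(rhs_vector(cells[cls], y)) < 1e-8


def test_doubling_gH_depolarizes_X_rest():
    lo = resting_state(default_neuron_params("X"))
    hi = resting_state(default_neuron_params(
        "X", {"g_H": 2 * default_neuron_params("X").conductance("H")}))
    assert hi.V > lo.V + 0.5


# ---------------------------------------------------------------------------
# class signatures under current clamp
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cls", ["X", "INT"])
def test_sag_and_rebound_under_hyperpolarizing_step(cls, rests):
    p = default_neuron_params(cls)
    res = _dc_run(p, -0.2, 250.0, 450.0)
    t, V = res.t, res.V[0]
    inh = (t > 50.0) & (t < 300.0)
    t_inh, v_inh = t[inh], V[inh]
    i_min = int(np.argmin(v_inh))
    # sag: the minimum precedes the hyperpolarized steady state
    assert t_inh[i_min] < t_inh[-1] - 50.0
    assert v_inh[-1] > v_inh[i_min] + 1.0
    # post-inhibitory rebound at release: overshoot or rebound spikes
    post = V[(t > 300.0) & (t < 400.0)]
    rebound_spikes = np.sum(res.spikes[0] > 300.0)
    assert rebound_spikes >= 1 or post.max() > rests[cls].V + 2.0


def test_ra_delayed_onset_shrinks_with_gA(rests):
    """Near-threshold depolarizing steps evoke delayed spiking in RA; the
    delay decreases as g_A decreases."""
    delays = {}
    for ga in (5.0, 10.0, 15.0):
        p = default_neuron_params("RA", {"g_A": ga})
        res = _dc_run(p, 0.15, 200.0, 300.0)
        assert len(res.spikes[0]) > 0
        delays[ga] = res.spikes[0][0] - 50.0
    assert delays[5.0] < delays[10.0] < delays[15.0]
    assert delays[10.0] > 1.0


def test_int_spikes_undershoot_rest(rests):
    res = _dc_run(default_neuron_params("INT"), 0.15, 200.0, 300.0,
                  record_stride=1)
    sp = res.spikes[0]
    assert len(sp) > 10  # fast tonic firing
    t, V = res.t, res.V[0]
    # troughs between spikes dip below the resting potential
    troughs = [V[(t > a) & (t < b)].min() for a, b in zip(sp[:-1], sp[1:])]
    assert np.median(troughs) < rests["INT"].V - 1.0


def test_ra_burst_rides_on_plateau(ra_burst_trace, rests):
    """Minimum inter-spike voltage within the pulse-evoked burst stays
    well above rest."""
    t, V, sp = ra_burst_trace
    assert 3 <= len(sp) <= 6
    troughs = [V[(t > a) & (t < b)].min() for a, b in zip(sp[:-1], sp[1:])]
    assert min(troughs) > rests["RA"].V + 8.0


def test_x_sk_adaptation_ordering():
    """With g_SK > 0, ISIs of a DC-evoked X train are non-decreasing
    (SK-mediated adaptation); with g_SK = 0 that ordering is lost."""
    res = _dc_run(default_neuron_params("X"), 0.2, 150.0, 250.0)
    isis = np.diff(res.spikes[0])[:10]
    assert len(isis) >= 6
    assert np.all(np.diff(isis) >= -0.05)  # non-decreasing (tolerance 50 us)
    res0 = _dc_run(default_neuron_params("X", {"g_SK": 0.0}), 0.2, 150.0, 250.0)
    isis0 = np.diff(res0.spikes[0])[:10]
    assert np.any(np.diff(isis0) < -0.5)  # ordering broken without SK


# ---------------------------------------------------------------------------
# kernel vs readable implementation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cls", CLASSES)
def test_kernel_rhs_matches_reference(cls, cells):
    """The compiled kernel computes the same derivatives as the numpy
    reference equations at random states."""
    from hvcnet import _kernel as kern
    from hvcnet._pack import _pack

    p = cells[cls]
    pack = _pack([p], [])
    rng = np.random.default_rng(7)
    for _ in range(25):
        V = rng.uniform(-90.0, 30.0)
        st0 = NeuronState(V=V, gates=steady_gates(p, rng.uniform(-90, 0)),
                          Ca=abs(rng.normal(0.3, 0.2)))
        y = state_to_vector(p, st0)
        ref = rhs_vector(p, y, I_syn=0.0, I_stim=12.0)
        Y = np.zeros(pack["n_state"])
        Y[0] = y[0]
        Y[pack["off"][0]:] = y[1:]
        dY = np.empty_like(Y)
        Iext = np.array([12.0])
        buf = np.empty(1)
        kern.rhs(Y, dY, pack["cls"], pack["C"], pack["Gn"], pack["EL"],
                 pack["K"], pack["off"], pack["pre"], pack["post"],
                 pack["gsyn"], pack["esyn"], pack["asyn"], pack["bsyn"],
                 pack["syn0"], -20.0, 2.0, Iext, buf)
        got = np.concatenate(([dY[0]], dY[pack["off"][0]:]))
        np.testing.assert_allclose(got, ref, rtol=1e-10, atol=1e-12)


def test_gates_stay_bounded_along_trajectory():
    """Gate values remain in [0,1] and Ca >= 0 along a driven trajectory."""
    from scipy.integrate import solve_ivp

    p = default_neuron_params("X")
    y0 = state_to_vector(p, resting_state(p))

    def f(t, y):
        I = 300.0 if 20 <= t < 60 else (-250.0 if 100 <= t < 160 else 0.0)
        return rhs_vector(p, y, I_stim=I)

    sol = solve_ivp(f, (0, 220), y0, method="LSODA", rtol=1e-6, atol=1e-9,
                    max_step=0.5)
    gates = sol.y[1:-1]  # V first, Ca last for X layout
    assert gates.min() >= -1e-9 and gates.max() <= 1.0 + 1e-9
    assert sol.y[-1].min() >= 0.0
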