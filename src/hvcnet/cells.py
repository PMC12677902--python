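"""Single-compartment Hodgkin–Huxley models of HVC_RA, HVC_X and HVC_INT.

This module is the readable, numpy reference implementation of the cell
models; the network engine compiles the same equations into a fast kernel
(:mod:`hvcnet._kernel`) and the two are cross-checked in the test suite.

Model structure
---------------
Each class carries the ionic currents identified pharmacologically for it:

- HVC_RA:  I_L, I_K, I_Na, I_CaL, I_A, I_SK           (6 state variables)
- HVC_X:   I_L, I_K, I_Na, I_CaL, I_CaT, I_SK, I_H    (8 state variables)
- HVC_INT: I_L, I_K, I_Na, I_CaL, I_CaT, I_H          (7 state variables)

Na activation, the SK Ca-gate and the fast A-current activation are
instantaneous; Na inactivation (h), delayed-rectifier activation (n),
RA's L-type Ca activation (s, the slow plateau gate), A-current
inactivation (e), T-type activation/inactivation (mT, hT) and H-current
activation (r; fast+slow components rf, rs in HVC_X) are dynamic, along
with intracellular Ca.  (HVC_X and HVC_INT use instantaneous L-type
activation.)

``dV/dt = (-sum(I_ionic) + I_stim + I_noise - I_syn) / C_m`` where every
ionic and synaptic current is ``g * gates * (V - E)`` (outward positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    ChannelParams,
    ConfigurationError,
    GateSpec,
    NeuronParams,
    STATE_VARS,
    h_components,
)

__all__ = [
    "NeuronState",
    "RestingStateError",
    "gating_steady_state",
    "gating_tau",
    "ionic_current",
    "membrane_rhs",
    "resting_state",
    "rhs_vector",
    "state_from_vector",
    "state_to_vector",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _tau_hm_cat_m(V, scale):
    return scale * (
        0.612 + 1.0 / (np.exp(-(V + 131.6) / 16.7) + np.exp((V + 16.8) / 18.2))
    )


def _tau_hm_h(V, scale):
    return scale / (np.exp(-14.59 - 0.086 * V) + np.exp(-1.87 + 0.0701 * V))


def _gate_inf(spec: GateSpec, V):
    return _sigmoid((V - spec.half) / spec.k)


def _gate_tau(spec: GateSpec, V):
    p = spec.tau_params
    if spec.tau_kind == "sigmoid":
        return p["min"] + p["amp"] * _sigmoid((V - p["half"]) / p["k"])
    if spec.tau_kind == "const":
        return p["min"] * np.ones_like(np.asarray(V, dtype=float))
    if spec.tau_kind == "hm_cat_m":
        return _tau_hm_cat_m(V, p["scale"])
    if spec.tau_kind == "hm_h":
        return _tau_hm_h(V, p["scale"])
    if spec.tau_kind == "instant":
        raise ConfigurationError(f"gate {spec.gate_id} is instantaneous; it has no tau")
    raise ConfigurationError(f"unknown tau kind {spec.tau_kind!r}")


def gating_steady_state(channel: ChannelParams, gate_id: str, V):
    """Steady-state value of one gating variable at voltage ``V`` (in [0,1])."""
    return _gate_inf(channel.gate(gate_id), V)


def gating_tau(channel: ChannelParams, gate_id: str, V):
    """Voltage-dependent time constant (ms) of one gating variable."""
    return _gate_tau(channel.gate(gate_id), V)


def sk_activation(Ca, kd: float):
    """Ca-dependent SK activation, Hill coefficient 2."""
    ca = np.maximum(Ca, 0.0)
    return ca * ca / (ca * ca + kd * kd)


# ---------------------------------------------------------------------------
# state container
# ---------------------------------------------------------------------------

@dataclass
class NeuronState:
    """Membrane state: voltage, dynamic gates, intracellular Ca."""

    V: float
    gates: dict[str, float] = field(default_factory=dict)
    Ca: float = 0.0

    def copy(self) -> "NeuronState":
        return NeuronState(self.V, dict(self.gates), self.Ca)


def state_to_vector(params: NeuronParams, state: NeuronState) -> np.ndarray:
    names = STATE_VARS[params.neuron_class]
    out = np.empty(len(names))
    for i, nm in enumerate(names):
        if nm == "V":
            out[i] = state.V
        elif nm == "Ca":
            out[i] = state.Ca
        else:
            out[i] = state.gates[nm]
    return out


def state_from_vector(params: NeuronParams, y: np.ndarray) -> NeuronState:
    names = STATE_VARS[params.neuron_class]
    if len(y) != len(names):
        raise ConfigurationError(
            f"state vector length {len(y)} != {len(names)} for class "
            f"{params.neuron_class}"
        )
    gates = {}
    V = Ca = 0.0
    for nm, val in zip(names, y):
        if nm == "V":
            V = float(val)
        elif nm == "Ca":
            Ca = float(val)
        else:
            gates[nm] = float(val)
    return NeuronState(V=V, gates=gates, Ca=Ca)


def steady_gates(params: NeuronParams, V: float) -> dict[str, float]:
    """All dynamic gates at their steady-state values for voltage ``V``."""
    cls = params.neuron_class
    ch = params.channels
    g: dict[str, float] = {}
    g["h"] = float(gating_steady_state(ch["Na"], "h", V))
    g["n"] = float(gating_steady_state(ch["K"], "n", V))
    if cls == "RA":
        g["s"] = float(gating_steady_state(ch["CaL"], "s", V))
        g["e"] = float(gating_steady_state(ch["A"], "e", V))
    else:
        g["mT"] = float(gating_steady_state(ch["CaT"], "mT", V))
        g["hT"] = float(gating_steady_state(ch["CaT"], "hT", V))
        r = float(gating_steady_state(ch["H"], "r", V))
        if cls == "X":
            g["rf"] = r
            g["rs"] = r
        else:
            g["r"] = r
    return g


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------

def _ca_currents(params: NeuronParams, state: NeuronState) -> float:
    """Sum of Ca-carrying currents (pA, outward positive)."""
    total = ionic_current(params.channels["CaL"], state)
    if "CaT" in params.channels:
        total += ionic_current(params.channels["CaT"], state, params=params)
    return total


def ionic_current(
    channel: ChannelParams,
    state: NeuronState,
    sk_kd: float | None = None,
    params: NeuronParams | None = None,
) -> float:
    """Current through one channel at the given state (pA, outward positive).

    ``I = g_max * prod(gate^exponent) * (V - E_rev)``; SK multiplies the
    Ca-dependent Hill activation instead of voltage gates.  Instantaneous
    gates (Na ``m``, CaL ``s``) are evaluated at ``state.V``; dynamic gate
    values are read from ``state.gates``.
    """
    V = state.V
    drive = V - channel.E_rev
    if channel.channel_id == "L":
        return channel.g_max * drive
    if channel.channel_id == "SK":
        kd = sk_kd if sk_kd is not None else (params.sk.kd if params else 0.5)
        return channel.g_max * sk_activation(state.Ca, kd) * drive
    open_frac = 1.0
    for spec in channel.gate_specs:
        if spec.tau_kind == "instant":
            x = _gate_inf(spec, V)
        else:
            if spec.gate_id == "r" and spec.gate_id not in state.gates:
                # two-component H current (HVC_X): weighted fast/slow gates
                f, s, _ = h_components("X")
                x = f * state.gates["rf"] + s * state.gates["rs"]
            else:
                x = state.gates[spec.gate_id]
        open_frac = open_frac * x ** spec.exponent
    return channel.g_max * open_frac * drive


def membrane_rhs(
    params: NeuronParams,
    state: NeuronState,
    I_syn: float = 0.0,
    I_stim: float = 0.0,
    I_noise: float = 0.0,
) -> NeuronState:
    """Time derivative of the full membrane state.

    Returns a :class:`NeuronState` whose fields hold d/dt values.
    ``I_stim``/``I_noise`` are injected currents (depolarizing positive);
    ``I_syn`` follows the ``g*s*(V - E)`` convention and is subtracted.
    """
    cls = params.neuron_class
    ch = params.channels
    V = state.V

    I_ion = 0.0
    for c in ch.values():
        I_ion += ionic_current(c, state, params=params)

    dV = (-I_ion + I_stim + I_noise - I_syn) / params.C_m

    d: dict[str, float] = {}

    def relax(channel_id, gate_id, key=None):
        spec = ch[channel_id].gate(gate_id)
        x = state.gates[key or gate_id]
        return (_gate_inf(spec, V) - x) / _gate_tau(spec, V)

    d["h"] = relax("Na", "h")
    d["n"] = relax("K", "n")
    if cls == "RA":
        d["s"] = relax("CaL", "s")
        d["e"] = relax("A", "e")
    else:
        d["mT"] = relax("CaT", "mT")
        d["hT"] = relax("CaT", "hT")
        if cls == "X":
            spec = ch["H"].gate("r")
            _, _, slow = h_components("X")
            rinf = _gate_inf(spec, V)
            tau = _gate_tau(spec, V)
            d["rf"] = (rinf - state.gates["rf"]) / tau
            d["rs"] = (rinf - state.gates["rs"]) / (slow * tau)
        else:
            d["r"] = relax("H", "r")

    cap = params.calcium
    dCa = -cap.influx * _ca_currents(params, state) - (state.Ca - cap.rest) / cap.tau
    return NeuronState(V=dV, gates=d, Ca=dCa)


def rhs_vector(params: NeuronParams, y: np.ndarray, I_syn=0.0, I_stim=0.0, I_noise=0.0) -> np.ndarray:
    """Vector form of :func:`membrane_rhs` for ODE solvers."""
    st = state_from_vector(params, y)
    dst = membrane_rhs(params, st, I_syn=I_syn, I_stim=I_stim, I_noise=I_noise)
    return state_to_vector(params, dst)


# ---------------------------------------------------------------------------
# resting state
# ---------------------------------------------------------------------------

class RestingStateError(RuntimeError):
    """Raised when an unstimulated neuron fails to settle to a fixed point.

    Carries the final stretch of the relaxation trajectory for diagnosis.
    """

    def __init__(self, msg, t=None, V=None):
        super().__init__(msg)
        self.t = t
        self.V = V


def resting_state(
    params: NeuronParams,
    horizon: float = 2000.0,
    tol: float = 1e-8,
    v0: float = -70.0,
) -> NeuronState:
    """Stable resting point of the unstimulated neuron.

    Relaxes from ``v0`` for ``horizon`` ms (long enough for the slow H
    current to settle) with the fixed-step kernel, polishes with a Newton
    solve, and verifies the derivative norm is below ``tol``.  An
    oscillating or runaway membrane (e.g. a spontaneously spiking
    parameter set) is rejected with the relaxation trajectory attached.
    """
    from . import _kernel as kern
    from ._pack import _pack

    st0 = NeuronState(V=v0, gates=steady_gates(params, v0), Ca=params.calcium.rest)
    y0 = state_to_vector(params, st0)

    pack = _pack([params], [])
    Y0 = np.zeros(pack["n_state"])
    Y0[0] = y0[0]
    Y0[pack["off"][0]:] = y0[1:]
    dt = 0.02
    n_steps = int(round(horizon / dt))
    empty_i = np.empty(0, dtype=np.int64)
    empty_f = np.empty(0, dtype=float)
    Vrec, sp_times, sp_counts, blow_step, _, Yend = kern.integrate(
        Y0, pack["cls"], pack["C"], pack["Gn"], pack["EL"], pack["K"],
        pack["off"], pack["pre"], pack["post"], pack["gsyn"], pack["esyn"],
        pack["asyn"], pack["bsyn"], pack["syn0"], -20.0, 2.0,
        empty_i, empty_f, empty_f, empty_f,
        dt, n_steps, 50, 0.0, 0, -20.0, 1.0, 100,
    )
    t_grid = np.arange(Vrec.shape[1]) * dt * 50
    if blow_step >= 0 or not np.all(np.isfinite(Yend)):
        raise RestingStateError(
            f"{params.neuron_class}: relaxation diverged", t=t_grid, V=Vrec[0],
        )
    tail = Vrec[0, t_grid > 0.9 * horizon]
    late_spikes = int((sp_times[0, :sp_counts[0]] > 0.5 * horizon).sum())
    if late_spikes > 0 or (tail.size and (tail.max() - tail.min()) > 1.0):
        raise RestingStateError(
            f"{params.neuron_class}: membrane does not settle "
            f"(spikes or oscillation during relaxation)",
            t=t_grid, V=Vrec[0],
        )
    y_end = np.concatenate(([Yend[0]], Yend[pack["off"][0]:]))

    from scipy.optimize import root

    res = root(lambda y: rhs_vector(params, y), y_end, method="hybr", tol=1e-12)
    y_star = res.x if res.success else y_end
    if np.linalg.norm(rhs_vector(params, y_star)) > tol:
        raise RestingStateError(
            f"{params.neuron_class}: derivative norm "
            f"{np.linalg.norm(rhs_vector(params, y_star)):.2e} above tolerance {tol}",
            t=sol.t, V=sol.y[0],
        )
    return state_from_vector(params, y_star)
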