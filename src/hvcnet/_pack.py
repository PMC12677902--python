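"""Packing of neuron/synapse parameters into kernel arrays."""

from __future__ import annotations

import numpy as np

from . import _kernel as kern
from .params import ConfigurationError, NeuronParams, STATE_DIM, h_components
from .synapses import Synapse

_CLS_ID = {"RA": kern.CLS_RA, "X": kern.CLS_X, "INT": kern.CLS_INT}


def _kinetic_row(p: NeuronParams) -> np.ndarray:
    """Pack one class's kinetic constants into a kernel row."""
    row = np.ones(kern.NK)
    ch = p.channels

    def put(idx, val):
        row[idx] = float(val)

    m = ch["Na"].gate("m")
    put(kern.K_M_HALF, m.half); put(kern.K_M_K, m.k)
    h = ch["Na"].gate("h")
    put(kern.K_H_HALF, h.half); put(kern.K_H_K, h.k)
    put(kern.K_H_TMIN, h.tau_params["min"]); put(kern.K_H_TAMP, h.tau_params["amp"])
    put(kern.K_H_THALF, h.tau_params["half"]); put(kern.K_H_TK, h.tau_params["k"])
    n = ch["K"].gate("n")
    put(kern.K_N_HALF, n.half); put(kern.K_N_K, n.k)
    put(kern.K_N_TMIN, n.tau_params["min"]); put(kern.K_N_TAMP, n.tau_params["amp"])
    put(kern.K_N_THALF, n.tau_params["half"]); put(kern.K_N_TK, n.tau_params["k"])
    s = ch["CaL"].gate("s")
    put(kern.K_S_HALF, s.half); put(kern.K_S_K, s.k)
    put(kern.K_S_TAU,
        s.tau_params["min"] if s.tau_kind == "const" else 0.0)
    if "CaT" in ch:
        mT = ch["CaT"].gate("mT"); hT = ch["CaT"].gate("hT")
        put(kern.K_MT_HALF, mT.half); put(kern.K_MT_K, mT.k)
        put(kern.K_MT_TSCALE, mT.tau_params["scale"])
        put(kern.K_HT_HALF, hT.half); put(kern.K_HT_K, hT.k)
        put(kern.K_HT_TMIN2, hT.tau_params["min"])
        put(kern.K_HT_TAMP2, hT.tau_params["amp"])
        put(kern.K_HT_THALF2, hT.tau_params["half"])
        put(kern.K_HT_TK2, hT.tau_params["k"])
    if "H" in ch:
        r = ch["H"].gate("r")
        put(kern.K_R_HALF, r.half); put(kern.K_R_K, r.k)
        put(kern.K_R_TSCALE, r.tau_params["scale"])
        f, _, slow = h_components(p.neuron_class)
        put(kern.K_R_FFRAC, f); put(kern.K_R_SLOWF, slow)
        put(kern.K_E_H, ch["H"].E_rev)
    if "A" in ch:
        a = ch["A"].gate("a"); e = ch["A"].gate("e")
        put(kern.K_A_HALF, a.half); put(kern.K_A_K, a.k)
        put(kern.K_A_TAU, a.tau_params["min"])
        put(kern.K_E_HALF, e.half); put(kern.K_E_K, e.k)
        put(kern.K_E_TAU, e.tau_params["min"])
    put(kern.K_SK_KD, p.sk.kd)
    put(kern.K_CA_INFLUX, p.calcium.influx)
    put(kern.K_CA_TAU, p.calcium.tau)
    put(kern.K_CA_REST, p.calcium.rest)
    put(kern.K_E_NA, ch["Na"].E_rev)
    put(kern.K_E_K_REV, ch["K"].E_rev)
    put(kern.K_E_CA, ch["CaL"].E_rev)
    return row


_G_COL = {"L": kern.G_L, "Na": kern.G_NA, "K": kern.G_K, "CaL": kern.G_CAL,
          "CaT": kern.G_CAT, "SK": kern.G_SK, "A": kern.G_A, "H": kern.G_H}


def _pack(neurons: list[NeuronParams], synapses: list[Synapse]):
    N = len(neurons)
    cls = np.array([_CLS_ID[p.neuron_class] for p in neurons], dtype=np.int64)
    C = np.array([p.C_m for p in neurons])
    EL = np.array([p.channels["L"].E_rev for p in neurons])
    Gn = np.zeros((N, kern.NG))
    for i, p in enumerate(neurons):
        for name, chan in p.channels.items():
            Gn[i, _G_COL[name]] = chan.g_max

    K = np.ones((3, kern.NK))
    seen = {}
    for p in neurons:
        if p.neuron_class not in seen:
            seen[p.neuron_class] = p
            K[_CLS_ID[p.neuron_class]] = _kinetic_row(p)
    # kinetics must be homogeneous within a class (only conductances vary)
    for p in neurons:
        ref = _kinetic_row(p)
        if not np.allclose(ref, K[_CLS_ID[p.neuron_class]]):
            raise ConfigurationError(
                "per-neuron kinetic constants differ within class "
                f"{p.neuron_class}; only maximal conductances may vary"
            )

    off = np.empty(N, dtype=np.int64)
    pos = N
    for i, p in enumerate(neurons):
        off[i] = pos
        pos += STATE_DIM[p.neuron_class] - 1
    syn0 = pos
    n_state = syn0 + len(synapses)

    pre = np.array([s.pre for s in synapses], dtype=np.int64)
    post = np.array([s.post for s in synapses], dtype=np.int64)
    gsyn = np.array([s.g for s in synapses], dtype=float)
    esyn = np.array([s.kinetics.E_rev for s in synapses], dtype=float)
    asyn = np.array([s.kinetics.alpha for s in synapses], dtype=float)
    bsyn = np.array([s.kinetics.beta for s in synapses], dtype=float)
    if pre.size and (pre.min() < 0 or pre.max() >= N or post.min() < 0 or post.max() >= N):
        raise ConfigurationError("synapse endpoint out of range")

    return dict(cls=cls, C=C, Gn=Gn, EL=EL, K=K, off=off, syn0=syn0,
                n_state=n_state, pre=pre, post=post, gsyn=gsyn, esyn=esyn,
                asyn=asyn, bsyn=bsyn)


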