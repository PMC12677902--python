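"""AMPA and GABA_A synapses and the stochastic background current.

Synaptic currents follow the two-state transmitter-driven scheme: each
directed edge carries a gating variable ``s`` obeying

    ds/dt = alpha * T(V_pre) * (1 - s) - beta * s

where ``T`` is a sigmoid of the presynaptic voltage around the release
threshold (default -20 mV), so ``s`` rises while the presynaptic cell is
spiking and decays with time constant ``1/beta`` otherwise.  The current
onto the postsynaptic cell is ``I = g * s * (V_post - E_rev)`` and the
per-neuron synaptic current is the sum over afferent edges.

The paper's network restricts which class pairs may be connected; those
rules are enforced here via :data:`ALLOWED_PAIRS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ConfigurationError, load_defaults

__all__ = [
    "ALLOWED_PAIRS",
    "NoiseConfig",
    "Synapse",
    "SynapseKinetics",
    "allowed_kind",
    "default_kinetics",
    "noise_current",
    "synapse_gate_rhs",
    "synaptic_current",
    "transmitter",
]

#: (pre class, post class) -> required synapse kind.  No other pair exists.
ALLOWED_PAIRS = {
    ("RA", "RA"): "AMPA",
    ("RA", "INT"): "AMPA",
    ("X", "INT"): "AMPA",
    ("INT", "RA"): "GABA_A",
    ("INT", "X"): "GABA_A",
}


def allowed_kind(pre_class: str, post_class: str) -> str:
    try:
        return ALLOWED_PAIRS[(pre_class, post_class)]
    except KeyError:
        raise ConfigurationError(
            f"no synapse is allowed from {pre_class} to {post_class}"
        ) from None


@dataclass
class SynapseKinetics:
    """Rise rate (1/ms), decay rate (1/ms) and reversal (mV) of one kind."""

    alpha: float
    beta: float
    E_rev: float

    @property
    def tau_decay(self) -> float:
        return 1.0 / self.beta


def default_kinetics() -> dict[str, SynapseKinetics]:
    raw = load_defaults()["synapses"]
    return {
        kind: SynapseKinetics(float(d["alpha"]), float(d["beta"]), float(d["E_rev"]))
        for kind, d in raw["kinds"].items()
    }


def pair_kinetics(pre_class: str, post_class: str) -> SynapseKinetics:
    """Kinetics for a class pair: the kind's defaults unless the pair has
    a specific override (e.g. slowly integrating INT->RA inhibition)."""
    raw = load_defaults()["synapses"]
    pair = f"{pre_class}_{post_class}"
    if pair in raw.get("pair_kinetics", {}):
        d = raw["pair_kinetics"][pair]
        return SynapseKinetics(float(d["alpha"]), float(d["beta"]),
                               float(d["E_rev"]))
    return default_kinetics()[allowed_kind(pre_class, post_class)]


def release_params() -> tuple[float, float]:
    """(threshold mV, slope mV) of the transmitter sigmoid."""
    raw = load_defaults()["synapses"]
    return float(raw["release_threshold"]), float(raw["release_slope"])


@dataclass
class Synapse:
    """One directed synapse."""

    pre: int
    post: int
    kind: str  # "AMPA" | "GABA_A"
    g: float  # nS
    s: float = 0.0
    kinetics: SynapseKinetics | None = None

    def __post_init__(self):
        if self.kind not in ("AMPA", "GABA_A"):
            raise ConfigurationError(f"unknown synapse kind {self.kind!r}")
        if self.g < 0:
            raise ConfigurationError("synaptic conductance must be >= 0")
        if self.kinetics is None:
            self.kinetics = default_kinetics()[self.kind]

    @property
    def E_rev(self) -> float:
        return self.kinetics.E_rev


def transmitter(V_pre, threshold: float | None = None, slope: float | None = None):
    """Transmitter-release drive in [0, 1] as a function of V_pre."""
    if threshold is None or slope is None:
        thr, slp = release_params()
        threshold = thr if threshold is None else threshold
        slope = slp if slope is None else slope
    return 1.0 / (1.0 + np.exp(-(np.asarray(V_pre, dtype=float) - threshold) / slope))


def synapse_gate_rhs(syn: Synapse, V_pre: float) -> float:
    """ds/dt of one synapse for the given presynaptic voltage."""
    T = float(transmitter(V_pre))
    k = syn.kinetics
    return k.alpha * T * (1.0 - syn.s) - k.beta * syn.s


def synaptic_current(synapses, V_post: float) -> float:
    """Total synaptic current onto one neuron: sum g*s*(V_post - E_rev).

    All synapses must share the same postsynaptic neuron; zero for an
    empty collection.
    """
    syns = list(synapses)
    if not syns:
        return 0.0
    posts = {s.post for s in syns}
    if len(posts) > 1:
        raise ConfigurationError(
            f"synaptic_current called with mixed postsynaptic neurons {posts}"
        )
    return float(sum(s.g * s.s * (V_post - s.E_rev) for s in syns))


@dataclass
class NoiseConfig:
    """Background current noise.

    ``sigma_percent`` expresses the amplitude as a percentage of the
    network-wide mean synaptic maximal conductance; it is converted to a
    current amplitude (pA) at a reference driving force (default 60 mV):
    ``sigma_pA = (sigma_percent/100) * mean_g * driving_force``.  The
    injected process is ``I_noise(t) = sigma_pA * xi(t)`` with unit-variance
    Gaussian white noise, discretized as ``sigma_pA * xi_k / sqrt(dt)`` per
    step (Euler–Maruyama), giving dt-independent statistics.
    """

    sigma_percent: float = 0.0
    seed: int = 0
    reference_driving_force: float = 60.0

    def __post_init__(self):
        if self.sigma_percent < 0:
            raise ConfigurationError("noise sigma must be >= 0")

    def sigma_pA(self, mean_synaptic_g: float) -> float:
        return self.sigma_percent / 100.0 * mean_synaptic_g * self.reference_driving_force


def noise_current(cfg: NoiseConfig, dt: float, rng: np.random.Generator,
                  mean_synaptic_g: float = 1.0, size=None):
    """One (or ``size``) noise-current sample(s) for a step of length dt."""
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    sig = cfg.sigma_pA(mean_synaptic_g)
    if sig == 0.0:
        return np.zeros(size) if size else 0.0
    draw = rng.standard_normal(size) if size else rng.standard_normal()
    return sig * draw / np.sqrt(dt)
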