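"""Parameter containers for the three HVC neuron classes.

Units used throughout the package: conductance nS, current pA, capacitance
pF, voltage mV, time ms, intracellular calcium in arbitrary concentration
units (a.c.u., scaled so the SK half-activation is order one).  With these
units ``nS * mV = pA`` and ``pA / pF = mV/ms``, so no conversion constants
appear in the right-hand sides.

Sign convention: every ionic and synaptic current is written as
``g * (V - E)`` (positive = outward) and *subtracted* in ``dV/dt``;
stimulus and noise currents are injected (positive = depolarizing) and
*added*.
"""

from __future__ import annotations

import copy
import functools
import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import yaml

CLASSES = ("RA", "X", "INT")

#: Ionic channel complement of each class.
CLASS_CHANNELS = {
    "RA": ("L", "K", "Na", "CaL", "A", "SK"),
    "X": ("L", "K", "Na", "CaL", "CaT", "SK", "H"),
    "INT": ("L", "K", "Na", "CaL", "CaT", "H"),
}

#: Ordered state variables per class.  Activation of Na, CaL and SK is
#: treated as instantaneous; the slower gates are dynamic.  The resulting
#: per-class dimensions are 6 (RA), 8 (X) and 7 (INT).
STATE_VARS = {
    "RA": ("V", "h", "n", "s", "e", "Ca"),
    "X": ("V", "h", "n", "mT", "hT", "rf", "rs", "Ca"),
    "INT": ("V", "h", "n", "mT", "hT", "r", "Ca"),
}

STATE_DIM = {cls: len(v) for cls, v in STATE_VARS.items()}

#: Gate ids owned by each channel (dynamic and instantaneous).
CHANNEL_GATES = {
    "Na": ("m", "h"),
    "K": ("n",),
    "CaL": ("s",),
    "CaT": ("mT", "hT"),
    "A": ("a", "e"),
    "H": ("r",),
    "L": (),
    "SK": (),  # gated by Ca, not by voltage
}

#: Which gates are rising (activation) vs falling (inactivation) with V.
ACTIVATION_GATES = {"m", "n", "s", "mT", "a", "r_is_not"}  # r handled below
INACTIVATION_GATES = {"h", "hT", "e", "r"}  # H-current activates on hyperpolarization


class ConfigurationError(ValueError):
    """Raised for inconsistent neuron/channel/network configuration."""


@dataclass
class GateSpec:
    """Steady state and time constant of one gating variable.

    The steady state is the Boltzmann sigmoid
    ``x_inf(V) = 1 / (1 + exp(-(V - half) / k))`` with ``k > 0`` for
    activation gates and ``k < 0`` for inactivation gates.  ``tau_kind``
    selects the functional form of the voltage-dependent time constant:

    - ``"sigmoid"``: ``tau_min + tau_amp * sigmoid((V - tau_half)/tau_k)``
    - ``"hm_cat_m"`` / ``"hm_cat_h"``: low-threshold Ca kinetics
      (Huguenard–McCormick relay-cell forms, scaled by ``tau_scale``)
    - ``"hm_h"``: anomalous-rectifier (H) kinetics, scaled by ``tau_scale``
    - ``"const"``: constant ``tau_min``
    - ``"instant"``: gate slaved to its steady state (no ODE)
    """

    gate_id: str
    exponent: int
    half: float
    k: float
    tau_kind: str = "instant"
    tau_params: dict = field(default_factory=dict)

    @property
    def is_activation(self) -> bool:
        return self.k > 0


@dataclass
class ChannelParams:
    """One ionic current: maximal conductance, reversal, gating."""

    channel_id: str
    g_max: float
    E_rev: float
    gate_specs: list[GateSpec] = field(default_factory=list)

    def __post_init__(self):
        if self.g_max < 0:
            raise ConfigurationError(
                f"channel {self.channel_id}: g_max must be >= 0, got {self.g_max}"
            )
        for gs in self.gate_specs:
            if gs.exponent < 1 or int(gs.exponent) != gs.exponent:
                raise ConfigurationError(
                    f"channel {self.channel_id}, gate {gs.gate_id}: "
                    f"exponent must be a positive integer"
                )

    def gate(self, gate_id: str) -> GateSpec:
        for gs in self.gate_specs:
            if gs.gate_id == gate_id:
                return gs
        raise ConfigurationError(
            f"channel {self.channel_id} has no gate {gate_id!r} "
            f"(available: {[g.gate_id for g in self.gate_specs]})"
        )


@dataclass
class CalciumParams:
    """First-order intracellular Ca balance.

    ``dCa/dt = -influx * (I_CaL + I_CaT) - (Ca - rest) / tau`` with inward
    (negative) Ca currents raising Ca.  ``rest`` is chosen small enough
    that SK is essentially off at the resting potential.
    """

    influx: float  # a.c.u. per pA per ms
    tau: float  # ms
    rest: float  # a.c.u.


@dataclass
class SKParams:
    """Ca-dependent activation of the SK current: Hill function
    ``k_inf(Ca) = Ca^2 / (Ca^2 + kd^2)``."""

    kd: float


@dataclass
class NeuronParams:
    """Complete single-compartment model of one HVC neuron class."""

    neuron_class: str
    C_m: float  # pF
    channels: dict[str, ChannelParams]
    calcium: CalciumParams
    sk: SKParams

    def __post_init__(self):
        if self.neuron_class not in CLASSES:
            raise ConfigurationError(f"unknown neuron class {self.neuron_class!r}")
        expected = set(CLASS_CHANNELS[self.neuron_class])
        got = set(self.channels)
        if expected != got:
            raise ConfigurationError(
                f"class {self.neuron_class}: channel set {sorted(got)} does not "
                f"match required {sorted(expected)}"
            )

    @property
    def state_vars(self) -> tuple[str, ...]:
        return STATE_VARS[self.neuron_class]

    @property
    def state_dim(self) -> int:
        return STATE_DIM[self.neuron_class]

    def copy(self) -> "NeuronParams":
        return copy.deepcopy(self)

    def conductance(self, name: str) -> float:
        """Maximal conductance by short name, e.g. ``"SK"`` or ``"g_SK"``."""
        key = name[2:] if name.startswith("g_") else name
        if key not in self.channels:
            raise ConfigurationError(
                f"class {self.neuron_class} has no channel {key!r}"
            )
        return self.channels[key].g_max

    def set_conductance(self, name: str, value: float) -> None:
        key = name[2:] if name.startswith("g_") else name
        if key not in self.channels:
            raise ConfigurationError(
                f"class {self.neuron_class} has no channel {key!r}"
            )
        if value < 0:
            raise ConfigurationError(f"g_{key} must be >= 0, got {value}")
        self.channels[key].g_max = value


# ---------------------------------------------------------------------------
# default parameter file
# ---------------------------------------------------------------------------

def _defaults_text() -> str:
    return (
        importlib.resources.files("hvcnet")
        .joinpath("params/defaults.yaml")
        .read_text()
    )


@functools.lru_cache(maxsize=1)
def _load_defaults_cached() -> dict:
    return yaml.safe_load(_defaults_text())


def load_defaults() -> dict:
    """Contents of the shipped default parameter file (a fresh copy)."""
    return copy.deepcopy(_load_defaults_cached())


def _gate_from_yaml(gate_id: str, d: Mapping) -> GateSpec:
    tau = d.get("tau", {"kind": "instant"})
    return GateSpec(
        gate_id=gate_id,
        exponent=int(d.get("exp", 1)),
        half=float(d["half"]),
        k=float(d["k"]),
        tau_kind=tau.get("kind", "instant"),
        tau_params={k: float(v) for k, v in tau.items() if k != "kind"},
    )


def _deep_merge(base, override):
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def neuron_params_from_dict(cls: str, raw: dict) -> NeuronParams:
    """Assemble :class:`NeuronParams` for one class from the parsed YAML."""
    rev = raw["reversal_potentials"]
    kin = raw["kinetics"]
    cell = raw["cells"][cls]
    ko = cell.get("kinetics_overrides")
    if ko:
        kin = _deep_merge(kin, ko)
    g = cell["conductances"]

    def chan(channel_id: str, g_key: str, E: float, gates: list[GateSpec]):
        return ChannelParams(channel_id, float(g[g_key]), E, gates)

    channels: dict[str, ChannelParams] = {}
    channels["L"] = chan("L", "L", float(cell["E_L"]), [])
    channels["Na"] = chan(
        "Na", "Na", float(rev["E_Na"]),
        [_gate_from_yaml("m", kin["na"]["m"]), _gate_from_yaml("h", kin["na"]["h"])],
    )
    channels["K"] = chan("K", "K", float(rev["E_K"]), [_gate_from_yaml("n", kin["k"]["n"])])
    channels["CaL"] = chan("CaL", "CaL", float(rev["E_Ca"]), [_gate_from_yaml("s", kin["cal"]["s"])])
    if "CaT" in CLASS_CHANNELS[cls]:
        channels["CaT"] = chan(
            "CaT", "CaT", float(rev["E_Ca"]),
            [_gate_from_yaml("mT", kin["cat"]["m"]), _gate_from_yaml("hT", kin["cat"]["h"])],
        )
    if "A" in CLASS_CHANNELS[cls]:
        channels["A"] = chan(
            "A", "A", float(rev["E_K"]),
            [_gate_from_yaml("a", kin["a"]["a"]), _gate_from_yaml("e", kin["a"]["e"])],
        )
    if "SK" in CLASS_CHANNELS[cls]:
        channels["SK"] = chan("SK", "SK", float(rev["E_K"]), [])
    if "H" in CLASS_CHANNELS[cls]:
        channels["H"] = chan("H", "H", float(rev["E_H"]), [_gate_from_yaml("r", kin["h"]["r"])])

    ca = cell["calcium"]
    return NeuronParams(
        neuron_class=cls,
        C_m=float(cell["C_m"]),
        channels=channels,
        calcium=CalciumParams(float(ca["influx"]), float(ca["tau"]), float(ca["rest"])),
        sk=SKParams(float(kin["sk"]["kd"])),
    )


def default_neuron_params(cls: str, overrides: Mapping | None = None) -> NeuronParams:
    """Default parameters for one class, optionally overriding conductances.

    ``overrides`` maps conductance names (``"g_SK"``/``"SK"``) or ``"C_m"``
    to values.
    """
    raw = load_defaults()
    p = neuron_params_from_dict(cls, raw)
    if overrides:
        for key, val in overrides.items():
            if key == "C_m":
                p.C_m = float(val)
            else:
                p.set_conductance(key, float(val))
    return p


def h_components(cls: str) -> tuple[float, float, float]:
    """(fast fraction, slow fraction, slow/fast tau ratio) of the H current.

    HVC_X sags relax with a fast and a slow component; its H current is
    split into two gating variables with a shared steady state.  HVC_INT
    uses a single component.
    """
    raw = load_defaults()
    hk = raw["kinetics"]["h"]
    if cls == "X":
        f = float(hk["fast_frac"])
        return f, 1.0 - f, float(hk["slow_factor"])
    return 1.0, 0.0, 1.0
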