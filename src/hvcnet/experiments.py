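"""Scripted in-silico experiments.

Reproductions of the study's protocols: the five paired-recording
calibration motifs, conductance perturbations that break sequence
propagation, the population-variability experiment on the X conductances,
admissible-range searches, and noise-tolerance scans.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .analysis import psp_metrics, sequence_metrics
from .config import RunConfig
from .engine import CellGroup, SolverConfig, StimulusProtocol, run_motif, simulate
from .netbuild import NetworkGraph, wire_network
from .params import CLASS_CHANNELS, ConfigurationError, default_neuron_params
from .synapses import NoiseConfig, Synapse

__all__ = [
    "Perturbation",
    "SweepSpec",
    "apply_perturbation",
    "conductance_range_search",
    "noise_tolerance_scan",
    "paired_recording_suite",
    "perturbation_battery",
    "population_variability_experiment",
]


@dataclass
class Perturbation:
    """A change to one conductance on selected neurons.

    ``targets`` is a list of neuron ids, or "population" for every neuron
    of ``neuron_class``.  ``mode`` "scale" multiplies the conductance by
    ``value`` (fold-change > 0); "set" assigns ``value`` nS.
    """

    neuron_class: str
    parameter: str  # e.g. "g_CaT"
    mode: str  # "scale" | "set"
    value: float
    targets: list[int] | str = "population"

    def __post_init__(self):
        if self.mode not in ("scale", "set"):
            raise ConfigurationError(f"unknown perturbation mode {self.mode!r}")
        if self.mode == "scale" and self.value <= 0:
            raise ConfigurationError("fold-change must be > 0")
        key = self.parameter[2:] if self.parameter.startswith("g_") else self.parameter
        if key not in CLASS_CHANNELS[self.neuron_class]:
            raise ConfigurationError(
                f"class {self.neuron_class} has no conductance {self.parameter!r}"
            )


@dataclass
class SweepSpec:
    parameters: dict[str, tuple[float, float]]  # name -> (lo, hi)
    n_sims: int = 100
    level: str = "population"  # "population" | "individual"
    seed: int = 0

    def __post_init__(self):
        if self.n_sims < 1:
            raise ConfigurationError("n_sims must be >= 1")
        for name, (lo, hi) in self.parameters.items():
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"bad range for {name}: [{lo}, {hi}]")


def apply_perturbation(net: NetworkGraph, pert: Perturbation) -> NetworkGraph:
    """Deep-copied network with the stated conductance(s) changed."""
    out = copy.deepcopy(net)
    if pert.targets == "population":
        ids = [i for i in range(out.n_neurons)
               if out.neuron_class(i) == pert.neuron_class]
    else:
        ids = list(pert.targets)
        for nid in ids:
            if out.neuron_class(nid) != pert.neuron_class:
                raise ConfigurationError(
                    f"neuron {nid} is {out.neuron_class(nid)}, "
                    f"not {pert.neuron_class}"
                )
    for nid in ids:
        p = out.neuron_params[nid]
        if pert.mode == "scale":
            p.set_conductance(pert.parameter,
                              p.conductance(pert.parameter) * pert.value)
        else:
            p.set_conductance(pert.parameter, pert.value)
    return out


# ---------------------------------------------------------------------------
# Fig-2-style paired-recording calibration motifs
# ---------------------------------------------------------------------------

def _pulse_train(target, onsets, width=10.0, amp=0.5):
    return StimulusProtocol(targets=[target], waveform="pulse_train",
                            amplitude_nA=amp, pulse_width=width,
                            onsets=list(onsets))


def paired_recording_suite(cfg: RunConfig | None = None) -> dict:
    """Run the five dual-recording calibration motifs.

    Motifs (10 ms, 0.5 nA pulse trains unless stated):

    - A: RA -> INT -> X disynaptic; X shows hyperpolarizing PSPs.
    - B: RA -> INT monosynaptic; INT shows depolarizing PSPs.
    - C: INT -> X pulses; X shows fast iPSPs.
    - D: INT -> X, 500 ms DC; X shows sustained hyperpolarization with sag.
    - E: X -> INT; INT shows depolarizing PSPs.

    Returns per-motif PSP polarity and amplitude of the recorded neuron.
    """
    cfg = cfg or RunConfig()
    sc = cfg.synapse_conductances
    onsets = [100.0, 200.0, 300.0, 400.0]
    solver = SolverConfig(duration=600.0, dt=cfg.solver.dt,
                          record_stride=cfg.solver.record_stride)

    def run(neuron_classes, synapses, stim, recorded, solver=solver,
            resp=None):
        grp = CellGroup([default_neuron_params(c) for c in neuron_classes],
                        synapses)
        res = simulate(grp, stim, solver)
        base = (stim.onsets[0] - 60.0, stim.onsets[0] - 10.0)
        if resp is None:
            # the synaptic response to the first pulse, before any
            # post-inhibitory rebound can contribute
            resp = (stim.onsets[0], stim.onsets[0] + stim.pulse_width + 10.0)
        m = psp_metrics(res.t, res.V[recorded], base, resp)
        m["n_spikes_driven"] = len(res.spikes[stim.targets[0]])
        return m, res

    report: dict[str, dict] = {}
    # A: RA->X disynaptic via INT
    syns = [Synapse(0, 1, "AMPA", sc["RA_INT"].default),
            Synapse(1, 2, "GABA_A", sc["INT_X"].default)]
    report["A_RA_to_X_disynaptic"], _ = run(["RA", "INT", "X"], syns,
                                            _pulse_train(0, onsets), 2)
    # B: RA->INT
    report["B_RA_to_INT"], _ = run(
        ["RA", "INT"], [Synapse(0, 1, "AMPA", sc["RA_INT"].default)],
        _pulse_train(0, onsets), 1)
    # C: INT->X pulses
    report["C_INT_to_X_pulses"], _ = run(
        ["INT", "X"], [Synapse(0, 1, "GABA_A", sc["INT_X"].default)],
        _pulse_train(0, onsets), 1)
    # D: INT->X, 500 ms DC: sustained hyperpolarization with sag
    stim_d = StimulusProtocol(targets=[0], amplitude_nA=0.5,
                              pulse_width=500.0, onsets=[100.0])
    solver_d = SolverConfig(duration=800.0, dt=cfg.solver.dt,
                            record_stride=cfg.solver.record_stride)
    m, res = run(["INT", "X"], [Synapse(0, 1, "GABA_A", sc["INT_X"].default)],
                 stim_d, 1, solver=solver_d, resp=(100.0, 600.0))
    # sag: within the DC window the minimum precedes partial relaxation
    t, V = res.t, res.V[1]
    inh = (t >= 100.0) & (t <= 600.0)
    t_inh, v_inh = t[inh], V[inh]
    i_min = int(np.argmin(v_inh))
    sag_amp = float(v_inh[-1] - v_inh[i_min])
    m["sag"] = bool(t_inh[i_min] < t_inh[-1] - 100.0 and sag_amp > 0.5)
    m["sag_amplitude"] = sag_amp
    report["D_INT_to_X_dc"] = m
    # E: X->INT
    report["E_X_to_INT"], _ = run(
        ["X", "INT"], [Synapse(0, 1, "AMPA", sc["X_INT"].default)],
        _pulse_train(0, onsets), 1)
    return report


# ---------------------------------------------------------------------------
# canonical perturbation battery
# ---------------------------------------------------------------------------

def population_desired(rep, cfg: RunConfig) -> bool:
    """Population-level desired-activity check: the RA sequence is complete
    and the X population's burst statistics stay inside the published
    bands (mean bursts/neuron 1-4, mean spikes/burst 4-9)."""
    blo, bhi = cfg.analysis.x_bursts
    slo, shi = cfg.analysis.x_spikes_per_burst
    xs = rep.stats["X"]
    return bool(rep.sequence_complete
                and blo <= xs.n_bursts_mean <= bhi
                and np.isfinite(xs.spikes_per_burst_mean)
                and slo <= xs.spikes_per_burst_mean <= shi)


def canonical_perturbations(cfg: RunConfig) -> dict[str, Perturbation]:
    """The seven class/conductance changes that each break the sequence."""
    fold = cfg.experiments.perturbation_fold_default
    return {
        "RA_gA_up": Perturbation("RA", "g_A", "scale", fold),
        "RA_gSK_up": Perturbation("RA", "g_SK", "scale", fold),
        "INT_gCaT_x10": Perturbation("INT", "g_CaT", "scale", 10.0),
        "INT_gH_x10": Perturbation("INT", "g_H", "scale", 10.0),
        "X_gH_x10": Perturbation("X", "g_H", "scale", 10.0),
        "X_gCaT_x15": Perturbation("X", "g_CaT", "scale", 15.0),
        "X_gSK_zero": Perturbation("X", "g_SK", "set", 0.0),
    }


def _target_ids(net: NetworkGraph, cls: str, rng: np.random.Generator, k: int = 1):
    ids = [i for i in range(net.n_neurons) if net.neuron_class(i) == cls]
    if cls == "RA":
        # perturb a mid-chain neuron so a break is observable downstream
        chain = net.chain_order
        ids = chain[len(chain) // 3: 2 * len(chain) // 3]
    return [int(x) for x in rng.choice(ids, size=k, replace=False)]


def perturbation_battery(cfg: RunConfig | None = None,
                         net: NetworkGraph | None = None,
                         rng: np.random.Generator | None = None) -> dict:
    """Run the baseline plus the seven canonical single-neuron perturbations.

    Each perturbation targets one neuron of the stated class (a single
    model neuron stands for a whole population); the report records
    whether the RA sequence stays complete and where it breaks.
    """
    cfg = cfg or RunConfig()
    net = net or wire_network(cfg)
    rng = rng or np.random.default_rng(cfg.seeds.network + 1)

    rows = {}

    def classify(network, label):
        res = run_motif(cfg, network=network, noise_seed=cfg.seeds.noise)
        rep = sequence_metrics(res, network, cfg.analysis)
        rows[label] = {
            "sequence_complete": rep.sequence_complete,
            "break_point": rep.break_point,
            "n_violations": rep.n_violations,
        }
        return rep

    classify(net, "baseline")
    for name, pert in canonical_perturbations(cfg).items():
        targeted = Perturbation(pert.neuron_class, pert.parameter, pert.mode,
                                pert.value,
                                targets=_target_ids(net, pert.neuron_class, rng))
        rows[name] = {"targets": targeted.targets}
        res = run_motif(cfg, network=apply_perturbation(net, targeted),
                        noise_seed=cfg.seeds.noise)
        rep = sequence_metrics(res, net, cfg.analysis)
        rows[name].update({
            "sequence_complete": rep.sequence_complete,
            "break_point": rep.break_point,
            "n_violations": rep.n_violations,
        })
    return rows


# ---------------------------------------------------------------------------
# population variability (Fig-12-style)
# ---------------------------------------------------------------------------

def population_variability_experiment(n_sims: int = 100,
                                      cfg: RunConfig | None = None,
                                      rng: np.random.Generator | None = None,
                                      net: NetworkGraph | None = None) -> dict:
    """Vary (g_CaT, g_SK, g_H) of the whole X population per simulation.

    Each run draws one value per conductance uniformly from the
    configured admissible ranges, applies it to every X neuron, runs a
    motif and classifies the outcome with the desired-activity validator.
    Returns the disrupted fraction with a 95% binomial (Wilson) interval.
    """
    cfg = cfg or RunConfig()
    rng = rng or np.random.default_rng(cfg.seeds.network + 2)
    net = net or wire_network(cfg)
    ranges = cfg.experiments.x_variation_ranges

    # a run is disrupted if the RA sequence breaks or the X population's
    # firing departs from the published pattern at the population level
    # (mean bursts/neuron outside 1-4, mean spikes/burst outside 4-9)
    disrupted = 0
    outcomes = []
    for _ in range(n_sims):
        pert_net = net
        draws = {}
        for name, (lo, hi) in ranges.items():
            val = float(rng.uniform(lo, hi))
            draws[name] = val
            pert_net = apply_perturbation(
                pert_net, Perturbation("X", name, "set", val))
        res = run_motif(cfg, network=pert_net, noise_seed=cfg.seeds.noise)
        rep = sequence_metrics(res, net, cfg.analysis)
        ok = population_desired(rep, cfg)
        outcomes.append({"draws": draws, "desired": ok,
                         "n_violations": rep.n_violations,
                         "x_bursts_mean": rep.stats["X"].n_bursts_mean,
                         "x_spb_mean": rep.stats["X"].spikes_per_burst_mean,
                         "break_point": rep.break_point})
        disrupted += int(not ok)

    frac = disrupted / n_sims
    z = 1.959963984540054
    denom = 1 + z * z / n_sims
    center = (frac + z * z / (2 * n_sims)) / denom
    half = z * np.sqrt(frac * (1 - frac) / n_sims
                       + z * z / (4 * n_sims * n_sims)) / denom
    return {
        "n_sims": n_sims,
        "disrupted_fraction": frac,
        "ci95": (max(0.0, center - half), min(1.0, center + half)),
        "outcomes": outcomes,
    }


# ---------------------------------------------------------------------------
# admissible-range search
# ---------------------------------------------------------------------------

def conductance_range_search(parameter: str, neuron_class: str = None,
                             cfg: RunConfig | None = None,
                             net: NetworkGraph | None = None,
                             n_steps: int = 6,
                             grow: float = 1.6,
                             synaptic: bool = False) -> dict:
    """Expand an interval around the default value until failure bounds it.

    Starting from the default (which must itself validate), the tested
    value is repeatedly multiplied (divided) by ``grow`` until the
    validator fails or ``n_steps`` is exhausted; the widest passing
    interval and the tested grid are returned.
    """
    cfg = cfg or RunConfig()
    net = net or wire_network(cfg)

    if synaptic:
        default = cfg.synapse_conductances[parameter].default
    else:
        default = default_neuron_params(neuron_class).conductance(parameter)

    def passes(value):
        if synaptic:
            test = copy.deepcopy(net)
            for s in test.synapses:
                pair = f"{test.neuron_class(s.pre)}_{test.neuron_class(s.post)}"
                if pair == parameter:
                    s.g = value
        else:
            test = apply_perturbation(
                net, Perturbation(neuron_class, parameter, "set", value))
        res = run_motif(cfg, network=test, noise_seed=cfg.seeds.noise)
        rep = sequence_metrics(res, net, cfg.analysis)
        return population_desired(rep, cfg)

    if not passes(default):
        raise ConfigurationError(
            f"baseline {parameter}={default} fails validation; "
            "range search undefined"
        )

    grid = {default: True}
    lo = hi = default
    v = default
    for _ in range(n_steps):
        v = v * grow
        ok = passes(v)
        grid[v] = ok
        if not ok:
            break
        hi = v
    v = default
    for _ in range(n_steps):
        v = v / grow
        ok = passes(v)
        grid[v] = ok
        if not ok:
            break
        lo = v
    return {"parameter": parameter, "default": default,
            "admissible": (lo, hi),
            "tested": {round(k, 6): bool(ok) for k, ok in grid.items()}}


# ---------------------------------------------------------------------------
# noise tolerance
# ---------------------------------------------------------------------------

def noise_tolerance_scan(sigma_grid=(1.0, 2.0, 3.0, 4.0, 5.0),
                         n_seeds: int = 3,
                         cfg: RunConfig | None = None,
                         net: NetworkGraph | None = None) -> dict:
    """Largest noise amplitude (percent of mean synaptic g) that always
    leaves the RA sequence complete across ``n_seeds`` noise seeds."""
    cfg = cfg or RunConfig()
    net = net or wire_network(cfg)
    rows = {}
    largest = 0.0
    for sigma in sigma_grid:
        seq = []
        for k in range(n_seeds):
            c = RunConfig(**_override(cfg, sigma))
            res = run_motif(c, network=net, noise_seed=1000 + k)
            rep = sequence_metrics(res, net, c.analysis)
            seq.append(bool(rep.sequence_complete))
        rows[sigma] = seq
        if all(seq):
            largest = max(largest, sigma)
    return {"grid": rows, "largest_passing_sigma_percent": largest}


def _override(cfg: RunConfig, sigma_percent: float) -> dict:
    d = cfg.dump()
    d["noise"]["sigma_percent"] = sigma_percent
    return d
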