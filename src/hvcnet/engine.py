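"""Time integration of single cells and whole networks.

The production integrator is fixed-step RK4 with Euler–Maruyama noise
(:mod:`hvcnet._kernel`), default dt = 0.01 ms.  A noiseless adaptive
reference integrator (scipy ``solve_ivp`` on the readable numpy equations
of :mod:`hvcnet.cells`/:mod:`hvcnet.synapses`) is kept for cross-checks;
adaptive stepping is ill-posed with white noise, so the reference refuses
nonzero sigma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernel as kern
from ._pack import _pack
from .cells import (
    resting_state,
    rhs_vector,
    state_to_vector,
    steady_gates,
    NeuronState,
)
from .params import (
    CLASSES,
    ConfigurationError,
    NeuronParams,
    STATE_DIM,
    h_components,
)
from .synapses import NoiseConfig, Synapse, release_params

__all__ = [
    "CellGroup",
    "SimResult",
    "SimulationError",
    "SolverConfig",
    "StimulusProtocol",
    "simulate",
    "run_motif",
]

_CLS_ID = {"RA": kern.CLS_RA, "X": kern.CLS_X, "INT": kern.CLS_INT}


class SimulationError(RuntimeError):
    """Runaway (non-finite) membrane state during integration."""

    def __init__(self, msg, t_blowup=None, neuron=None):
        super().__init__(msg)
        self.t_blowup = t_blowup
        self.neuron = neuron


@dataclass
class StimulusProtocol:
    """Injected current pulses.

    ``waveform`` "dc_pulse" applies one pulse per onset of ``pulse_width``
    ms; "pulse_train" is the same thing with several onsets.  Amplitude is
    in nA (1 nA = 1000 pA), matching the units the calibration protocols
    are quoted in.
    """

    targets: list[int] = field(default_factory=list)
    waveform: str = "dc_pulse"
    amplitude_nA: float = 0.0
    pulse_width: float = 10.0
    onsets: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.waveform not in ("dc_pulse", "pulse_train"):
            raise ConfigurationError(f"unknown waveform {self.waveform!r}")
        if not np.isfinite(self.amplitude_nA):
            raise ConfigurationError("stimulus amplitude must be finite")
        if self.pulse_width <= 0:
            raise ConfigurationError("pulse width must be > 0")
        if sorted(self.onsets) != list(self.onsets):
            raise ConfigurationError("stimulus onsets must be sorted")

    def pulses(self) -> list[tuple[int, float, float, float]]:
        """(target, amplitude_pA, t_on, t_off) per pulse."""
        out = []
        for t0 in self.onsets:
            for tgt in self.targets:
                out.append((tgt, self.amplitude_nA * 1000.0, t0, t0 + self.pulse_width))
        return out


@dataclass
class SolverConfig:
    method: str = "fixed_rk4_em"
    dt: float = 0.01  # ms
    record_stride: int = 10  # record every record_stride-th step
    duration: float = 1000.0  # ms
    rel_tol: float = 1e-6
    abs_tol: float = 1e-8

    def __post_init__(self):
        if self.dt <= 0 or self.duration <= 0:
            raise ConfigurationError("solver.dt and solver.duration must be > 0")
        if self.method not in ("fixed_rk4_em", "adaptive_reference"):
            raise ConfigurationError(f"unknown solver method {self.method!r}")


@dataclass
class CellGroup:
    """A plain collection of neurons and synapses (ad-hoc motifs)."""

    neurons: list[NeuronParams]
    synapses: list[Synapse] = field(default_factory=list)

    @property
    def neuron_classes(self) -> list[str]:
        return [p.neuron_class for p in self.neurons]


@dataclass
class SimResult:
    """Time grid, voltage traces, spike times and run provenance."""

    t: np.ndarray  # recorded time grid (ms)
    V: np.ndarray  # (n_neurons, len(t)) membrane potentials
    spikes: list[np.ndarray]  # per-neuron sorted spike times (ms)
    classes: list[str]
    duration: float
    dt: float
    stimulus: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    def save(self, h5_path, spikes_csv=None):
        import h5py

        with h5py.File(h5_path, "w") as f:
            f.create_dataset("t", data=self.t)
            f.create_dataset("V", data=self.V, compression="gzip", compression_opts=4)
            g = f.create_group("spikes")
            for i, sp in enumerate(self.spikes):
                g.create_dataset(str(i), data=sp)
            f.attrs["classes"] = json.dumps(self.classes)
            f.attrs["duration"] = self.duration
            f.attrs["dt"] = self.dt
            f.attrs["stimulus"] = json.dumps(self.stimulus)
            f.attrs["seeds"] = json.dumps(self.seeds)
        if spikes_csv is not None:
            import pandas as pd

            rows = [
                (i, self.classes[i], t)
                for i in range(self.n_neurons)
                for t in self.spikes[i]
            ]
            pd.DataFrame(rows, columns=["neuron_id", "class", "spike_time_ms"]).to_csv(
                spikes_csv, index=False
            )

    @classmethod
    def load(cls, h5_path):
        import h5py

        try:
            with h5py.File(h5_path, "r") as f:
                t = f["t"][:]
                V = f["V"][:]
                nsp = len(f["spikes"])
                spikes = [f["spikes"][str(i)][:] for i in range(nsp)]
                return cls(
                    t=t,
                    V=V,
                    spikes=spikes,
                    classes=json.loads(f.attrs["classes"]),
                    duration=float(f.attrs["duration"]),
                    dt=float(f.attrs["dt"]),
                    stimulus=json.loads(f.attrs["stimulus"]),
                    seeds=json.loads(f.attrs["seeds"]),
                )
        except (OSError, KeyError) as e:
            raise ConfigurationError(f"not a valid SimResult file: {h5_path} ({e})")


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

_REST_CACHE: dict = {}


def _initial_state(neurons, pack) -> np.ndarray:
    """Per-class resting states for every neuron; synapse gates at zero.

    A neuron with no stable fixed point (e.g. a pathologically perturbed
    cell that fires spontaneously) is initialized at -70 mV with gates at
    their steady states; its ongoing activity is then part of the
    simulated dynamics.
    """
    from .cells import RestingStateError, steady_gates

    Y0 = np.zeros(pack["n_state"])
    for i, p in enumerate(neurons):
        key = (p.neuron_class, p.C_m,
               tuple(sorted((k, c.g_max, c.E_rev) for k, c in p.channels.items())),
               p.calcium.influx, p.calcium.tau, p.calcium.rest, p.sk.kd)
        if key not in _REST_CACHE:
            try:
                _REST_CACHE[key] = resting_state(p)
            except RestingStateError:
                _REST_CACHE[key] = NeuronState(
                    V=-70.0, gates=steady_gates(p, -70.0),
                    Ca=p.calcium.rest)
        st = _REST_CACHE[key]
        vec = state_to_vector(p, st)
        Y0[i] = vec[0]
        k = STATE_DIM[p.neuron_class] - 1
        Y0[pack["off"][i]:pack["off"][i] + k] = vec[1:]
    return Y0


def _neurons_synapses(net):
    """Accept a NetworkGraph or a CellGroup."""
    if hasattr(net, "neuron_params"):
        return net.neuron_params, net.synapses
    return net.neurons, net.synapses


def simulate(
    net,
    stim: StimulusProtocol | None = None,
    solver: SolverConfig | None = None,
    noise: NoiseConfig | None = None,
    spike_threshold: float = -20.0,
    refractory: float = 1.0,
    initial_state: np.ndarray | None = None,
    validate: bool = True,
) -> SimResult:
    """Integrate all neuron and synapse state variables jointly.

    Initial conditions are per-class resting states with synapse gates at
    zero.  Fully reproducible from (network, noise.seed, solver).
    """
    stim = stim or StimulusProtocol()
    solver = solver or SolverConfig()
    noise = noise or NoiseConfig()

    if validate and hasattr(net, "validate"):
        violations = net.validate()
        if violations:
            raise ConfigurationError(
                f"network fails validation ({len(violations)} rule violations); "
                f"first: {violations[0]}"
            )

    neurons, synapses = _neurons_synapses(net)
    N = len(neurons)
    for tgt in stim.targets:
        if not (0 <= tgt < N):
            raise ConfigurationError(f"stimulus target {tgt} does not exist")

    pack = _pack(neurons, synapses)
    Y0 = initial_state if initial_state is not None else _initial_state(neurons, pack)
    if len(Y0) != pack["n_state"]:
        raise ConfigurationError("initial state has wrong dimension")

    mean_g = float(np.mean(pack["gsyn"])) if len(synapses) else 0.0
    sigma = noise.sigma_pA(mean_g)

    pulses = stim.pulses()
    p_target = np.array([p[0] for p in pulses], dtype=np.int64)
    p_amp = np.array([p[1] for p in pulses], dtype=float)
    p_on = np.array([p[2] for p in pulses], dtype=float)
    p_off = np.array([p[3] for p in pulses], dtype=float)

    rel_thr, rel_slope = release_params()
    n_steps = int(round(solver.duration / solver.dt))

    if solver.method == "adaptive_reference":
        if sigma > 0 or noise.sigma_percent > 0:
            raise ConfigurationError(
                "adaptive_reference cannot integrate white noise; use fixed_rk4_em"
            )
        return _simulate_reference(
            neurons, synapses, pack, Y0, stim, solver,
            spike_threshold, refractory,
        )

    Vrec, sp_times, sp_counts, blow_step, blow_neuron, _ = kern.integrate(
        Y0, pack["cls"], pack["C"], pack["Gn"], pack["EL"], pack["K"], pack["off"],
        pack["pre"], pack["post"], pack["gsyn"], pack["esyn"], pack["asyn"],
        pack["bsyn"], pack["syn0"], rel_thr, rel_slope,
        p_target, p_amp, p_on, p_off,
        solver.dt, n_steps, solver.record_stride,
        sigma, int(noise.seed) & 0x7FFFFFFF,
        spike_threshold, refractory, 4000,
    )
    if blow_step >= 0:
        raise SimulationError(
            f"non-finite membrane state at t={blow_step * solver.dt:.3f} ms "
            f"(neuron {blow_neuron})",
            t_blowup=blow_step * solver.dt, neuron=blow_neuron,
        )
    t = np.arange(Vrec.shape[1]) * solver.dt * solver.record_stride
    spikes = [np.asarray(sp_times[i, :sp_counts[i]]) for i in range(N)]
    return SimResult(
        t=t, V=Vrec, spikes=spikes,
        classes=[p.neuron_class for p in neurons],
        duration=solver.duration, dt=solver.dt,
        stimulus=asdict(stim),
        seeds={"noise": int(noise.seed), "sigma_pA": sigma,
               "network": getattr(net, "seed", None)},
    )


def _simulate_reference(neurons, synapses, pack, Y0, stim, solver,
                        spike_threshold, refractory) -> SimResult:
    """Adaptive noiseless reference: scipy LSODA over the numpy equations."""
    from scipy.integrate import solve_ivp
    from .synapses import transmitter

    N = len(neurons)
    off = pack["off"]
    syn0 = pack["syn0"]
    rel_thr, rel_slope = release_params()
    pulses = stim.pulses()

    dims = [STATE_DIM[p.neuron_class] for p in neurons]

    def f(t, Y):
        dY = np.zeros_like(Y)
        I_syn = np.zeros(N)
        for e, syn in enumerate(synapses):
            s = Y[syn0 + e]
            T = float(transmitter(Y[syn.pre], rel_thr, rel_slope))
            k = syn.kinetics
            dY[syn0 + e] = k.alpha * T * (1.0 - s) - k.beta * s
            I_syn[syn.post] += syn.g * s * (Y[syn.post] - k.E_rev)
        for i, p in enumerate(neurons):
            I_stim = sum(a for (tgt, a, t0, t1) in pulses if tgt == i and t0 <= t < t1)
            y = np.concatenate(([Y[i]], Y[off[i]:off[i] + dims[i] - 1]))
            dy = rhs_vector(p, y, I_syn=I_syn[i], I_stim=I_stim)
            dY[i] = dy[0]
            dY[off[i]:off[i] + dims[i] - 1] = dy[1:]
        return dY

    # pulse edges as solver breakpoints so the discontinuities are resolved
    edges = sorted({t for (_, _, t0, t1) in pulses for t in (t0, t1)
                    if 0 < t < solver.duration})
    t_eval = np.arange(0.0, solver.duration + 1e-9,
                       solver.dt * solver.record_stride)
    sol = solve_ivp(
        f, (0.0, solver.duration), Y0, method="LSODA",
        rtol=solver.rel_tol, atol=solver.abs_tol, t_eval=t_eval,
        max_step=1.0,
    )
    if not sol.success:
        raise SimulationError(f"reference integration failed: {sol.message}")
    V = sol.y[:N]
    from .analysis import detect_spikes

    spikes = [detect_spikes(sol.t, V[i], threshold=spike_threshold,
                            refractory=refractory) for i in range(N)]
    return SimResult(
        t=sol.t, V=V, spikes=spikes,
        classes=[p.neuron_class for p in neurons],
        duration=solver.duration, dt=solver.dt,
        stimulus=asdict(stim),
        seeds={"noise": None, "sigma_pA": 0.0, "network": None},
    )


def run_motif(config=None, network=None, noise_seed: int = 0) -> SimResult:
    """Build the default network, kick-start the first RA, simulate a motif.

    ``config`` is a :class:`hvcnet.config.RunConfig` (defaults if None);
    a prebuilt ``network`` overrides the build step.  Propagation failure
    is an analysis outcome, not an engine error.
    """
    from .config import RunConfig
    from .netbuild import wire_network

    cfg = config or RunConfig()
    net = network if network is not None else wire_network(cfg)
    first_ra = net.microcircuits[0].ra_ids[0]
    stim = StimulusProtocol(
        targets=[first_ra],
        waveform="dc_pulse",
        amplitude_nA=cfg.stimulus.kick_amplitude_nA,
        pulse_width=cfg.stimulus.kick_width_ms,
        onsets=[cfg.stimulus.kick_onset_ms],
    )
    solver = SolverConfig(
        method=cfg.solver.method, dt=cfg.solver.dt,
        record_stride=cfg.solver.record_stride, duration=cfg.solver.duration,
        rel_tol=cfg.solver.rel_tol, abs_tol=cfg.solver.abs_tol,
    )
    noise = NoiseConfig(sigma_percent=cfg.noise.sigma_percent, seed=noise_seed,
                        reference_driving_force=cfg.noise.reference_driving_force_mV)
    return simulate(net, stim, solver, noise,
                    spike_threshold=cfg.analysis.spike_threshold,
                    refractory=cfg.analysis.refractory)
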