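"""Spike detection, burst grouping and sequence-propagation metrics.

The "desired network activity" standard: every RA neuron emits exactly
one burst of 3–6 spikes lasting at most ~10 ms, with burst onsets ordered
along the chain; X neurons emit 1–4 rebound bursts of 4–9 spikes; INT
neurons fire densely throughout the active span of the motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Burst",
    "ValidationReport",
    "detect_spikes",
    "group_bursts",
    "inter_burst_delay",
    "psp_metrics",
    "sequence_metrics",
    "raster_figure",
]


@dataclass
class Burst:
    neuron_id: int
    onset: float  # ms, first spike
    offset: float  # ms, last spike
    n_spikes: int
    peak_times: list[float] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def detect_spikes(t, V, threshold: float = -20.0, refractory: float = 1.0):
    """Spike times from a uniformly sampled voltage trace.

    Upward crossings of ``threshold`` separated by at least ``refractory``
    ms; each spike is localized at the local maximum after the crossing.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    above = V > threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    last = -np.inf
    for idx in crossings:
        # local maximum between this crossing and the next downward crossing
        j = idx
        while j + 1 < len(V) and V[j + 1] >= V[j]:
            j += 1
        ts = t[j]
        if ts - last >= refractory:
            times.append(ts)
            last = ts
    return np.asarray(times)


def group_bursts(spike_times, isi_threshold: float = 15.0,
                 min_spikes: int = 2, neuron_id: int = -1):
    """Group sorted spikes into bursts: maximal runs with ISIs <= threshold.

    Returns (bursts, isolated_spikes): runs shorter than ``min_spikes``
    are reported as isolated spikes, not bursts.
    """
    st = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted")
    bursts: list[Burst] = []
    isolated: list[float] = []
    if st.size == 0:
        return bursts, isolated
    run = [st[0]]
    for s in st[1:]:
        if s - run[-1] <= isi_threshold:
            run.append(s)
        else:
            _close_run(run, bursts, isolated, min_spikes, neuron_id)
            run = [s]
    _close_run(run, bursts, isolated, min_spikes, neuron_id)
    return bursts, isolated


def _close_run(run, bursts, isolated, min_spikes, neuron_id):
    if len(run) >= min_spikes:
        bursts.append(Burst(neuron_id, run[0], run[-1], len(run), list(run)))
    else:
        isolated.extend(run)


def inter_burst_delay(pre_spikes, post_spikes):
    """First-peak-to-first-peak latency (ms) between two neurons.

    Returns None (flagged absent) when either neuron never spikes.
    """
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    if pre.size == 0 or post.size == 0:
        return None
    return float(post[0] - pre[0])


def psp_metrics(t, V, baseline_window, response_window):
    """Polarity and amplitude of a postsynaptic-potential deflection.

    Baseline is the mean over ``baseline_window``; the response extremum
    over ``response_window`` determines polarity ("depolarizing" /
    "hyperpolarizing" / "none") and amplitude (mV).
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    b0, b1 = baseline_window
    r0, r1 = response_window
    if not (t[0] <= b0 <= b1 <= t[-1] and t[0] <= r0 <= r1 <= t[-1]):
        raise ValueError("analysis windows must lie within the trace")
    base = V[(t >= b0) & (t <= b1)].mean()
    seg = V[(t >= r0) & (t <= r1)]
    up = seg.max() - base
    down = base - seg.min()
    if max(up, down) == 0.0:
        return {"polarity": "none", "amplitude": 0.0, "baseline": float(base)}
    if up >= down:
        return {"polarity": "depolarizing", "amplitude": float(up),
                "baseline": float(base)}
    return {"polarity": "hyperpolarizing", "amplitude": float(down),
            "baseline": float(base)}


# ---------------------------------------------------------------------------
# network-level validation
# ---------------------------------------------------------------------------

@dataclass
class ClassStats:
    n_neurons: int = 0
    n_bursts_mean: float = np.nan
    burst_duration_mean: float = np.nan
    burst_duration_sd: float = np.nan
    spikes_per_burst_mean: float = np.nan
    spikes_per_burst_sd: float = np.nan
    total_spikes: int = 0


@dataclass
class ValidationReport:
    """Per-class burst statistics and desired-activity pass/fail flags."""

    sequence_complete: bool
    break_point: int | None  # first chain-order RA without a burst
    stats: dict[str, ClassStats]
    ra_flags: dict[int, list[str]]
    x_flags: dict[int, list[str]]
    int_flags: dict[int, list[str]]
    ra_bursts: dict[int, Burst]
    x_bursts: dict[int, list[Burst]]
    onsets_ordered: bool

    @property
    def n_violations(self) -> int:
        return (sum(len(v) for v in self.ra_flags.values())
                + sum(len(v) for v in self.x_flags.values())
                + sum(len(v) for v in self.int_flags.values()))

    @property
    def desired(self) -> bool:
        return self.sequence_complete and self.n_violations == 0

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = {
            "sequence_complete": self.sequence_complete,
            "break_point": self.break_point,
            "onsets_ordered": self.onsets_ordered,
            "desired": self.desired,
            "stats": {k: asdict(v) for k, v in self.stats.items()},
            "flags": {
                "RA": {k: v for k, v in self.ra_flags.items() if v},
                "X": {k: v for k, v in self.x_flags.items() if v},
                "INT": {k: v for k, v in self.int_flags.items() if v},
            },
        }
        return d


def _burst_stats(all_bursts: list[Burst], n_neurons: int, counts) -> ClassStats:
    s = ClassStats(n_neurons=n_neurons)
    if all_bursts:
        durs = np.array([b.duration for b in all_bursts])
        spk = np.array([b.n_spikes for b in all_bursts])
        s.burst_duration_mean = float(durs.mean())
        s.burst_duration_sd = float(durs.std(ddof=1)) if len(durs) > 1 else 0.0
        s.spikes_per_burst_mean = float(spk.mean())
        s.spikes_per_burst_sd = float(spk.std(ddof=1)) if len(spk) > 1 else 0.0
    if counts:
        s.n_bursts_mean = float(np.mean(counts))
    return s


def sequence_metrics(result, net, cfg=None) -> ValidationReport:
    """Score one simulated motif against the desired-activity criteria.

    ``result`` is a SimResult and ``net`` the NetworkGraph it came from;
    ``cfg`` an AnalysisSection (defaults if None).
    """
    if cfg is None:
        from .config import RunConfig

        cfg = RunConfig().analysis

    chain = net.chain_order
    isi = cfg.isi_threshold
    mins = cfg.min_burst_spikes

    ra_bursts: dict[int, Burst] = {}
    ra_flags: dict[int, list[str]] = {}
    onsets = []
    break_point = None
    ra_burst_list = []
    lo, hi = cfg.ra_spikes_per_burst
    for nid in chain:
        flags = []
        bursts, _ = group_bursts(result.spikes[nid], isi, mins, nid)
        # an RA "burst" must reach the lower bound of the in vivo spike
        # count; a partially inhibited doublet does not qualify
        bursts = [b for b in bursts if b.n_spikes >= lo]
        if len(bursts) == 0:
            flags.append("no burst")
            if break_point is None:
                break_point = nid
        else:
            if len(bursts) > 1:
                flags.append(f"{len(bursts)} bursts (expected exactly 1)")
            b = bursts[0]
            ra_bursts[nid] = b
            ra_burst_list.append(b)
            onsets.append(b.onset)
            if b.n_spikes > hi:
                flags.append(f"{b.n_spikes} spikes outside [{lo}, {hi}]")
            if b.duration > cfg.ra_max_burst_duration:
                flags.append(f"duration {b.duration:.2f} ms > "
                             f"{cfg.ra_max_burst_duration} ms")
        ra_flags[nid] = flags

    onsets_arr = np.array(onsets)
    onsets_ordered = bool(np.all(np.diff(onsets_arr) >= 0)) if len(onsets) > 1 else True
    sequence_complete = (
        break_point is None
        and onsets_ordered
        and all("bursts (expected exactly 1)" not in f
                for fl in ra_flags.values() for f in fl)
    )

    # X neurons: 1-4 bursts of 4-9 spikes
    x_flags: dict[int, list[str]] = {}
    x_bursts: dict[int, list[Burst]] = {}
    x_counts = []
    x_all = []
    blo, bhi = cfg.x_bursts
    slo, shi = cfg.x_spikes_per_burst
    x_ids = [nid for mc in net.microcircuits for nid in mc.x_ids]
    for nid in x_ids:
        flags = []
        bursts, _ = group_bursts(result.spikes[nid], isi, mins, nid)
        x_bursts[nid] = bursts
        x_counts.append(len(bursts))
        x_all.extend(bursts)
        if not (blo <= len(bursts) <= bhi):
            flags.append(f"{len(bursts)} bursts outside [{blo}, {bhi}]")
        for b in bursts:
            if not (slo <= b.n_spikes <= shi):
                flags.append(f"burst at {b.onset:.1f} ms has {b.n_spikes} "
                             f"spikes outside [{slo}, {shi}]")
        x_flags[nid] = flags

    # INT neurons: dense tonic firing across their active span.
    # Operationalized: >= int_min_bursts bursts, and no silent gap longer
    # than int_window_ms between consecutive spikes within the neuron's
    # active span [first spike, last RA burst offset].
    int_flags: dict[int, list[str]] = {}
    int_ids = [nid for mc in net.microcircuits for nid in mc.int_ids]
    motif_end = max((b.offset for b in ra_burst_list), default=result.duration)
    int_counts = []
    int_all = []
    int_total = 0
    for nid in int_ids:
        flags = []
        st = np.asarray(result.spikes[nid])
        bursts, _ = group_bursts(st, isi, mins, nid)
        int_counts.append(len(bursts))
        int_all.extend(bursts)
        int_total += len(st)
        if len(bursts) < cfg.int_min_bursts:
            flags.append(f"only {len(bursts)} bursts "
                         f"(tonicity needs >= {cfg.int_min_bursts})")
        if st.size == 0:
            flags.append("silent")
        else:
            span = np.concatenate((st, [min(motif_end, result.duration)]))
            gaps = np.diff(span)
            if gaps.size and gaps.max() > cfg.int_window_ms:
                flags.append(f"silent gap of {gaps.max():.0f} ms in active span")
        int_flags[nid] = flags

    stats = {
        "RA": _burst_stats(ra_burst_list, len(chain),
                           [1 if n in ra_bursts else 0 for n in chain]),
        "X": _burst_stats(x_all, len(x_ids), x_counts),
        "INT": _burst_stats(int_all, len(int_ids), int_counts),
    }
    stats["RA"].total_spikes = int(sum(len(result.spikes[n]) for n in chain))
    stats["X"].total_spikes = int(sum(len(result.spikes[n]) for n in x_ids))
    stats["INT"].total_spikes = int_total

    return ValidationReport(
        sequence_complete=sequence_complete,
        break_point=break_point,
        stats=stats,
        ra_flags=ra_flags,
        x_flags=x_flags,
        int_flags=int_flags,
        ra_bursts=ra_bursts,
        x_bursts=x_bursts,
        onsets_ordered=onsets_ordered,
    )


def raster_figure(result, net, path=None):
    """Raster of RA (chain order), INT and X spike trains for one motif."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(10, 9), sharex=True,
                             height_ratios=[3, 1, 1])
    chain = net.chain_order
    for row, nid in enumerate(chain):
        axes[0].vlines(result.spikes[nid], row, row + 0.9, color="crimson", lw=0.6)
    axes[0].set_ylabel("RA (chain order)")
    int_ids = [n for mc in net.microcircuits for n in mc.int_ids]
    for row, nid in enumerate(int_ids):
        axes[1].vlines(result.spikes[nid], row, row + 0.9, color="black", lw=0.4)
    axes[1].set_ylabel("INT")
    x_ids = [n for mc in net.microcircuits for n in mc.x_ids]
    for row, nid in enumerate(x_ids):
        axes[2].vlines(result.spikes[nid], row, row + 0.9, color="navy", lw=0.6)
    axes[2].set_ylabel("X")
    axes[2].set_xlabel("time (ms)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig
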