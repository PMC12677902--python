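"""Spike detection, burst grouping, delays, PSP metrics, validator."""

import numpy as np
import pytest

from hvcnet.analysis import (
    Burst,
    detect_spikes,
    group_bursts,
    inter_burst_delay,
    psp_metrics,
    sequence_metrics,
)
from hvcnet.config import RunConfig
from hvcnet.engine import SimResult


# ---------------------------------------------------------------------------
# detect_spikes
# ---------------------------------------------------------------------------

def test_flat_trace_has_no_spikes():
    t = np.arange(0, 100, 0.1)
    assert detect_spikes(t, np.full_like(t, -65.0)).size == 0


def test_planted_spikes_recovered():
    t = np.arange(0, 100, 0.1)
    V = np.full_like(t, -65.0)
    planted = [12.0, 30.0, 55.5, 70.0, 91.0]
    for ts in planted:
        i = int(round(ts / 0.1))
        V[i - 2:i + 3] = [-30, 10, 40, 10, -30]
    got = detect_spikes(t, V, threshold=-20.0)
    assert len(got) == 5
    np.testing.assert_allclose(got, planted, atol=0.1 + 1e-9)


def test_refractory_merges_double_crossings():
    t = np.arange(0, 10, 0.05)
    V = np.full_like(t, -65.0)
    # two crossings 0.4 ms apart collapse into one spike at refractory 1 ms
    for ts in (5.0, 5.4):
        i = int(round(ts / 0.05))
        V[i] = 0.0
    assert detect_spikes(t, V, refractory=1.0).size == 1


def test_threshold_sweep_is_plateau_robust(ra_burst_trace):
    """Sweeping the detection threshold from -30 to -10 mV over a simulated
    RA burst leaves the spike count unchanged."""
    t, V, sp = ra_burst_trace
    counts = {thr: detect_spikes(t, V, threshold=thr).size
              for thr in np.arange(-30.0, -9.0, 5.0)}
    assert len(set(counts.values())) == 1
    assert next(iter(counts.values())) == len(sp)


# ---------------------------------------------------------------------------
# group_bursts
# ---------------------------------------------------------------------------

def test_constructed_isi_pattern():
    """ISIs [2,2,2, 50, 2,2] at threshold 15 -> bursts of 4 and 3 spikes."""
    st = np.cumsum([10.0, 2, 2, 2, 50, 2, 2])
    bursts, isolated = group_bursts(st, isi_threshold=15.0, min_spikes=2)
    assert [b.n_spikes for b in bursts] == [4, 3]
    assert isolated == []
    assert bursts[0].duration == pytest.approx(6.0)


def test_tonic_train_yields_no_bursts():
    st = np.arange(0, 200, 20.0)
    bursts, isolated = group_bursts(st, isi_threshold=15.0, min_spikes=2)
    assert bursts == []
    assert len(isolated) == len(st)


def test_unsorted_spikes_rejected():
    with pytest.raises(ValueError):
        group_bursts([3.0, 1.0])


def _brute_force_grouping(st, thr, min_spikes):
    """O(n^2) clustering: two spikes share a burst iff connected by a chain
    of ISIs <= thr."""
    st = list(st)
    groups = []
    for s in st:
        for g in groups:
            if any(abs(s - x) <= thr for x in g):
                g.append(s)
                break
        else:
            groups.append([s])
    # merge adjacent groups (chain transitivity)
    merged = []
    for g in groups:
        if merged and min(g) - max(merged[-1]) <= thr:
            merged[-1].extend(g)
        else:
            merged.append(sorted(g))
    return [g for g in merged if len(g) >= min_spikes]


def test_grouping_matches_brute_force_on_random_trains():
    rng = np.random.default_rng(42)
    for _ in range(300):
        n = rng.integers(0, 40)
        st = np.sort(rng.uniform(0, 300, size=n))
        thr = float(rng.uniform(2, 30))
        bursts, _ = group_bursts(st, isi_threshold=thr, min_spikes=2)
        expected = _brute_force_grouping(st, thr, 2)
        assert [b.n_spikes for b in bursts] == [len(g) for g in expected]
        for b, g in zip(bursts, expected):
            assert b.onset == pytest.approx(g[0])
            assert b.offset == pytest.approx(g[-1])


# ---------------------------------------------------------------------------
# inter_burst_delay and psp_metrics
# ---------------------------------------------------------------------------

def test_delay_identity_fixture_and_missing():
    assert inter_burst_delay([5.0, 7.0], [5.0, 7.0]) == 0.0
    assert inter_burst_delay([10.0], [14.0]) == pytest.approx(4.0)
    assert inter_burst_delay([], [14.0]) is None
    assert inter_burst_delay([10.0], []) is None


def test_psp_flat_and_planted_deflection():
    t = np.arange(0, 200, 0.1)
    V = np.full_like(t, -70.0)
    m = psp_metrics(t, V, (0, 50), (60, 150))
    assert m["amplitude"] == 0.0
    V2 = V.copy()
    V2[(t > 80) & (t < 100)] -= 3.0
    m2 = psp_metrics(t, V2, (0, 50), (60, 150))
    assert m2["polarity"] == "hyperpolarizing"
    assert m2["amplitude"] == pytest.approx(3.0)
    V3 = V.copy()
    V3[(t > 80) & (t < 100)] += 5.0
    assert psp_metrics(t, V3, (0, 50), (60, 150))["polarity"] == "depolarizing"
    with pytest.raises(ValueError):
        psp_metrics(t, V, (-10, 50), (60, 150))


# ---------------------------------------------------------------------------
# sequence_metrics on hand-built results
# ---------------------------------------------------------------------------

def _synthetic_result(net, cfg, ra_onsets, x_trains=None, int_trains=None):
    """SimResult with hand-written spike trains: each RA gets a 5-spike,
    8-ms burst at its prescribed onset."""
    n = net.n_neurons
    spikes = [np.array([]) for _ in range(n)]
    for nid, onset in ra_onsets.items():
        spikes[nid] = onset + np.array([0.0, 2.0, 4.0, 6.0, 8.0])
    for nid, train in (x_trains or {}).items():
        spikes[nid] = np.asarray(train, dtype=float)
    for nid, train in (int_trains or {}).items():
        spikes[nid] = np.asarray(train, dtype=float)
    t = np.arange(0, cfg.solver.duration, 1.0)
    return SimResult(t=t, V=np.zeros((n, len(t))), spikes=spikes,
                     classes=[net.neuron_class(i) for i in range(n)],
                     duration=cfg.solver.duration, dt=cfg.solver.dt)


@pytest.fixture(scope="module")
def tiny():
    cfg = RunConfig(network={"pools": {"RA": 12, "INT": 4, "X": 4},
                             "n_circuits": 4,
                             "ra_per_circuit": (3, 3),
                             "int_per_circuit": (1, 1),
                             "x_per_circuit": (1, 1)},
                    solver={"duration": 300.0})
    from hvcnet.netbuild import wire_network

    return cfg, wire_network(cfg)


def _healthy_trains(net, cfg):
    chain = net.chain_order
    ra_onsets = {nid: 20.0 + 12.0 * k for k, nid in enumerate(chain)}
    end = max(ra_onsets.values()) + 8.0
    x_ids = [n for mc in net.microcircuits for n in mc.x_ids]
    int_ids = [n for mc in net.microcircuits for n in mc.int_ids]
    x_trains = {nid: 40.0 + 30 * i + np.array([0, 2, 4, 6, 8.0])
                for i, nid in enumerate(x_ids)}
    # tonic interneurons: a short burst every 25 ms through the motif
    starts = np.arange(15.0, end, 25.0)
    int_train = np.sort(np.concatenate([starts, starts + 2.0, starts + 4.0]))
    int_trains = {nid: int_train for nid in int_ids}
    return ra_onsets, x_trains, int_trains


def test_healthy_synthetic_run_passes(tiny):
    cfg, net = tiny
    ra, xs, ints = _healthy_trains(net, cfg)
    rep = sequence_metrics(_synthetic_result(net, cfg, ra, xs, ints), net,
                           cfg.analysis)
    assert rep.sequence_complete
    assert rep.break_point is None
    assert rep.n_violations == 0
    s = rep.stats["RA"]
    assert s.spikes_per_burst_mean == pytest.approx(5.0)
    assert s.burst_duration_mean == pytest.approx(8.0)
    assert s.burst_duration_sd == pytest.approx(0.0)


@pytest.mark.parametrize("k", [0, 3, 7, 11])
def test_deleting_any_ra_burst_breaks_sequence(tiny, k):
    """Removing the burst of chain-position k flips sequence_complete and
    sets break_point to that neuron."""
    cfg, net = tiny
    ra, xs, ints = _healthy_trains(net, cfg)
    victim = net.chain_order[k]
    del ra[victim]
    rep = sequence_metrics(_synthetic_result(net, cfg, ra, xs, ints), net,
                           cfg.analysis)
    assert not rep.sequence_complete
    assert rep.break_point == victim


def test_out_of_order_onsets_detected(tiny):
    cfg, net = tiny
    ra, xs, ints = _healthy_trains(net, cfg)
    a, b = net.chain_order[2], net.chain_order[3]
    ra[a], ra[b] = ra[b], ra[a]
    rep = sequence_metrics(_synthetic_result(net, cfg, ra, xs, ints), net,
                           cfg.analysis)
    assert not rep.onsets_ordered
    assert not rep.sequence_complete


def test_out_of_range_bursts_flagged(tiny):
    cfg, net = tiny
    ra, xs, ints = _healthy_trains(net, cfg)
    # an X burst of 3 spikes violates the 4-9 spikes/burst band
    xid = next(n for mc in net.microcircuits for n in mc.x_ids)
    xs[xid] = np.array([50.0, 52.0, 54.0])
    rep = sequence_metrics(_synthetic_result(net, cfg, ra, xs, ints), net,
                           cfg.analysis)
    assert rep.x_flags[xid]
    # a silent INT is flagged for lost tonicity
    iid = next(n for mc in net.microcircuits for n in mc.int_ids)
    ints2 = dict(ints)
    ints2[iid] = []
    rep2 = sequence_metrics(_synthetic_result(net, cfg, ra, xs, ints2), net,
                            cfg.analysis)
    assert any("silent" in f or "bursts" in f for f in rep2.int_flags[iid])


def test_validator_is_pure(tiny):
    cfg, net = tiny
    ra, xs, ints = _healthy_trains(net, cfg)
    res = _synthetic_result(net, cfg, ra, xs, ints)
    a = sequence_metrics(res, net, cfg.analysis).to_dict()
    b = sequence_metrics(res, net, cfg.analysis).to_dict()
    assert a == b


def test_burst_dataclass_duration():
    b = Burst(neuron_id=1, onset=10.0, offset=18.0, n_spikes=5)
    assert b.duration == pytest.approx(8.0)
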