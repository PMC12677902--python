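"""Randomized chain-of-microcircuits network construction.

The network is a chain of microcircuits, each encoding one sub-syllabic
segment.  Construction rules ("rules of engagement"):

- the RA/INT/X pools (default 120/50/50, a 2:1:1 ratio) are partitioned
  over the microcircuits with per-circuit counts drawn from configured
  ranges (RA 3–10, INT 1–4, X 1–4) conditioned on the pool totals;
- within each circuit the RA neurons form a random simple chain of AMPA
  synapses; consecutive circuits are linked last-RA(i) -> first-RA(i+1);
- each INT receives 3–8 AMPA afferents from RA neurons anywhere in the
  pool, and sends 2–4 GABA synapses to RA neurons *outside* its own
  circuit (inhibition must never arrive in an RA's own time slot);
- each X excites 1–3 INT of its own circuit (AMPA); each INT inhibits
  1–2 X of its own circuit (GABA).

Per-edge maximal conductances are drawn uniformly from the per-pair
ranges in the configuration.  Everything is deterministic given
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .params import ConfigurationError, NeuronParams, default_neuron_params
from .synapses import Synapse, allowed_kind, default_kinetics, pair_kinetics

__all__ = [
    "Microcircuit",
    "NetworkGraph",
    "build_ra_chain",
    "partition_pool",
    "validate_graph",
    "wire_network",
]


@dataclass
class Microcircuit:
    """One functional unit of the chain (one sub-syllabic segment)."""

    index: int  # 1-based position in the chain
    ra_ids: list[int] = field(default_factory=list)  # in chain order
    int_ids: list[int] = field(default_factory=list)
    x_ids: list[int] = field(default_factory=list)

    @property
    def first_ra(self) -> int:
        return self.ra_ids[0]

    @property
    def last_ra(self) -> int:
        return self.ra_ids[-1]


@dataclass
class NetworkGraph:
    """Pools of neurons partitioned into ordered microcircuits + synapses."""

    microcircuits: list[Microcircuit]
    synapses: list[Synapse]
    pools: dict[str, int]  # class -> pool size
    seed: int
    neuron_params: list[NeuronParams] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return sum(self.pools.values())

    def neuron_class(self, nid: int) -> str:
        n_ra = self.pools["RA"]
        n_int = self.pools["INT"]
        if nid < n_ra:
            return "RA"
        if nid < n_ra + n_int:
            return "INT"
        if nid < self.n_neurons:
            return "X"
        raise ConfigurationError(f"neuron id {nid} out of range")

    def circuit_of(self, nid: int) -> int:
        """1-based microcircuit index housing a neuron."""
        for mc in self.microcircuits:
            if nid in mc.ra_ids or nid in mc.int_ids or nid in mc.x_ids:
                return mc.index
        raise ConfigurationError(f"neuron id {nid} not in any microcircuit")

    @property
    def chain_order(self) -> list[int]:
        """All RA ids in global chain (firing) order."""
        out = []
        for mc in self.microcircuits:
            out.extend(mc.ra_ids)
        return out

    def validate(self) -> list[str]:
        return validate_graph(self)

    # -- serialization ------------------------------------------------------

    def edge_table(self):
        import pandas as pd

        return pd.DataFrame(
            [(s.pre, s.post, s.kind, s.g) for s in self.synapses],
            columns=["pre_id", "post_id", "kind", "g_nS"],
        )

    def save(self, edge_csv, sidecar_json):
        """Edge-list CSV plus JSON sidecar (membership, chain order, seed)."""
        self.edge_table().to_csv(edge_csv, index=False, float_format="%.17g")
        side = {
            "seed": self.seed,
            "pools": self.pools,
            "config": self.config,
            "microcircuits": [
                {"index": m.index, "ra_ids": m.ra_ids, "int_ids": m.int_ids,
                 "x_ids": m.x_ids}
                for m in self.microcircuits
            ],
        }
        with open(sidecar_json, "w") as f:
            json.dump(side, f, indent=1, sort_keys=True)

    @classmethod
    def load(cls, edge_csv, sidecar_json):
        import pandas as pd

        with open(sidecar_json) as f:
            side = json.load(f)
        df = pd.read_csv(edge_csv)
        syns = [
            Synapse(int(r.pre_id), int(r.post_id), str(r.kind), float(r.g_nS))
            for r in df.itertuples()
        ]
        net = cls(
            microcircuits=[Microcircuit(**m) for m in side["microcircuits"]],
            synapses=syns,
            pools={k: int(v) for k, v in side["pools"].items()},
            seed=int(side["seed"]),
            config=side.get("config", {}),
        )
        net.neuron_params = _default_population(net.pools, side.get("config", {}))
        return net

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        for mc in self.microcircuits:
            for nid in mc.ra_ids + mc.int_ids + mc.x_ids:
                g.add_node(nid, neuron_class=self.neuron_class(nid), circuit=mc.index)
        for s in self.synapses:
            g.add_edge(s.pre, s.post, kind=s.kind, g=s.g)
        return g


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def partition_pool(pool_size: int, n_circuits: int, per_circuit_range,
                   rng: np.random.Generator, max_tries: int = 100_000):
    """Split ``pool_size`` into ``n_circuits`` counts within [lo, hi].

    Rejection sampling over iid uniform counts conditioned on the sum, so
    every feasible composition is equally likely.  Deterministic given the
    generator state.
    """
    lo, hi = int(per_circuit_range[0]), int(per_circuit_range[1])
    if lo > hi or lo < 0:
        raise ConfigurationError(f"bad per-circuit range [{lo}, {hi}]")
    if not (n_circuits * lo <= pool_size <= n_circuits * hi):
        raise ConfigurationError(
            f"cannot split pool of {pool_size} into {n_circuits} parts "
            f"within [{lo}, {hi}]"
        )
    if lo == hi:
        return [lo] * n_circuits
    for _ in range(max_tries):
        parts = rng.integers(lo, hi + 1, size=n_circuits)
        if parts.sum() == pool_size:
            return [int(p) for p in parts]
    raise ConfigurationError(
        f"partition sampling failed after {max_tries} tries "
        f"(pool {pool_size}, {n_circuits} parts in [{lo}, {hi}])"
    )


def build_ra_chain(circuit: Microcircuit, rng: np.random.Generator,
                   g_range=(8.0, 12.0)) -> list[Synapse]:
    """Order the circuit's RA members uniformly at random and connect
    consecutive pairs with AMPA synapses.  Mutates ``circuit.ra_ids`` to
    the chain order and returns the internal edges."""
    ids = list(circuit.ra_ids)
    order = [ids[i] for i in rng.permutation(len(ids))]
    circuit.ra_ids = order
    kin = default_kinetics()["AMPA"]
    return [
        Synapse(order[i], order[i + 1], "AMPA",
                float(rng.uniform(g_range[0], g_range[1])), kinetics=kin)
        for i in range(len(order) - 1)
    ]


def _default_population(pools: dict, config: dict) -> list[NeuronParams]:
    """One NeuronParams per neuron: RA block, then INT, then X."""
    overrides = (config or {}).get("cell_overrides", {})
    out = []
    for cls in ("RA", "INT", "X"):
        proto = default_neuron_params(cls, overrides.get(cls))
        out.extend(proto.copy() for _ in range(pools[cls]))
    return out


def wire_network(config=None, rng: np.random.Generator | None = None) -> "NetworkGraph":
    """Construct the full randomized network from a RunConfig (or defaults)."""
    from .config import RunConfig

    cfg = config or RunConfig()
    net_cfg = cfg.network
    seed = int(cfg.seeds.network)
    rng = rng or np.random.default_rng(seed)

    pools = dict(net_cfg.pools)
    M = net_cfg.n_circuits
    n_ra, n_int, n_x = pools["RA"], pools["INT"], pools["X"]

    ra_counts = partition_pool(n_ra, M, net_cfg.ra_per_circuit, rng)
    int_counts = partition_pool(n_int, M, net_cfg.int_per_circuit, rng)
    # X partition is conditioned on the INT partition: every X must be
    # coverable by within-circuit inhibition under the per-INT quota,
    # so circuit i needs x_i <= hi_quota * int_i.
    hi_quota = net_cfg.int_to_x_out[1]
    for _ in range(net_cfg.max_retries):
        x_counts = partition_pool(n_x, M, net_cfg.x_per_circuit, rng)
        if all(x_counts[i] <= hi_quota * int_counts[i] for i in range(M)):
            break
    else:
        raise ConfigurationError(
            "could not partition X pool compatibly with INT partition"
        )

    # ids: RA 0..n_ra-1, INT n_ra..n_ra+n_int-1, X beyond.
    ra_ids = list(rng.permutation(n_ra))
    int_ids = list(n_ra + rng.permutation(n_int))
    x_ids = list(n_ra + n_int + rng.permutation(n_x))

    circuits = []
    for i in range(M):
        mc = Microcircuit(index=i + 1)
        mc.ra_ids = [int(ra_ids.pop()) for _ in range(ra_counts[i])]
        mc.int_ids = [int(int_ids.pop()) for _ in range(int_counts[i])]
        mc.x_ids = [int(x_ids.pop()) for _ in range(x_counts[i])]
        circuits.append(mc)

    gr = cfg.synaptic_ranges  # dict pair -> (lo, hi)
    synapses: list[Synapse] = []
    edge_set = set()

    def add_edge(pre, post, pre_cls, post_cls, pair_key):
        kind = allowed_kind(pre_cls, post_cls)
        key = (pre, post, kind)
        if pre == post or key in edge_set:
            return False
        lo, hi = gr[pair_key]
        synapses.append(Synapse(pre, post, kind, float(rng.uniform(lo, hi)),
                                kinetics=pair_kinetics(pre_cls, post_cls)))
        edge_set.add(key)
        return True

    # RA chains within circuits
    for mc in circuits:
        chain = build_ra_chain(mc, rng, g_range=gr["RA_RA"])
        for s in chain:
            synapses.append(s)
            edge_set.add((s.pre, s.post, s.kind))
    # inter-circuit links: last RA of i -> first RA of i+1
    for i in range(M - 1):
        add_edge(circuits[i].last_ra, circuits[i + 1].first_ra, "RA", "RA", "RA_RA")

    all_ra = [nid for mc in circuits for nid in mc.ra_ids]
    retries = net_cfg.max_retries

    def sample_targets(candidates, count):
        return [int(c) for c in rng.choice(candidates, size=count, replace=False)]

    circuit_of_ra = {nid: mc.index for mc in circuits for nid in mc.ra_ids}
    for mc in circuits:
        out_ra = [nid for other in circuits if other.index != mc.index
                  for nid in other.ra_ids]
        for inid in mc.int_ids:
            # 3-8 AMPA afferents from the whole RA pool
            k = int(rng.integers(net_cfg.ra_to_int_in[0], net_cfg.ra_to_int_in[1] + 1))
            for _ in range(retries):
                donors = sample_targets(all_ra, k)
                if all((d, inid, "AMPA") not in edge_set for d in donors):
                    break
            else:
                raise ConfigurationError("could not sample RA->INT donors")
            for d in donors:
                add_edge(d, inid, "RA", "INT", "RA_INT")
            # 2-4 GABA outputs to RA outside the INT's own circuit.  The
            # "rules of engagement" demand that no inhibition arrive while
            # a target RA elicits its burst; since this INT bursts at its
            # donors' time slots, targets are additionally kept a guard
            # band of circuits away from every donor's circuit (relaxed
            # stepwise if the network is too small to honor it).
            k = int(rng.integers(net_cfg.int_to_ra_out[0], net_cfg.int_to_ra_out[1] + 1))
            if not out_ra:
                raise ConfigurationError(
                    f"circuit {mc.index}: no out-of-circuit RA targets"
                )
            k = min(k, len(out_ra))  # tiny networks: clamp to what exists
            donor_circuits = {circuit_of_ra[d] for d in donors}
            for guard in (2, 1, 0, -1):
                if guard < 0:
                    pool = out_ra
                else:
                    pool = [nid for nid in out_ra
                            if min(abs(circuit_of_ra[nid] - dc)
                                   for dc in donor_circuits) > guard]
                if len(pool) >= k:
                    break
            targets = sample_targets(pool, k)
            for tgt in targets:
                add_edge(inid, tgt, "INT", "RA", "INT_RA")
        # 1-2 GABA outputs per INT to X in its own circuit.  Quotas are
        # drawn per INT, then bumped (within the allowed range) until the
        # circuit's X neurons can all be covered; target selection prefers
        # X neurons that are still uninhibited, since an X without
        # inhibition can never fire its rebound bursts.
        lo_q, hi_q = net_cfg.int_to_x_out
        if not mc.x_ids:
            raise ConfigurationError(f"circuit {mc.index} has no X neurons")
        if not mc.int_ids:
            raise ConfigurationError(f"circuit {mc.index} has no INT neurons")
        quotas = {i_: int(rng.integers(lo_q, hi_q + 1)) for i_ in mc.int_ids}
        bumpable = [i_ for i_ in mc.int_ids if quotas[i_] < hi_q]
        while sum(quotas.values()) < len(mc.x_ids) and bumpable:
            pick = bumpable[int(rng.integers(len(bumpable)))]
            quotas[pick] += 1
            bumpable = [i_ for i_ in mc.int_ids if quotas[i_] < hi_q]
        uncovered = set(mc.x_ids)
        for inid in mc.int_ids:
            k = min(quotas[inid], len(mc.x_ids))
            pool = list(uncovered) if len(uncovered) >= k else list(mc.x_ids)
            targets = sample_targets(pool, k)
            for tgt in targets:
                add_edge(inid, tgt, "INT", "X", "INT_X")
                uncovered.discard(tgt)
        for xid in mc.x_ids:
            # 1-3 AMPA outputs to INT in own circuit
            k = int(rng.integers(net_cfg.x_to_int_out[0], net_cfg.x_to_int_out[1] + 1))
            k = min(k, len(mc.int_ids))
            if k == 0:
                raise ConfigurationError(f"circuit {mc.index} has no INT neurons")
            for tgt in sample_targets(mc.int_ids, k):
                add_edge(xid, tgt, "X", "INT", "X_INT")

    net = NetworkGraph(
        microcircuits=circuits,
        synapses=synapses,
        pools=pools,
        seed=seed,
        config=cfg.network_dict(),
    )
    net.neuron_params = _default_population(pools, net.config)
    violations = validate_graph(net)
    if violations:
        raise ConfigurationError(
            f"constructed network violates its own rules: {violations[:3]}"
        )
    return net


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_graph(net: NetworkGraph) -> list[str]:
    """Brute-force check of every architectural rule.

    Returns one message per violation (empty list = legal graph).
    """
    v: list[str] = []
    seen_ids: dict[int, int] = {}
    for mc in net.microcircuits:
        for nid in mc.ra_ids + mc.int_ids + mc.x_ids:
            if nid in seen_ids:
                v.append(f"neuron {nid} in circuits {seen_ids[nid]} and {mc.index}")
            seen_ids[nid] = mc.index
    for nid in range(net.n_neurons):
        if nid not in seen_ids:
            v.append(f"neuron {nid} not assigned to any microcircuit")

    circuit = seen_ids
    cls = net.neuron_class

    dup = set()
    for s in net.synapses:
        key = (s.pre, s.post, s.kind)
        if key in dup:
            v.append(f"duplicate edge {key}")
        dup.add(key)
        if s.pre == s.post:
            v.append(f"self-synapse on neuron {s.pre}")
        try:
            want = allowed_kind(cls(s.pre), cls(s.post))
            if want != s.kind:
                v.append(f"edge {s.pre}->{s.post} has kind {s.kind}, expected {want}")
        except ConfigurationError:
            v.append(f"forbidden pair {cls(s.pre)}->{cls(s.post)} "
                     f"({s.pre}->{s.post})")
            continue
        pc, qc = cls(s.pre), cls(s.post)
        if pc == "INT" and qc == "RA" and circuit.get(s.pre) == circuit.get(s.post):
            v.append(f"INT {s.pre} inhibits RA {s.post} in its own circuit "
                     f"{circuit.get(s.pre)}")
        if {(pc, qc)} & {("INT", "X"), ("X", "INT")}:
            if circuit.get(s.pre) != circuit.get(s.post):
                v.append(f"{pc} {s.pre} -> {qc} {s.post} crosses circuits "
                         f"{circuit.get(s.pre)} -> {circuit.get(s.post)}")

    # RA chain inside each circuit is a simple path in chain order
    edges = {(s.pre, s.post) for s in net.synapses if s.kind == "AMPA"}
    for mc in net.microcircuits:
        for a, b in zip(mc.ra_ids, mc.ra_ids[1:]):
            if (a, b) not in edges:
                v.append(f"circuit {mc.index}: missing chain edge {a}->{b}")
    for i in range(len(net.microcircuits) - 1):
        a = net.microcircuits[i].last_ra
        b = net.microcircuits[i + 1].first_ra
        if (a, b) not in edges:
            v.append(f"chain break between circuits {i + 1}, {i + 2}")
    return v
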