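"""Neutral networks, bridge sequences and bi-stability landscapes.

A *neutral network* of a structure c is a connected component, under
single-point mutation, of the set of sequences that have c among their
native structures with degeneracy at most g_cap (the *extended* member set).
The *core* of a network is its subset of uniquely folding (g = 1) sequences;
the *prototype* is the core sequence with the highest native fractional
population.  A multi-stable sequence is a *bridge* when single-point mutants
of it fold uniquely into at least two distinct members of its native
structure set, thereby connecting the corresponding networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqmap import SequenceSpaceMap, seq_to_str

__all__ = [
    "NeutralNetwork",
    "Bridge",
    "NetworkAtlas",
    "ExamplePair",
    "build_networks",
    "find_bridges",
    "bridge_summary_table",
    "pair_connectivity",
    "bistability_landscape",
    "landscape_distance_profile",
    "nearest_prototype_distances",
    "find_example_pair",
]


@dataclass
class NeutralNetwork:
    """One connected component of the extended member graph of a structure."""

    structure_id: int
    component_id: int
    core: frozenset[int]
    extended: frozenset[int]
    prototype: int | None  # None when the core is empty
    prototype_p: float | None = None

    @property
    def core_size(self) -> int:
        return len(self.core)

    @property
    def extended_size(self) -> int:
        return len(self.extended)


@dataclass
class Bridge:
    """A multi-stable sequence connecting at least two core networks."""

    seq: int
    g: int
    connections: frozenset[frozenset[int]]  # unordered network-id pairs

    @property
    def n_connections(self) -> int:
        return len(self.connections)

    def max_connections(self) -> int:
        return self.g * (self.g - 1) // 2


def _hamming(a: int, b: int) -> int:
    return int(a ^ b).bit_count()


def reverse_sequence(seq: int, L: int) -> int:
    """The chain-reversed sequence (monomer 1 becomes monomer L)."""
    out = 0
    for i in range(L):
        if (seq >> i) & 1:
            out |= 1 << (L - 1 - i)
    return out


class NetworkAtlas:
    """All neutral networks of a sequence-space map, with fast lookups."""

    def __init__(self, smap: SequenceSpaceMap, networks: list[NeutralNetwork]):
        self.smap = smap
        self.networks = networks
        # (structure_id, seq) -> network index; components of one structure
        # partition its member set, so the key is unique.
        self.member_net: dict[tuple[int, int], int] = {}
        # seq -> indices of all networks the sequence belongs to
        self.nets_of_seq: dict[int, list[int]] = {}
        for idx, net in enumerate(networks):
            for s in net.extended:
                self.member_net[(net.structure_id, s)] = idx
                self.nets_of_seq.setdefault(s, []).append(idx)
        # a g=1 sequence belongs to exactly one network
        self.core_net: dict[int, int] = {}
        for idx, net in enumerate(networks):
            for s in net.core:
                self.core_net[s] = idx

    def __len__(self) -> int:
        return len(self.networks)

    def __getitem__(self, idx: int) -> NeutralNetwork:
        return self.networks[idx]

    def with_min_core(self, min_core: int) -> list[int]:
        return [i for i, n in enumerate(self.networks)
                if n.core_size >= min_core]

    def reversal_key(self, net_id: int) -> tuple:
        """Canonical key identifying a network with its chain-reversal twin.

        Chain reversal maps every sequence onto its reverse and every
        structure onto its reversed walk, so the network inventory consists
        of mirror twins (plus a few self-symmetric networks).  Network-level
        statistics count each twin pair once.  The key is the smaller of the
        sorted member tuple and its reversed image.
        """
        L = self.smap.L
        net = self.networks[net_id]
        base = net.core if net.core else net.extended
        fwd = tuple(sorted(base))
        rev = tuple(sorted(reverse_sequence(s, L) for s in base))
        return min(fwd, rev)

    def to_frame(self) -> pd.DataFrame:
        L = self.smap.L
        rows = [
            {
                "network_id": i,
                "structure_id": n.structure_id,
                "component_id": n.component_id,
                "core_size": n.core_size,
                "extended_size": n.extended_size,
                "prototype": (seq_to_str(n.prototype, L)
                              if n.prototype is not None else ""),
                "prototype_p": (n.prototype_p
                                if n.prototype_p is not None else np.nan),
            }
            for i, n in enumerate(self.networks)
        ]
        return pd.DataFrame(rows)


def build_networks(smap: SequenceSpaceMap, g_cap: int | None = None
                   ) -> NetworkAtlas:
    """Connected components of every structure's extended member set.

    Membership: sequence s belongs to structure c's member set when c is
    among s's native structures and g(s) <= g_cap.  Components are found by
    breadth-first search over single-point-mutation (Hamming-1) edges.
    Prototypes (max native population, ties broken by the numerically
    smallest sequence) are assigned per component from its core.
    """
    if g_cap is None:
        g_cap = smap.params.g_cap
    L = smap.L
    viable = np.flatnonzero((smap.g >= 1) & (smap.g <= g_cap))
    members_of_structure: dict[int, list[int]] = {}
    for s in viable:
        for c in smap.native_ids(int(s)):
            members_of_structure.setdefault(c, []).append(int(s))

    # prototype selection needs native populations of all core sequences
    core_seqs = smap.core_sequences()
    core_p = dict(zip(core_seqs.tolist(),
                      smap.p_native_many(core_seqs).tolist()))

    networks: list[NeutralNetwork] = []
    for c in sorted(members_of_structure):
        members = set(members_of_structure[c])
        seen: set[int] = set()
        comp_id = 0
        for start in sorted(members):
            if start in seen:
                continue
            comp = {start}
            queue = [start]
            while queue:
                s = queue.pop()
                for k in range(L):
                    m = s ^ (1 << k)
                    if m in members and m not in comp:
                        comp.add(m)
                        queue.append(m)
            seen |= comp
            core = frozenset(s for s in comp if smap.g[s] == 1)
            prototype = None
            proto_p = None
            if core:
                # max population; ties -> smallest sequence
                prototype = min(core, key=lambda s: (-core_p[s], s))
                proto_p = core_p[prototype]
            networks.append(NeutralNetwork(
                structure_id=int(c), component_id=comp_id,
                core=core, extended=frozenset(comp),
                prototype=prototype, prototype_p=proto_p,
            ))
            comp_id += 1
    return NetworkAtlas(smap, networks)


def find_bridges(smap: SequenceSpaceMap, atlas: NetworkAtlas) -> list[Bridge]:
    """Identify every bridge sequence and the network pairs it connects.

    A sequence with 2 <= g <= g_cap connects the networks of two distinct
    native structures c1 != c2 when it has one single-point mutant folding
    uniquely (g = 1) into c1 and another folding uniquely into c2.  Such a
    mutant is Hamming-adjacent to the sequence and hence lies in the same
    component as the sequence itself, so the connected pair is
    (network of (c1, seq), network of (c2, seq)).
    """
    L = smap.L
    bridges: list[Bridge] = []
    for s in smap.multistable_sequences():
        s = int(s)
        native = smap.native_ids(s)
        witnessed: set[int] = set()
        for k in range(L):
            m = s ^ (1 << k)
            if smap.g[m] != 1:
                continue
            c = smap.native_ids(m)[0]
            if c in native:
                witnessed.add(c)
        if len(witnessed) < 2:
            continue
        connections = frozenset(
            frozenset((atlas.member_net[(c1, s)], atlas.member_net[(c2, s)]))
            for c1, c2 in itertools.combinations(sorted(witnessed), 2)
        )
        bridges.append(Bridge(seq=s, g=int(smap.g[s]),
                              connections=connections))
    return bridges


def bridge_summary_table(smap: SequenceSpaceMap, bridges: list[Bridge]
                         ) -> pd.DataFrame:
    """Per-degeneracy bridge statistics (counts, percentages, connections).

    Columns are indexed by degeneracy g = 2..g_cap plus a pooled "all"
    column; percentages are over the multi-stable census, the entire
    sequence space, and the bridges attaining the combinatorial maximum of
    g(g-1)/2 network connections.
    """
    g_cap = smap.params.g_cap
    hist = smap.degeneracy_histogram()
    n_space = smap.n_sequences
    gs = list(range(2, g_cap + 1))
    by_g = {gv: [b for b in bridges if b.g == gv] for gv in gs}
    cols: dict[str, list] = {}
    for gv in gs:
        bs = by_g[gv]
        multi = hist[gv]
        at_limit = sum(1 for b in bs
                       if b.n_connections == gv * (gv - 1) // 2)
        cols[str(gv)] = [
            multi,
            len(bs),
            100.0 * len(bs) / multi if multi else np.nan,
            100.0 * len(bs) / n_space,
            gv * (gv - 1) // 2,
            (np.mean([b.n_connections for b in bs]) if bs else np.nan),
            100.0 * at_limit / len(bs) if bs else np.nan,
        ]
    n_multi = sum(hist[gv] for gv in gs)
    at_limit_all = sum(
        1 for b in bridges if b.n_connections == b.max_connections()
    )
    cols["all"] = [
        n_multi,
        len(bridges),
        100.0 * len(bridges) / n_multi if n_multi else np.nan,
        100.0 * len(bridges) / n_space,
        np.nan,
        (np.mean([b.n_connections for b in bridges]) if bridges else np.nan),
        100.0 * at_limit_all / len(bridges) if bridges else np.nan,
    ]
    index = [
        "n_multistable",
        "n_bridges",
        "pct_bridges_of_multistable",
        "pct_bridges_of_sequence_space",
        "max_connections_per_bridge",
        "mean_connections_per_bridge",
        "pct_bridges_at_connection_limit",
    ]
    return pd.DataFrame(cols, index=index)


@dataclass
class PairConnectivity:
    """Connectivity statistics over size-filtered network pairs.

    With ``dedup`` (the default), chain-reversal twin networks are counted
    once; ``representative_pairs`` maps each counted bridged pair to one
    concrete (net_i, net_j) instance of it in the atlas.
    """

    min_core: int
    network_ids: list[int]
    n_networks: int
    n_pairs: int
    bridged_pairs: set[frozenset]
    representative_pairs: dict[frozenset, tuple[int, int]]
    core_adjacent_pairs: set[frozenset] = field(default_factory=set)
    extended_adjacent_pairs: set[frozenset] = field(default_factory=set)

    @property
    def n_bridged_pairs(self) -> int:
        return len(self.bridged_pairs)


def pair_connectivity(atlas: NetworkAtlas, bridges: list[Bridge],
                      min_core: int, adjacency: bool = True,
                      dedup: bool = True) -> PairConnectivity:
    """Pairwise connectivity of networks with at least ``min_core`` core seqs.

    Counts unordered pairs of size-filtered networks, the subset sharing at
    least one bridge, and (optionally) the subsets adjacent via a single
    mutation between cores or between extended member sets.  By default each
    network is identified with its chain-reversal twin before counting.
    """
    if min_core < 1:
        raise ValueError("min_core must be >= 1")
    ids = atlas.with_min_core(min_core)
    idset = set(ids)
    if dedup:
        key_of = {i: atlas.reversal_key(i) for i in ids}
    else:
        key_of = {i: i for i in ids}
    n = len(set(key_of.values()))
    bridged: set[frozenset] = set()
    representative: dict[frozenset, tuple[int, int]] = {}
    for b in bridges:
        for pair in b.connections:
            if not all(i in idset for i in pair):
                continue
            i, j = sorted(pair)
            key = frozenset((key_of[i], key_of[j]))
            bridged.add(key)
            if key not in representative or (i, j) < representative[key]:
                representative[key] = (i, j)
    result = PairConnectivity(
        min_core=min_core, network_ids=ids, n_networks=n,
        n_pairs=n * (n - 1) // 2, bridged_pairs=bridged,
        representative_pairs=representative,
    )
    if not adjacency:
        return result
    L = atlas.smap.L
    core_adj: set[frozenset] = set()
    ext_adj: set[frozenset] = set()
    for i in ids:
        net = atlas.networks[i]
        for s in net.extended:
            in_core = s in net.core
            for k in range(L):
                m = s ^ (1 << k)
                for j_ in atlas.nets_of_seq.get(m, ()):
                    if j_ == i or j_ not in idset:
                        continue
                    key = frozenset((key_of[i], key_of[j_]))
                    if len(key) == 1:
                        continue  # a network and its own twin
                    ext_adj.add(key)
                    if in_core and m in atlas.networks[j_].core:
                        core_adj.add(key)
    result.core_adjacent_pairs = core_adj
    result.extended_adjacent_pairs = ext_adj
    return result


def _shared_bridges(atlas: NetworkAtlas, bridges: list[Bridge],
                    net_a: int, net_b: int) -> list[Bridge]:
    key = frozenset((net_a, net_b))
    return [b for b in bridges if key in b.connections]


def bistability_landscape(smap: SequenceSpaceMap, atlas: NetworkAtlas,
                          bridges: list[Bridge], net_a: int, net_b: int,
                          compute_population: bool = True) -> pd.DataFrame:
    """Per-sequence bi-stability landscape of one bridged network pair.

    For every member of either extended network: the stability difference
    delta_n = n(seq, structure_B) - n(seq, structure_A) (negative favors A,
    zero marks exact bi-stability), the Hamming distance to the nearest
    shared bridge, a side label (A / B / overlap), the signed distance
    (negative on the A side, bridges at zero) and the native population.

    Raises ``ValueError`` when the pair shares no bridge (the bridge
    distance would be undefined).
    """
    shared = _shared_bridges(atlas, bridges, net_a, net_b)
    if not shared:
        raise ValueError(
            f"networks {net_a} and {net_b} share no bridge; "
            "bridge distance is undefined"
        )
    a, b = atlas.networks[net_a], atlas.networks[net_b]
    c_a, c_b = a.structure_id, b.structure_id
    members = sorted(a.extended | b.extended)
    seqs = np.array(members, dtype=np.int64)
    n_a = smap.contacts_on_structure(seqs, c_a)
    n_b = smap.contacts_on_structure(seqs, c_b)
    p_nat = (smap.p_native_many(seqs) if compute_population
             else np.full(len(seqs), np.nan))
    bridge_seqs = [br.seq for br in shared]
    rows = []
    for t, s in enumerate(members):
        dist = min(_hamming(s, bs) for bs in bridge_seqs)
        in_a, in_b = s in a.extended, s in b.extended
        side = "overlap" if (in_a and in_b) else ("A" if in_a else "B")
        dn = int(n_b[t] - n_a[t])
        if in_a and in_b:
            sign = -1 if dn < 0 else (1 if dn > 0 else 0)
        else:
            sign = -1 if in_a else 1
        rows.append({
            "seq": s, "hp": seq_to_str(s, smap.L), "side": side,
            "delta_n": dn, "bridge_distance": dist,
            "signed_distance": sign * dist, "p_native": p_nat[t],
            "is_bridge": s in set(bridge_seqs),
        })
    return pd.DataFrame(rows)


def landscape_distance_profile(smap: SequenceSpaceMap, atlas: NetworkAtlas,
                               bridges: list[Bridge], min_core: int = 5
                               ) -> pd.DataFrame:
    """Distance-binned |delta_n| aggregate over all bridged network pairs.

    For every unordered pair of networks with >= min_core core sequences
    sharing at least one bridge (623 pairs at L = 18), each pair counted
    once with the larger network labeled A: per Hamming distance from the
    nearest shared bridge, the pair's mean |delta_n|.  Rows: one per
    (pair, distance); aggregate medians over pairs give the distance trend.
    """
    conn = pair_connectivity(atlas, bridges, min_core, adjacency=False)
    reps = sorted(conn.representative_pairs.values())
    rows = []
    for pair_id, (i, j) in enumerate(reps):
        # larger core network is labeled A
        if atlas.networks[j].core_size > atlas.networks[i].core_size:
            i, j = j, i
        df = bistability_landscape(smap, atlas, bridges, i, j,
                                   compute_population=False)
        for dist, grp in df.groupby("bridge_distance"):
            rows.append({
                "pair_id": pair_id, "net_a": i, "net_b": j,
                "distance": int(dist),
                "mean_abs_delta_n": float(grp["delta_n"].abs().mean()),
                "n_sequences": len(grp),
            })
    return pd.DataFrame(rows)


def nearest_prototype_distances(smap: SequenceSpaceMap, atlas: NetworkAtlas,
                                bridges: list[Bridge]) -> pd.DataFrame:
    """Minimal Hamming distance of multi-stable sequences to a prototype.

    For each sequence with 2 <= g <= g_cap, the prototypes of the networks
    (components containing the sequence) of all its native structures are
    collected; the row reports the smallest Hamming distance to any of them.
    Sequences none of whose native structures' networks has a prototype are
    excluded.
    """
    bridge_set = {b.seq for b in bridges}
    rows = []
    for s in smap.multistable_sequences():
        s = int(s)
        protos = []
        for c in smap.native_ids(s):
            net = atlas.networks[atlas.member_net[(c, s)]]
            if net.prototype is not None:
                protos.append(net.prototype)
        if not protos:
            continue
        rows.append({
            "seq": s, "g": int(smap.g[s]), "is_bridge": s in bridge_set,
            "distance": min(_hamming(s, p) for p in protos),
        })
    return pd.DataFrame(rows)


@dataclass
class ExamplePair:
    """The canonical adjacent-network pair used for evolutionary runs."""

    net_a: int
    net_b: int
    core_a: int
    core_b: int
    extended_extra_a: int
    extended_extra_b: int
    prototype_distance: int
    contact_difference: int
    shared_bridges: list[int]


def contact_substitutions(smap: SequenceSpaceMap, struct_a: int,
                          struct_b: int) -> int:
    """Number of intra-chain contacts by which two structures differ.

    Counted as the larger of the two one-sided set differences of the
    contact sets: the number of contacts that must be exchanged to turn one
    structure's contact map into the other's (2 for the canonical example
    pair, whose 9-contact native structures share 7 contacts).
    """
    ma = int(smap.confs.masks[struct_a])
    mb = int(smap.confs.masks[struct_b])
    return max((ma & ~mb).bit_count(), (mb & ~ma).bit_count())


def find_example_pair(smap: SequenceSpaceMap, atlas: NetworkAtlas,
                      bridges: list[Bridge],
                      contact_difference: int = 2,
                      net_b: int | None = None) -> ExamplePair:
    """Locate the canonical adjacent-network pair for evolutionary runs.

    Network A is the largest core network.  B is chosen among A's bridged
    partners whose native structure differs from A's by exactly
    ``contact_difference`` contact substitutions; ties go to the partner
    sharing the most bridges with A, then to the larger core.  Pass
    ``net_b`` to select a specific partner instead.

    Raises ``LookupError`` when no partner qualifies.
    """
    net_a = max(range(len(atlas)),
                key=lambda i: (atlas.networks[i].core_size, -i))
    a = atlas.networks[net_a]
    if net_b is None:
        n_shared: dict[int, int] = {}
        for b in bridges:
            for pair in b.connections:
                if net_a in pair:
                    (other,) = pair - {net_a}
                    n_shared[other] = n_shared.get(other, 0) + 1
        candidates = [
            other for other in sorted(n_shared)
            if contact_substitutions(smap, a.structure_id,
                                     atlas.networks[other].structure_id)
            == contact_difference
        ]
        if not candidates:
            raise LookupError(
                "no bridged partner of the largest core network differs by "
                f"{contact_difference} contact substitutions"
            )
        net_b = max(candidates,
                    key=lambda i: (n_shared[i],
                                   atlas.networks[i].core_size, -i))
    b = atlas.networks[net_b]
    shared = _shared_bridges(atlas, bridges, net_a, net_b)
    if not shared:
        raise LookupError(f"networks {net_a} and {net_b} share no bridge")
    return ExamplePair(
        net_a=net_a, net_b=net_b,
        core_a=a.core_size, core_b=b.core_size,
        extended_extra_a=a.extended_size - a.core_size,
        extended_extra_b=b.extended_size - b.core_size,
        prototype_distance=_hamming(a.prototype, b.prototype),
        contact_difference=contact_substitutions(smap, a.structure_id,
                                                 b.structure_id),
        shared_bridges=[br.seq for br in shared],
    )
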