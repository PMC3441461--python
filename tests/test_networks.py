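"""Neutral networks, bridges and landscape statistics on small chains."""

import numpy as np
import pytest

from hpbridge import networks as nw
from hpbridge import synthdata as sd


@pytest.fixture(scope="module")
def built_l8(map_l8):
    atlas = nw.build_networks(map_l8)
    bridges = nw.find_bridges(map_l8, atlas)
    return map_l8, atlas, bridges


@pytest.fixture(scope="module")
def built_l10(map_l10):
    atlas = nw.build_networks(map_l10)
    bridges = nw.find_bridges(map_l10, atlas)
    return map_l10, atlas, bridges


def test_core_networks_partition_unique_folders(built_l8):
    smap, atlas, _ = built_l8
    seen = {}
    for idx, net in enumerate(atlas.networks):
        assert net.core <= net.extended
        for s in net.core:
            assert s not in seen
            seen[s] = idx
    assert set(seen) == set(int(s) for s in smap.core_sequences())


def test_extended_components_are_connected(built_l8):
    smap, atlas, _ = built_l8
    L = smap.L
    for net in atlas.networks:
        members = set(net.extended)
        start = next(iter(members))
        reached = {start}
        frontier = [start]
        while frontier:
            s = frontier.pop()
            for k in range(L):
                m = s ^ (1 << k)
                if m in members and m not in reached:
                    reached.add(m)
                    frontier.append(m)
        assert reached == members


def test_prototype_is_most_stable_core_member(built_l8):
    smap, atlas, _ = built_l8
    for net in atlas.networks:
        if not net.core:
            assert net.prototype is None
            continue
        ps = {s: smap.p_native(s) for s in net.core}
        assert net.prototype in net.core
        assert ps[net.prototype] == max(ps.values())


@pytest.mark.parametrize("L", [6, 8])
def test_networks_and_bridges_match_oracle(L):
    """Member sets and bridge connection counts equal brute force."""
    from hpbridge.seqmap import ModelParams, full_map

    oracle = sd.oracle_enumerate(L)
    o_nets, o_bridges = sd.oracle_networks_and_bridges(oracle)
    smap = full_map(ModelParams(L=L))
    atlas = nw.build_networks(smap)
    bridges = nw.find_bridges(smap, atlas)
    # conformation ids are comparable: both sides use the canonical order
    prod_nets = {(n.structure_id, n.core, n.extended)
                 for n in atlas.networks}
    orac_nets = {(d["structure"], d["core"], d["extended"])
                 for d in o_nets}
    assert prod_nets == orac_nets
    assert {(b.seq, b.g, b.n_connections) for b in bridges} == \
        {(d["seq"], d["g"], len(d["connections"])) for d in o_bridges}


def test_bridges_connect_distinct_native_structures(built_l10):
    smap, atlas, bridges = built_l10
    for b in bridges[:200]:
        native = smap.native_ids(b.seq)
        assert 2 <= b.g <= smap.params.g_cap
        assert 1 <= b.n_connections <= b.g * (b.g - 1) // 2
        for pair in b.connections:
            structs = {atlas.networks[i].structure_id for i in pair}
            assert len(structs) == 2
            assert structs <= set(native)


def test_unique_folders_are_never_bridges(built_l10):
    smap, _, bridges = built_l10
    assert all(smap.g[b.seq] != 1 for b in bridges)


def test_bridge_summary_table_shape(built_l10):
    smap, atlas, bridges = built_l10
    table = nw.bridge_summary_table(smap, bridges)
    assert list(table.columns) == ["2", "3", "4", "5", "6", "all"]
    assert table.loc["n_bridges", "all"] == len(bridges)
    # every connected g=2 bridge attains its single possible connection
    if (table.loc["n_bridges", "2"] or 0) > 0:
        assert table.loc["pct_bridges_at_connection_limit", "2"] == 100.0


def test_pair_connectivity_counts(built_l10):
    smap, atlas, bridges = built_l10
    conn = nw.pair_connectivity(atlas, bridges, min_core=2)
    assert conn.n_pairs == conn.n_networks * (conn.n_networks - 1) // 2
    assert conn.n_bridged_pairs <= conn.n_pairs
    # bridged pairs are a subset of extended-adjacent pairs: the bridge is
    # a member of both networks, so each is within one mutation of a core
    assert conn.bridged_pairs <= conn.extended_adjacent_pairs
    with pytest.raises(ValueError):
        nw.pair_connectivity(atlas, bridges, min_core=0)


def test_reversal_key_pairs_networks(built_l10):
    _, atlas, _ = built_l10
    sizes = {}
    for i in range(len(atlas)):
        sizes.setdefault(atlas.reversal_key(i), set()).add(
            atlas.networks[i].core_size)
    # twins have identical core sizes
    assert all(len(v) == 1 for v in sizes.values())


@pytest.fixture(scope="module")
def built_l12():
    from hpbridge.seqmap import ModelParams, full_map

    smap = full_map(ModelParams(L=12))
    atlas = nw.build_networks(smap)
    return smap, atlas, nw.find_bridges(smap, atlas)


def test_bistability_landscape_properties(built_l12):
    smap, atlas, bridges = built_l12
    conn = nw.pair_connectivity(atlas, bridges, min_core=2,
                                adjacency=False)
    assert conn.representative_pairs, "need at least one bridged pair"
    i, j = sorted(conn.representative_pairs.values())[0]
    df = nw.bistability_landscape(smap, atlas, bridges, i, j)
    bridges_df = df[df.is_bridge]
    assert (bridges_df.delta_n == 0).all()
    assert (bridges_df.bridge_distance == 0).all()
    # core-A neighbors of a bridge fold uniquely to A, hence favor it
    core_a = df[(df.side == "A") & (df.bridge_distance == 1)
                & (smap.g[df.seq] == 1)]
    assert len(core_a) > 0
    assert (core_a.delta_n <= -1).all()
    # unbridged pair raises
    unbridged = None
    all_pairs = {frozenset((a, b)) for a in range(len(atlas))
                 for b in range(a + 1, min(a + 30, len(atlas)))}
    for pair in sorted(all_pairs, key=lambda p: tuple(sorted(p))):
        if pair not in conn.bridged_pairs:
            unbridged = tuple(sorted(pair))
            break
    with pytest.raises(ValueError):
        nw.bistability_landscape(smap, atlas, bridges, *unbridged)


def test_nearest_prototype_distance_small_chain(built_l10):
    """Brute-force recomputation of the distance-to-prototype statistic."""
    smap, atlas, bridges = built_l10
    df = nw.nearest_prototype_distances(smap, atlas, bridges)
    assert set(df.columns) >= {"seq", "g", "is_bridge", "distance"}
    # spot-check rows against a direct recomputation
    for row in df.itertuples():
        protos = []
        for c in smap.native_ids(row.seq):
            net = atlas.networks[atlas.member_net[(c, row.seq)]]
            if net.prototype is not None:
                protos.append(net.prototype)
        assert row.distance == min(
            int(row.seq ^ p).bit_count() for p in protos)
        assert row.distance >= 1
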