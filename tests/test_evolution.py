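"""Mutation-selection dynamics: closed-form toys and a small real system."""

import numpy as np
import pytest
import scipy.sparse as sp

from hpbridge import evolution as ev
from hpbridge import networks as nw
from hpbridge import synthdata as sd
from hpbridge.seqmap import ModelParams, full_map


def _iterate(p, F, A, mu, L, n=5000):
    A = sp.csr_matrix(A)
    for _ in range(n):
        p, _ = ev.master_equation_step(p, F, A, mu, L)
    return p


# --- toy-network closed forms -------------------------------------------


def test_two_genotypes_equal_fitness_symmetric():
    toy = sd.make_toy_network("pair")
    p = _iterate(np.array([1.0, 0.0]), toy.fitness, toy.adjacency,
                 mu=0.01, L=2)
    assert p == pytest.approx([0.5, 0.5], abs=1e-12)


def test_two_genotypes_low_mutation_favors_fitter():
    toy = sd.make_toy_network("pair", fitness_ratio=2.0)
    for mu in (1e-2, 1e-3, 1e-4):
        p = _iterate(np.array([0.0, 1.0]), toy.fitness, toy.adjacency,
                     mu=mu, L=2, n=200_000)
        assert p[0] > p[1]
    # mu -> 0 limit: point mass on the fitter genotype
    assert p[0] > 1 - 10 * 1e-4


def test_zero_mutation_point_mass_on_max_fitness():
    toy = sd.make_toy_network("chain", n=3, fitness=[1.0, 1.5, 1.2])
    p = _iterate(np.full(3, 1 / 3), toy.fitness, toy.adjacency, mu=0.0,
                 L=3, n=2000)
    assert p == pytest.approx([0.0, 1.0, 0.0], abs=1e-10)


def test_uniform_fitness_steady_state_is_principal_eigenvector():
    toy = sd.make_toy_network("star", n_leaves=4)
    mu, L = 1e-2, 5
    p = _iterate(np.array([0, 1.0, 0, 0, 0]), toy.fitness, toy.adjacency,
                 mu=mu, L=L, n=50_000)
    M = (1 - L * mu) * np.eye(toy.n) + mu * toy.adjacency
    vals, vecs = np.linalg.eig(M)
    v = np.abs(vecs[:, np.argmax(vals.real)].real)
    v /= v.sum()
    assert p == pytest.approx(v, abs=1e-10)
    # the hub is the most populated genotype
    assert np.argmax(p) == 0


def test_normalization_and_extinction():
    toy = sd.make_toy_network("chain", n=4, fitness=[1, 2, 3, 4])
    p = np.full(4, 0.25)
    A = sp.csr_matrix(toy.adjacency)
    for _ in range(10_000):
        p, fbar = ev.master_equation_step(p, toy.fitness, A, 1e-3, 4)
        assert abs(p.sum() - 1.0) < 1e-12
        assert fbar > 0
    with pytest.raises(ev.ExtinctionError):
        ev.master_equation_step(np.array([1.0, 0.0]),
                                np.array([0.0, 1.0]),
                                sp.csr_matrix(np.eye(2)), 1e-3, 2)


# --- the smallest chain length with a bridged network pair ---------------


@pytest.fixture(scope="module")
def small_system():
    smap = full_map(ModelParams(L=12))
    atlas = nw.build_networks(smap)
    bridges = nw.find_bridges(smap, atlas)
    conn = nw.pair_connectivity(atlas, bridges, min_core=2,
                                adjacency=False)
    net_a, net_b = sorted(conn.representative_pairs.values())[0]
    if atlas.networks[net_b].core_size > atlas.networks[net_a].core_size:
        net_a, net_b = net_b, net_a
    return smap, atlas, bridges, net_a, net_b


def test_fitness_saturation_and_tau_zero(small_system):
    smap, atlas, bridges, net_a, net_b = small_system
    system = ev.PairSystem(smap, atlas, bridges, net_a, net_b)
    i_bridge = system.index[system.s_ab]
    # both terms saturate for the most stable bridge at tau <= P_max
    F = ev.fitness(system, ev.FitnessParams(system.p_max, system.p_max))
    assert F[i_bridge] == pytest.approx(2.0)
    assert F.max() == pytest.approx(F[i_bridge])
    # tau = 0: all viable genotypes share the same fitness
    F0 = ev.fitness(system, ev.FitnessParams(0.0, 0.0))
    assert np.allclose(F0, 2.0)
    # tau = 1: ranking by stability sum
    F1 = ev.fitness(system, ev.FitnessParams(1.0, 1.0))
    assert np.allclose(F1, system.p_a + system.p_b)


def test_steady_state_independent_of_initial_condition(small_system):
    smap, atlas, bridges, net_a, net_b = small_system
    system = ev.PairSystem(smap, atlas, bridges, net_a, net_b)
    params = ev.FitnessParams(system.p_max, system.p_max)
    res_a = ev.run_to_steady_state(system, params)
    p0 = np.full(len(system), 1.0 / len(system))
    res_b = ev.run_to_steady_state(system, params, p0=p0)
    assert res_a.p == pytest.approx(res_b.p, abs=1e-9)


def test_weak_selection_favors_most_stable_bridge(small_system):
    smap, atlas, bridges, net_a, net_b = small_system
    system = ev.PairSystem(smap, atlas, bridges, net_a, net_b)
    res = ev.run_to_steady_state(
        system, ev.FitnessParams(system.p_max, system.p_max))
    assert system.genotypes[np.argmax(res.p)] == system.s_ab


def test_bridge_removal_control(small_system):
    smap, atlas, bridges, net_a, net_b = small_system
    control = ev.remove_bridges_control(smap, atlas, bridges, net_a, net_b)
    full = ev.PairSystem(smap, atlas, bridges, net_a, net_b)
    assert set(control.genotypes) == \
        set(full.genotypes) - full.all_bridges_in_g
    params = ev.FitnessParams(full.p_max, full.p_max)
    res = ev.run_to_steady_state(control, params)
    # removed genotypes cannot be populated; distribution flattens
    full_res = ev.run_to_steady_state(full, params)
    assert res.p.max() < full_res.p.max()


def test_monte_carlo_reproducible_and_conserves_population(small_system):
    smap, atlas, bridges, net_a, net_b = small_system
    system = ev.PairSystem(smap, atlas, bridges, net_a, net_b)
    params = ev.FitnessParams(system.p_max, system.p_max)
    config = ev.MCConfig(pop_size=200, mu=1e-3, n_runs=3, seed=11,
                         max_generations=50, record_every=10)
    res1 = ev.monte_carlo_evolve(system, params, config)
    res2 = ev.monte_carlo_evolve(system, params, config)
    assert np.array_equal(res1.final_counts, res2.final_counts)
    assert np.array_equal(res1.mean_counts, res2.mean_counts)
    # population size is exactly pop_size every recorded generation
    assert np.allclose(res1.mean_counts.sum(axis=1), 200)
    assert (res1.final_counts.sum(axis=1) == 200).all()


def test_monte_carlo_neutral_drift_preserves_expectation(small_system):
    """mu = 0 and uniform fitness: resampling drift, constant expectation."""
    smap, atlas, bridges, net_a, net_b = small_system
    system = ev.PairSystem(smap, atlas, bridges, net_a, net_b)
    config = ev.MCConfig(pop_size=500, mu=0.0, n_runs=40, seed=5,
                         max_generations=30, record_every=30)
    res = ev.monte_carlo_evolve(system, ev.FitnessParams(0.0, 0.0), config)
    i0 = system.index[system.prototype_a]
    assert res.mean_counts[0, i0] == 500
    # all mass stays on the initial genotype without mutation
    assert res.mean_counts[-1, i0] == 500


def test_phase_diagram_regions(small_system):
    smap, atlas, bridges, net_a, net_b = small_system
    system = ev.PairSystem(smap, atlas, bridges, net_a, net_b)
    diagram = ev.selection_phase_diagram(system, n_grid=30)
    # the equal-pressure point tau_A = tau_B = P_max favors the bridge
    i = int(np.argmin(np.abs(diagram.tau_a_grid - 1.0)))
    assert diagram.labels[i, i] == 0
    df = diagram.to_frame()
    assert set(df.winner) <= {"bridge", "prototype_A", "prototype_B"}
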