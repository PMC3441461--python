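"""Evolutionary dynamics on a pair of adjacent neutral networks.

Models an adaptive conflict: one gene simultaneously selected for two
alternative native structures Xi_A and Xi_B.  The genotype set G is the
union of the two extended neutral networks; fitness is additive over the
two structures with threshold-saturated, tau-normalized contributions

    F(s) = f_A(s) + f_B(s),     f_X(s) = min(P_X(s), tau_X) / tau_X

where P_X(s) is the fractional (Boltzmann) population of structure X in
sequence s's conformational ensemble and tau_X sets the stability demand:
high tau rewards stability up to tau (strong selection), low tau tolerates
destabilization (weak selection), and tau_X = 0 means no stability
requirement at all (f_X = 1 for every viable sequence, the tau -> 0+ limit
of the expression above).  Sequences outside G are non-viable.

Two dynamics are provided: a deterministic mutation-selection master
equation for an effectively infinite population, iterated to steady state,
and a finite-population Wright-Fisher-style Monte Carlo with per-monomer
mutation and fitness-proportional (roulette-wheel) resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .networks import Bridge, ExamplePair, NetworkAtlas
from .seqmap import SequenceSpaceMap, seq_to_str

__all__ = [
    "FitnessParams",
    "MCConfig",
    "PairSystem",
    "PopulationState",
    "SteadyStateResult",
    "MCResult",
    "ExtinctionError",
    "fitness",
    "master_equation_step",
    "run_to_steady_state",
    "remove_bridges_control",
    "monte_carlo_evolve",
    "selection_phase_diagram",
]

DEFAULT_MU = 1e-3


class ExtinctionError(RuntimeError):
    """Raised when total population fitness reaches zero."""


@dataclass(frozen=True)
class FitnessParams:
    """Selection pressures (stability thresholds on the P_N scale)."""

    tau_a: float
    tau_b: float

    def __post_init__(self):
        for tau in (self.tau_a, self.tau_b):
            if not 0.0 <= tau <= 1.0:
                raise ValueError("tau must lie in [0, 1]")


@dataclass(frozen=True)
class MCConfig:
    """Finite-population Monte Carlo settings."""

    pop_size: int = 1000
    mu: float = DEFAULT_MU
    n_runs: int = 100
    seed: int = 0
    max_generations: int = 2000
    record_every: int = 1


@dataclass
class PopulationState:
    """Normalized genotype frequency vector at one generation."""

    t: int
    p: np.ndarray
    mean_fitness: float
    mu: float
    L: int


class PairSystem:
    """The genotype space G of one adjacent network pair.

    Holds, per genotype: the fractional populations toward the two selected
    structures, the Hamming-1 adjacency restricted to G, the shared bridges
    of the pair, the most stable bridge s_AB (ties broken by the smallest
    sequence) and signed Hamming distances to it (negative on the A side,
    positive on the B side; overlap members are signed by which structure
    they favor).
    """

    def __init__(self, smap: SequenceSpaceMap, atlas: NetworkAtlas,
                 bridges: list[Bridge], net_a: int, net_b: int,
                 removed: frozenset[int] = frozenset()):
        self.smap = smap
        self.net_a = net_a
        self.net_b = net_b
        self.removed = removed
        a, b = atlas.networks[net_a], atlas.networks[net_b]
        key = frozenset((net_a, net_b))
        shared = sorted(br.seq for br in bridges if key in br.connections)
        if not shared:
            raise ValueError("the network pair shares no bridge")
        self.all_bridges_in_g = frozenset(
            br.seq for br in bridges
            if br.seq in a.extended or br.seq in b.extended
        )
        members = sorted((a.extended | b.extended) - removed)
        self.genotypes = np.array(members, dtype=np.int64)
        self.index = {s: i for i, s in enumerate(members)}
        self.L = smap.L
        n_a = smap.contacts_on_structure(self.genotypes, a.structure_id)
        n_b = smap.contacts_on_structure(self.genotypes, b.structure_id)
        self.n_a, self.n_b = n_a, n_b
        dos = smap.dos_many(self.genotypes)
        ns = np.arange(dos.shape[1])
        beta = smap.params.beta_eps
        w = np.exp(-beta * (ns - ns.max()))
        z = dos @ w
        self.p_a = np.exp(-beta * (n_a - ns.max())) / z
        self.p_b = np.exp(-beta * (n_b - ns.max())) / z
        # shared bridges (may have been removed from G in control systems)
        self.bridge_seqs = shared
        p_of = {}
        for s in shared:
            na = int(smap.contacts_on_structure(
                np.array([s], dtype=np.int64), a.structure_id)[0])
            d = smap.dos(s)
            p_of[s] = float(np.exp(-beta * (na - ns.max()))
                            / float(d @ w))
        self.s_ab = min(shared, key=lambda s: (-p_of[s], s))
        self.p_max = p_of[self.s_ab]
        self.prototype_a = a.prototype
        self.prototype_b = b.prototype
        # adjacency restricted to G
        rows, cols = [], []
        for i, s in enumerate(members):
            for k in range(self.L):
                m = s ^ (1 << k)
                j = self.index.get(m)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
        self.adjacency = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(members), len(members)),
        )
        # signed distance to s_AB (kept even for genotypes of control runs)
        dist = np.array([int(s ^ self.s_ab).bit_count() for s in members])
        in_a = np.array([s in a.extended for s in members])
        in_b = np.array([s in b.extended for s in members])
        dn = n_b - n_a  # negative favors A
        # overlap members signed by the structure they favor; exact ties
        # (other bridges) go to the A side so only s_AB sits at zero
        ov_sign = np.where(dn > 0, 1, -1)
        sign = np.where(in_a & in_b, ov_sign, np.where(in_a, -1, 1))
        self.signed_distance = (sign * dist).astype(np.int64)

    def __len__(self) -> int:
        return len(self.genotypes)

    def genotype_index(self, seq: int) -> int:
        return self.index[seq]

    def point_mass(self, seq: int | None = None) -> np.ndarray:
        """Initial condition: all population on one genotype (prototype A)."""
        if seq is None:
            seq = self.prototype_a
        p = np.zeros(len(self))
        p[self.index[seq]] = 1.0
        return p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "seq": self.genotypes,
            "hp": [seq_to_str(int(s), self.L) for s in self.genotypes],
            "n_a": self.n_a, "n_b": self.n_b,
            "p_a": self.p_a, "p_b": self.p_b,
            "signed_distance": self.signed_distance,
        })


def fitness(system: PairSystem, params: FitnessParams) -> np.ndarray:
    """Fitness of every genotype in G under the two selection pressures."""
    def term(p: np.ndarray, tau: float) -> np.ndarray:
        if tau <= 0.0:
            return np.ones_like(p)
        return np.minimum(p, tau) / tau

    return term(system.p_a, params.tau_a) + term(system.p_b, params.tau_b)


def remove_bridges_control(smap: SequenceSpaceMap, atlas: NetworkAtlas,
                           bridges: list[Bridge], net_a: int, net_b: int
                           ) -> PairSystem:
    """The control genotype set with every bridge protein removed from G.

    Removal may disconnect the two networks; the master equation then keeps
    all population on the initially populated side.  Signed distances remain
    defined relative to the (removed) most stable bridge s_AB.
    """
    full = PairSystem(smap, atlas, bridges, net_a, net_b)
    control = PairSystem(smap, atlas, bridges, net_a, net_b,
                         removed=full.all_bridges_in_g)
    # distances and s_AB must refer to the removed bridge of the full system
    control.s_ab = full.s_ab
    control.p_max = full.p_max
    dist = np.array([int(s ^ full.s_ab).bit_count()
                     for s in control.genotypes])
    a, b = atlas.networks[net_a], atlas.networks[net_b]
    in_a = np.array([s in a.extended for s in control.genotypes])
    in_b = np.array([s in b.extended for s in control.genotypes])
    dn = control.n_b - control.n_a
    ov_sign = np.where(dn > 0, 1, -1)
    sign = np.where(in_a & in_b, ov_sign, np.where(in_a, -1, 1))
    control.signed_distance = (sign * dist).astype(np.int64)
    return control


def master_equation_step(p: np.ndarray, fitnesses: np.ndarray,
                         adjacency: sp.spmatrix, mu: float, L: int
                         ) -> tuple[np.ndarray, float]:
    """One mutation-selection update of the infinite-population dynamics.

    Mutation first: each genotype retains (1 - L*mu) of its frequency and
    receives mu times the frequency of each of its neighbors in G (flow to
    mutants outside G is lost).  Selection multiplies by f_i / f_bar; the
    normalization Lambda restores sum(p) = 1.

    Returns (next frequency vector, mean fitness f_bar of the input state).
    """
    f_bar = float(p @ fitnesses)
    if f_bar <= 0.0:
        raise ExtinctionError("mean fitness is zero")
    q = (1.0 - L * mu) * p + mu * (adjacency @ p)
    nxt = fitnesses * q / f_bar
    total = nxt.sum()
    if total <= 0.0:
        raise ExtinctionError("population vanished after update")
    return nxt / total, f_bar


@dataclass
class SteadyStateResult:
    """Converged master-equation state plus a sampled trajectory."""

    system: PairSystem
    params: FitnessParams
    mu: float
    p: np.ndarray
    generations: int
    converged: bool
    trajectory: pd.DataFrame  # generation x recorded genotype frequencies

    def to_frame(self) -> pd.DataFrame:
        """Steady state keyed by signed distance to s_AB (Fig-4-style)."""
        with np.errstate(divide="ignore"):
            neg_log = -np.log(self.p)
        return pd.DataFrame({
            "seq": self.system.genotypes,
            "hp": [seq_to_str(int(s), self.system.L)
                   for s in self.system.genotypes],
            "signed_distance": self.system.signed_distance,
            "p": self.p,
            "neg_log_p": neg_log,
        })


def run_to_steady_state(system: PairSystem, params: FitnessParams,
                        mu: float = DEFAULT_MU, tol: float = 1e-13,
                        window: int = 100, max_iter: int = 1_000_000,
                        p0: np.ndarray | None = None,
                        record_every: int = 50,
                        record_seqs: list[int] | None = None
                        ) -> SteadyStateResult:
    """Iterate the master equation until frequencies stop changing.

    Convergence requires max_i |Delta p_i| < tol over ``window`` consecutive
    generations.  The default initial condition is a point mass on the
    prototype of network A.  Raises ``RuntimeError`` on non-convergence.
    """
    p = system.point_mass() if p0 is None else np.asarray(p0, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("initial state must be normalized")
    F = fitness(system, params)
    if record_seqs is None:
        record_seqs = [system.prototype_a]
        if system.s_ab in system.index:
            record_seqs.append(system.s_ab)
        if system.prototype_b in system.index:
            record_seqs.append(system.prototype_b)
    rec_idx = [system.index[s] for s in record_seqs]
    traj_rows = []
    quiet = 0
    t = 0
    converged = False
    while t < max_iter:
        if t % record_every == 0:
            traj_rows.append([t] + [p[i] for i in rec_idx])
        nxt, _ = master_equation_step(p, F, system.adjacency, mu, system.L)
        delta = np.max(np.abs(nxt - p))
        p = nxt
        t += 1
        quiet = quiet + 1 if delta < tol else 0
        if quiet >= window:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"master equation did not converge within {max_iter} iterations "
            f"(last max |dp| over window unknown, tol={tol})"
        )
    traj = pd.DataFrame(
        traj_rows,
        columns=["generation"] + [seq_to_str(s, system.L)
                                  for s in record_seqs],
    )
    return SteadyStateResult(system=system, params=params, mu=mu, p=p,
                             generations=t, converged=converged,
                             trajectory=traj)


@dataclass
class MCResult:
    """Averaged finite-population trajectories and per-run endpoints."""

    config: MCConfig
    generations: np.ndarray
    mean_counts: np.ndarray        # (n_recorded, n_genotypes)
    final_counts: np.ndarray       # (n_runs, n_genotypes)

    def mean_frequency(self, idx: int) -> np.ndarray:
        return self.mean_counts[:, idx] / self.config.pop_size

    def final_frequency_stats(self, idx: int) -> tuple[float, float]:
        """(mean, standard error) of a genotype's final-generation frequency."""
        freqs = self.final_counts[:, idx] / self.config.pop_size
        se = float(freqs.std(ddof=1) / np.sqrt(len(freqs)))
        return float(freqs.mean()), se


def monte_carlo_evolve(system: PairSystem, params: FitnessParams,
                       config: MCConfig) -> MCResult:
    """Finite-population stochastic dynamics, averaged over replicate runs.

    Each generation: every monomer of every individual mutates with
    probability mu (H <-> P); mutants leaving G are non-viable (fitness 0)
    and can only disappear at selection.  Selection draws pop_size
    individuals by fitness-proportional roulette, which on genotype counts
    is a multinomial draw with weights count_g * F_g.  Populations are
    tracked as genotype count vectors; mutation events are applied
    sequentially, so a multiply-hit individual within one generation is
    approximated by independent single-site moves (events are rare at the
    default mu).  Runs are independently seeded from ``config.seed`` and
    bit-reproducible.
    """
    F = fitness(system, params)
    n_geno = len(system)
    L = system.L
    N = config.pop_size
    init_idx = system.index[system.prototype_a]
    # mutant lookup: target genotype index or -1 (outside G)
    targets = np.full((n_geno, L), -1, dtype=np.int64)
    for i, s in enumerate(system.genotypes):
        for k in range(L):
            targets[i, k] = system.index.get(int(s) ^ (1 << k), -1)
    n_rec = (config.max_generations // config.record_every) + 1
    sum_counts = np.zeros((n_rec, n_geno), dtype=np.float64)
    final = np.zeros((config.n_runs, n_geno), dtype=np.int64)
    gens = np.arange(n_rec) * config.record_every
    children = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    for run in range(config.n_runs):
        rng = np.random.default_rng(children[run])
        counts = np.zeros(n_geno, dtype=np.int64)
        counts[init_idx] = N
        dead = 0
        rec = 0
        for t in range(config.max_generations + 1):
            if t % config.record_every == 0:
                sum_counts[rec] += counts
                rec += 1
            if t == config.max_generations:
                break
            # mutation: number of (individual, site) events is binomial
            n_events = rng.binomial(N * L, config.mu)
            for _ in range(n_events):
                slot = rng.integers(N)
                cum = np.cumsum(counts)
                if slot >= cum[-1]:
                    continue  # event hit a non-viable individual
                g = int(np.searchsorted(cum, slot, side="right"))
                k = int(rng.integers(L))
                counts[g] -= 1
                tgt = targets[g, k]
                if tgt >= 0:
                    counts[tgt] += 1
                else:
                    dead += 1
            # selection: fitness-proportional multinomial resampling
            w = counts * F
            total = w.sum()
            if total <= 0.0:
                raise ExtinctionError(f"run {run}: total fitness is zero")
            counts = rng.multinomial(N, w / total)
            dead = 0
        final[run] = counts
    return MCResult(config=config, generations=gens,
                    mean_counts=sum_counts / config.n_runs,
                    final_counts=final)


@dataclass
class PhaseDiagram:
    """Winning-genotype classification over a (tau_A, tau_B) grid."""

    tau_a_grid: np.ndarray  # in units of P_max
    tau_b_grid: np.ndarray
    labels: np.ndarray      # 0 = bridge, 1 = prototype A, 2 = prototype B
    p_max: float

    def to_frame(self) -> pd.DataFrame:
        names = np.array(["bridge", "prototype_A", "prototype_B"])
        aa, bb = np.meshgrid(self.tau_a_grid, self.tau_b_grid,
                             indexing="ij")
        return pd.DataFrame({
            "tau_a_over_pmax": aa.ravel(),
            "tau_b_over_pmax": bb.ravel(),
            "winner": names[self.labels.ravel()],
        })


def selection_phase_diagram(system: PairSystem,
                            tau_a_grid: np.ndarray | None = None,
                            tau_b_grid: np.ndarray | None = None,
                            n_grid: int = 50,
                            tau_max_over_pmax: float = 3.0) -> PhaseDiagram:
    """Which genotype wins under every combination of selection pressures.

    Grid values are in units of P_max (the stability of the most stable
    bridge's equally populated native structures).  A grid point is labeled
    "bridge" when the most stable bridge out-competes both prototypes,
    otherwise by the fitter prototype.
    """
    if tau_a_grid is None:
        tau_a_grid = np.linspace(tau_max_over_pmax / n_grid,
                                 tau_max_over_pmax, n_grid)
    if tau_b_grid is None:
        tau_b_grid = tau_a_grid.copy()
    seqs = [system.s_ab, system.prototype_a, system.prototype_b]
    idx = [system.index[s] for s in seqs]
    pa = system.p_a[idx]
    pb = system.p_b[idx]
    labels = np.zeros((tau_a_grid.size, tau_b_grid.size), dtype=np.int8)
    for i, ua in enumerate(tau_a_grid):
        tau_a = ua * system.p_max
        fa = np.minimum(pa, tau_a) / tau_a if tau_a > 0 else np.ones(3)
        for j, ub in enumerate(tau_b_grid):
            tau_b = ub * system.p_max
            fb = (np.minimum(pb, tau_b) / tau_b if tau_b > 0
                  else np.ones(3))
            F = fa + fb
            if F[0] > F[1] and F[0] > F[2]:
                labels[i, j] = 0
            else:
                labels[i, j] = 1 if F[1] >= F[2] else 2
    return PhaseDiagram(tau_a_grid=tau_a_grid, tau_b_grid=tau_b_grid,
                        labels=labels, p_max=system.p_max)


def example_system(smap: SequenceSpaceMap, atlas: NetworkAtlas,
                   bridges: list[Bridge], pair: ExamplePair) -> PairSystem:
    """Convenience constructor for the canonical example pair."""
    return PairSystem(smap, atlas, bridges, pair.net_a, pair.net_b)
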