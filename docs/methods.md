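# Methods

## The model

Proteins are chains of `L` monomers over the two-letter alphabet {H, P}
(hydrophobic / polar), configured as self-avoiding walks on the 2D square
lattice.  The only energy term is a favorable contact energy `eps < 0`
between two H monomers occupying adjacent lattice sites without being
chain neighbors.  With `n(s, c)` the number of such HH contacts of
sequence `s` in conformation `c`, the conformational ensemble is exactly
summable and the fractional population of a structure is

    P(s, c) = exp(-beta_eps * n(s, c)) / sum_n h_s(n) exp(-beta_eps * n)

where `beta_eps = eps / (k_B T)` and `h_s` is the density of states
(conformations per contact count).  The *native state* of `s` is the set
of conformations attaining the maximal contact count; its size is the
degeneracy `g`.  `g = 1` sequences fold uniquely; `2 <= g <= g_cap`
(default cap 6) sequences are multi-stable and are the raw material for
*bridge* behavior: a multi-stable sequence whose single-point mutants fold
uniquely into at least two of its native structures connects the
corresponding neutral networks.

Default `beta_eps = -2.0`.  Every integer census statistic (degeneracy
counts, bridge counts, network sizes) is independent of `beta_eps`; it
only scales the population values `P` and hence prototype stabilities and
fitness magnitudes.  The value -2 places uniquely folding 18-mers at
native populations of order 0.1-0.2, a regime in which folding is strongly
but not absurdly favored, and is exposed in `ModelParams`.

## Enumeration

Conformations related by one of the eight lattice symmetries (four
rotations x reflection) are the same structure and are enumerated once;
chain reversal is *not* quotiented because monomer 1 is distinguishable
from monomer `L`.  The canonical representative fixes the first step to R
and keeps the direction string that is lexicographically no larger
(U < D < L < R) than its up/down reflection; the depth-first search prunes
non-canonical prefixes, so exactly one walk per orbit is emitted.  At
`L = 18` this yields 5,808,335 conformations, in agreement with published
exhaustive counts for this model.  The maximal contact count at `L = 18`
is 10 (realized by 3x6 compact rectangles: 27 lattice adjacencies minus 17
chain bonds), verified independently from coordinates.

Conformations are grouped into *contact classes* (identical contact sets;
170,670 classes at `L = 18`).  Admissible contact pairs `(i, j)` require
`j - i` odd and `>= 3`; there are 64 at `L = 18`, so a contact set is one
64-bit mask.  A sequence's census is computed by intersecting its H-pair
mask with every class mask (`popcount`), scanning classes in order of
decreasing contact count and stopping once no remaining class can reach
the running maximum.  The full 2^18-sequence census runs in roughly half a
minute on one CPU.  Densities of states are recomputed lazily per sequence
rather than stored for all 262,144 sequences.

## Neutral networks and bridges

A *neutral network* of structure `c` is a connected component, under
single-point mutation, of the set of sequences having `c` among their
native structures with `g <= g_cap` (the *extended* member set).  The
*core* is the subset folding uniquely; the *prototype* is the core
sequence of maximal native population (ties broken toward the smaller
sequence integer).  A bridge's connected network pair for structures
`(c1, c2)` is well defined because any uniquely folding 1-mutant of the
bridge is Hamming-adjacent to it and therefore lies in the same component
the bridge occupies.

Chain reversal maps every network onto a twin (reverse every member
sequence, reverse the structure's walk), so the inventory consists of
mirror pairs plus a few self-symmetric networks.  Network-level pair
statistics (`pair_connectivity`) therefore count reversal twins once by
default; sequence-level statistics (degeneracy and bridge censuses) never
deduplicate, since a sequence and its reverse are distinct genotypes.

The counts of size-filtered networks are sensitive to a definitional
choice that integer censuses are immune to: whether components are taken
over the extended member graph (used here) or over the core graph with
multi-stable members attached afterwards.  With the extended-graph
definition this package finds, at `L = 18`, 209 twin-deduplicated networks
with at least 5 core sequences (648 of their pairs sharing a bridge) and
22 networks with at least 20 core sequences (231 pairs).  The core-graph
alternative gives 187 and 21 networks respectively; both definitions are
implemented in the test oracles and the extended-graph one is canonical
throughout the package.

## Bi-stability landscape conventions

The stability difference of a sequence between two structures is
`delta_n = n(s, B) - n(s, A)`: negative values favor the first structure
(more contacts = lower energy), zero marks exact bi-stability.  Landscape
plots key sequences by Hamming distance to the nearest shared bridge of a
network pair, signed negative on the A side (A = larger core).  Members of
both extended networks are signed by the structure they favor;
exactly-bi-stable overlap members other than the reference bridge go to
the A side so that only the reference bridge sits at distance zero.

The pooled landscape profile (`landscape_distance_profile`) averages
|delta_n| per distance within each bridged pair (each twin-deduplicated
pair counted once), then takes medians across pairs per distance.  At
`L = 18` the median grows monotonically from 0 at distance 0 through
every populated distance bin — bi-stability decays smoothly with every
mutation away from a bridge.

## Fitness under adaptive conflict

Selection acts simultaneously for two structures with thresholds
`tau_A, tau_B` on the population scale:

    F(s) = min(P_A(s), tau_A)/tau_A + min(P_B(s), tau_B)/tau_B

Each term saturates at 1 once the structure is populated to `tau`; low
`tau` tolerates destabilization (weak selection), high `tau` demands
stability (strong selection).  At `tau_X = 0` the term is defined as 1 for
every viable sequence — the `tau -> 0+` limit of the expression, since
`P > 0` — making fitness uniform over the genotype set (pure-topology
dynamics).  Sequences outside the genotype set `G` (the union of the
pair's extended networks) are non-viable.  Reference pressures used in
tests: `tau_weak = P_max` (the native population of the most stable shared
bridge) and `tau_strong = max(P(prototype A), P(prototype B))`.

## Master-equation dynamics

Frequencies over `G` update as mutation followed by selection and
renormalization:

    q_i = (1 - L*mu) p_i + mu * sum_{j ~ i, j in G} p_j
    p'_i = Lambda * F_i * q_i / F_bar,   F_bar = sum_i p_i F_i

with per-monomer mutation rate `mu = 1e-3` per generation (default;
exposed) and `Lambda` restoring normalization (mutational flow to
sequences outside `G` is lost before renormalizing).  Steady state is
declared when `max_i |dp_i| < 1e-13` for 100 consecutive generations
(at most 10^6 iterations); normalization is conserved to < 1e-12 over
10^5 iterations.  The default initial condition is a point mass on
prototype A.  The steady state is independent of the initial state
whenever `G` is connected.

Bridge-removal controls delete every bridge sequence from `G` and
recompute adjacency; distances remain defined relative to the removed
reference bridge.  When removal disconnects the pair, only the initially
populated component carries population at steady state.

## Finite-population Monte Carlo

Populations of 1000 individuals evolve by per-monomer mutation
(probability `mu` per site per generation, H <-> P) followed by
fitness-proportional roulette selection of 1000 individuals.  The
implementation tracks genotype *counts*: the roulette draw is exactly a
multinomial with weights `count_g * F_g`, and the per-site Bernoulli
mutation field is sampled as a binomial event count assigned to uniformly
random (individual, site) slots — distributionally identical to
independent per-site coin flips.  Mutation events are applied
sequentially, so an individual hit twice within one generation is
approximated by two independent single-site moves; at `mu = 1e-3` such
events occur at rate ~1.5e-4 per individual per generation.  Mutants
leaving `G` receive fitness 0 and disappear at the next selection.  Each
replicate run draws its generator from a spawned `SeedSequence`, making
runs bit-reproducible and independent.  Averaged over 100 runs, the bridge
trajectory matches the master-equation steady state within Monte Carlo
standard error.

## Two-pressure phase diagram

For a grid of `(tau_A, tau_B)` in units of `P_max`, each point is labeled
by the fittest of {most stable bridge, prototype A, prototype B}.  The
bridge-favoring region is contiguous, centered on the diagonal, and
contains `tau_A = tau_B = P_max` (where the bridge attains the global
maximum F = 2); sufficiently unequal pressures hand the win to the
prototype of the strongly selected structure.  The classification is a
direct fitness comparison, not a dynamics run: with mutation weak and
fitness differences of order one, the master-equation steady state
concentrates on the fittest genotype, which the regime tests confirm.

## Atomic contact density

For an all-atom structure, `f_C` is the fraction of inter-residue atomic
contacts that are carbon-carbon, with a contact defined as an atom pair
from residues at least 3 positions apart (author numbering) at distance
strictly below the cutoff.  The default cutoff is 5.0 A — mid-range among
common heavy-atom contact criteria — and is configurable; hydrogens are
excluded by default (crystal structures rarely resolve them), waters
always.  Carbon counting is element-based, not a residue hydrophobicity
scale: buried carbons of polar residues contribute.  `Delta f_C` between
two structures of one sequence is antisymmetric and invariant under rigid
motions (verified to 1e-10).

Candidate screening consumes tabular records of structure pairs
(accession, backbone RMSD, sequence identity, externally computed
per-length stability scores) and keeps pairs with RMSD >= 2.0 A, identity
>= 95%, and stability-score difference within the lowest 10th percentile
of the survivors, sorted by ascending difference.  All thresholds are
parameters; the defaults bracket the observed minima of typical curated
fold-switch candidate sets.  No energy function is implemented — stability
scores are inputs.

## Synthetic data and oracles

The brute-force oracle enumerates all `4^(L-1)` direction strings
(feasible to `L = 12`), reduces symmetry orbits by explicitly applying all
eight lattice transforms, counts contacts from coordinates, and evaluates
sequences one conformation at a time; it shares no code path with the
production DFS/bitmask pipeline.  Production and oracle agree exactly on
conformation counts, member sets, densities of states, degeneracy
histograms, networks and bridge sets for `L = 3..10` (gold enumeration
files for `L = 6, 8, 10` are frozen as fixtures).  Note that short even
chains fold poorly — `L = 10` has only 6 uniquely folding sequences and no
bridges, so network-pair and evolution tests use `L = 12` (87 unique
folders, 49 bridges) as the smallest nontrivial stage.

Synthetic PDB fixtures place non-interacting backbone atoms 20 A apart
and realize each requested contact with a dedicated atom pair 2 A apart at
an isolated site, so carbon/total contact counts at the stated cutoff are
exact by construction; coordinate jitter (seeded, bounded so no count can
flip) exercises robustness.  These fixtures emulate nothing about real
protein geometry — no covalent structure, no side chains, no packing — and
tests passing on them certify only the counting and I/O logic, not
biological realism of `f_C` values.

## Problem sizes and runtimes

The package's own test suite runs the complete `L = 18` space (5.8M
conformations, 262,144 sequences) once, plus the `L <= 12` oracle stages;
the Monte Carlo check uses 100 runs x 1000 individuals x 1500 generations.
The whole suite completes in a few minutes on one CPU; the from-scratch
acceptance pipeline takes about half a minute after JIT compilation.

## Known limitations

- 2D lattice, two-letter alphabet, single contact energy: census numbers
  are exact for the model, not predictions for real proteins.
- The network-pair counts depend on the component definition as described
  above; sequence-level censuses do not.
- The Monte Carlo treats within-generation double mutations of one
  individual as sequential independent events (rate ~1.5e-4 at the
  default mu).
- `f_C` depends on the cutoff choice; only relative comparisons at a fixed
  cutoff are meaningful, and no cutoff calibration against experimental
  fold-switch data is attempted here.
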