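"""Independent oracles and synthetic fixtures.

Everything the production pipeline computes cleverly is recomputed here the
slow, obvious way so the two can be compared on small instances:

* a brute-force lattice oracle that scans all 4^(L-1) directed walks,
  reduces symmetry orbits explicitly, counts contacts from coordinates, and
  evaluates sequences one conformation at a time;
* toy genotype networks with prescribed fitness for closed-form checks of
  the population dynamics;
* synthetic PDB-format structures whose carbon / non-carbon contact
  composition at a stated cutoff is controlled exactly by construction.

None of this code shares logic with the production modules: the oracle
canonicalizes via explicit coordinate transforms of all eight lattice
symmetries, where production fixes the first step and prunes reflections
during depth-first search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OracleResult",
    "oracle_enumerate",
    "oracle_sequence_summary",
    "oracle_networks_and_bridges",
    "ToyNetwork",
    "make_toy_network",
    "SyntheticStructureSpec",
    "make_synthetic_structure",
]

ORACLE_MAX_L = 12

_STEP = {"U": (0, 1), "D": (0, -1), "L": (-1, 0), "R": (1, 0)}
_ORDER = {"U": 0, "D": 1, "L": 2, "R": 3}

# the eight symmetries of the square lattice as 2x2 integer matrices
_SYMMETRIES = [
    np.array(m)
    for m in [
        [[1, 0], [0, 1]], [[0, -1], [1, 0]], [[-1, 0], [0, -1]],
        [[0, 1], [-1, 0]], [[1, 0], [0, -1]], [[-1, 0], [0, 1]],
        [[0, 1], [1, 0]], [[0, -1], [-1, 0]],
    ]
]

_VEC_TO_DIR = {(0, 1): "U", (0, -1): "D", (-1, 0): "L", (1, 0): "R"}


def _walk_coords(directions: str) -> list[tuple[int, int]] | None:
    """Coordinates of a directed walk, or None if it self-intersects."""
    x, y = 0, 0
    coords = [(0, 0)]
    seen = {(0, 0)}
    for ch in directions:
        dx, dy = _STEP[ch]
        x, y = x + dx, y + dy
        if (x, y) in seen:
            return None
        seen.add((x, y))
        coords.append((x, y))
    return coords


def _canonical_image(directions: str) -> str:
    """Smallest symmetry image (first step R, lex order U<D<L<R)."""
    steps = np.array([_STEP[ch] for ch in directions])
    images = []
    for sym in _SYMMETRIES:
        transformed = steps @ sym.T
        dirs = "".join(_VEC_TO_DIR[tuple(v)] for v in transformed)
        if dirs[0] == "R":
            images.append(dirs)
    return min(images, key=lambda d: [_ORDER[c] for c in d])


def _contacts_from_coords(coords: list[tuple[int, int]]
                          ) -> frozenset[tuple[int, int]]:
    out = set()
    for (i, a), (j, b) in itertools.combinations(enumerate(coords), 2):
        if j - i >= 3 and abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1:
            out.add((i + 1, j + 1))
    return frozenset(out)


@dataclass
class OracleResult:
    """Brute-force enumeration of one chain length."""

    L: int
    directions: list[str]                     # canonical, sorted
    contacts: list[frozenset[tuple[int, int]]]
    n_directed_walks: int

    def __len__(self) -> int:
        return len(self.directions)


def oracle_enumerate(L: int) -> OracleResult:
    """Scan all 4^(L-1) direction strings; keep one walk per symmetry orbit."""
    if not 2 <= L <= ORACLE_MAX_L:
        raise ValueError(f"oracle supports 2 <= L <= {ORACLE_MAX_L}")
    canonical: dict[str, frozenset[tuple[int, int]]] = {}
    n_directed = 0
    for combo in itertools.product("UDLR", repeat=L - 1):
        directions = "".join(combo)
        coords = _walk_coords(directions)
        if coords is None:
            continue
        n_directed += 1
        canon = _canonical_image(directions)
        if canon not in canonical:
            canonical[canon] = _contacts_from_coords(_walk_coords(canon))
    dirs = sorted(canonical, key=lambda d: [_ORDER[c] for c in d])
    return OracleResult(L=L, directions=dirs,
                        contacts=[canonical[d] for d in dirs],
                        n_directed_walks=n_directed)


def oracle_sequence_summary(oracle: OracleResult, seq: int
                            ) -> tuple[np.ndarray, int, int, tuple[int, ...]]:
    """(dos, n_native, g, native conformation indices) for one sequence.

    Direct per-conformation evaluation: the HH-contact count of the sequence
    in every enumerated conformation, histogrammed.
    """
    counts = []
    for contacts in oracle.contacts:
        n = sum(1 for (i, j) in contacts
                if (seq >> (i - 1)) & 1 and (seq >> (j - 1)) & 1)
        counts.append(n)
    counts = np.array(counts)
    n_max_possible = max((len(c) for c in oracle.contacts), default=0)
    dos = np.bincount(counts, minlength=n_max_possible + 1)
    n_native = int(counts.max())
    native = tuple(int(i) for i in np.flatnonzero(counts == n_native))
    return dos, n_native, len(native), native


def oracle_networks_and_bridges(oracle: OracleResult, g_cap: int = 6
                                ) -> tuple[list[dict], list[dict]]:
    """Neutral networks and bridges of a small sequence space, brute force.

    Returns (networks, bridges).  Each network dict has structure index,
    core and extended member sets; each bridge dict has seq, g and the set
    of connected (structure_i, component_i, structure_j, component_j) pairs.
    """
    L = oracle.L
    n_seq = 1 << L
    summary = [oracle_sequence_summary(oracle, s) for s in range(n_seq)]
    members: dict[int, set[int]] = {}
    for s in range(n_seq):
        _, _, g, native = summary[s]
        if g <= g_cap:
            for c in native:
                members.setdefault(c, set()).add(s)
    networks = []
    net_of: dict[tuple[int, int], int] = {}  # (structure, seq) -> net index
    for c in sorted(members):
        remaining = set(members[c])
        while remaining:
            start = min(remaining)
            comp = {start}
            frontier = [start]
            while frontier:
                s = frontier.pop()
                for k in range(L):
                    m = s ^ (1 << k)
                    if m in remaining or (m in members[c] and m not in comp):
                        if m not in comp:
                            comp.add(m)
                            frontier.append(m)
            remaining -= comp
            idx = len(networks)
            networks.append({
                "structure": c,
                "core": frozenset(s for s in comp if summary[s][2] == 1),
                "extended": frozenset(comp),
            })
            for s in comp:
                net_of[(c, s)] = idx
    bridges = []
    for s in range(n_seq):
        _, _, g, native = summary[s]
        if not 2 <= g <= g_cap:
            continue
        witnessed = set()
        for k in range(L):
            m = s ^ (1 << k)
            _, _, gm, native_m = summary[m]
            if gm == 1 and native_m[0] in native:
                witnessed.add(native_m[0])
        if len(witnessed) >= 2:
            connections = frozenset(
                frozenset((net_of[(c1, s)], net_of[(c2, s)]))
                for c1, c2 in itertools.combinations(sorted(witnessed), 2)
            )
            bridges.append({"seq": s, "g": g, "connections": connections})
    return networks, bridges


@dataclass
class ToyNetwork:
    """A hand-specified genotype graph with fitness labels."""

    n: int
    edges: list[tuple[int, int]]
    fitness: np.ndarray
    adjacency: "np.ndarray" = field(init=False)

    def __post_init__(self):
        A = np.zeros((self.n, self.n))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        self.adjacency = A


def make_toy_network(kind: str, **kwargs) -> ToyNetwork:
    """Deterministic toy instances with analytically known steady states.

    kinds: "pair" (2 genotypes, one edge; fitness ratio r), "chain"
    (n genotypes in a path, uniform fitness unless given), "star" (hub plus
    leaves, uniform fitness).
    """
    if kind == "pair":
        r = kwargs.get("fitness_ratio", 1.0)
        return ToyNetwork(2, [(0, 1)], np.array([r, 1.0]))
    if kind == "chain":
        n = kwargs.get("n", 3)
        fit = np.asarray(kwargs.get("fitness", np.ones(n)), dtype=float)
        return ToyNetwork(n, [(i, i + 1) for i in range(n - 1)], fit)
    if kind == "star":
        n_leaves = kwargs.get("n_leaves", 4)
        n = n_leaves + 1
        return ToyNetwork(n, [(0, i) for i in range(1, n)], np.ones(n))
    raise ValueError(f"unknown toy network kind {kind!r}")


@dataclass(frozen=True)
class SyntheticStructureSpec:
    """Recipe for a synthetic PDB-format structure with exact contact counts.

    The generated file contains ``n_residues`` placeholder residues whose
    backbone atoms are spaced too far apart to interact; each requested
    contact is realized by a dedicated pair of atoms (carbon-carbon or
    nitrogen-nitrogen) placed 2 A apart at an isolated site.  At the stated
    cutoff the structure therefore has exactly ``n_cc`` carbon-carbon and
    ``n_total`` total inter-residue contacts.  ``noise`` jitters all
    coordinates uniformly by up to that amplitude (must stay below 1 A to
    preserve the counts); ``carbon_backbone`` selects the element of the
    non-interacting backbone atoms.
    """

    n_residues: int = 6
    n_cc: int = 3
    n_total: int = 5
    cutoff: float = 5.0
    noise: float = 0.0
    seed: int = 0
    carbon_backbone: bool = True

    def __post_init__(self):
        if self.n_cc > self.n_total:
            raise ValueError("n_cc cannot exceed n_total")
        if not 0 <= self.noise < 1.0:
            raise ValueError("noise must stay below 1 A")
        if self.n_residues < 4 and self.n_total > 0:
            raise ValueError("need >= 4 residues for separation-3 contacts")


_PDB_ATOM = ("ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
             "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
             "{occ:6.2f}{b:6.2f}          {element:>2s}\n")


def make_synthetic_structure(spec: SyntheticStructureSpec, path) -> None:
    """Write a synthetic PDB file realizing the spec's contact counts.

    Round-trips through :func:`hpbridge.contacts3d.read_structure`; the
    resulting contact density at ``spec.cutoff`` is exactly
    ``spec.n_cc / spec.n_total`` (a zero-contact spec yields a structure for
    which the density is undefined and the reader of f_C must signal it).
    """
    rng = np.random.default_rng(spec.seed)
    spacing = 4.0 * spec.cutoff  # backbone atoms never interact
    lines = ["HEADER    SYNTHETIC CONTACT-DENSITY FIXTURE\n"]
    serial = 1
    backbone_el = "C" if spec.carbon_backbone else "N"

    def emit(name, element, res_idx, x, y, z):
        nonlocal serial
        jitter = rng.uniform(-spec.noise, spec.noise, 3) if spec.noise else (
            np.zeros(3))
        lines.append(_PDB_ATOM.format(
            serial=serial, name=f" {name:<3s}", alt=" ", res="GLY",
            chain="A", resseq=res_idx + 1, icode=" ",
            x=x + jitter[0], y=y + jitter[1], z=z + jitter[2],
            occ=1.0, b=0.0, element=element))
        serial += 1

    for r in range(spec.n_residues):
        emit("CA" if backbone_el == "C" else "N", backbone_el, r,
             r * spacing, 0.0, 0.0)
    # contact sites: isolated meeting points, one per requested contact,
    # each between residues 1 and 4 (separation 3)
    gap = 2.0
    # worst-case jitter moves both atoms sqrt(3)*noise apart
    if gap + 2 * np.sqrt(3) * spec.noise >= spec.cutoff:
        raise ValueError("noise too large for the requested cutoff")
    for k in range(spec.n_total):
        element = "C" if k < spec.n_cc else "N"
        y = spacing * (k + 2)
        name = f"{element}X{k % 10}"
        emit(name, element, 0, 0.0, y, 0.0)
        emit(name, element, 3, gap, y, 0.0)
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
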