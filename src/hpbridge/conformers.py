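"""Enumeration of symmetry-distinct self-avoiding walks on the square lattice.

A chain of ``L`` monomers is a self-avoiding walk of ``L - 1`` unit steps on
the 2D square lattice.  Walks related by one of the 8 lattice symmetries
(4 rotations x reflection) describe the same structure and are counted once;
chain reversal is *not* a symmetry because monomer 1 is distinguishable from
monomer L.  The canonical representative of an orbit fixes the first step to
R and, of the two reflection images that remain, keeps the lexicographically
smaller direction string under the order U < D < L < R.

Structures are reduced further to *contact classes*: groups of conformations
with identical sets of non-bonded nearest-neighbor residue pairs.  Energy
evaluation of a sequence only depends on the contact set, so the sequence
sweep operates on classes rather than on the full conformation list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "Conformation",
    "ConformationSet",
    "ContactClassSet",
    "MAX_LENGTH",
    "admissible_pairs",
    "enumerate_saws",
    "contact_pairs",
    "build_contact_classes",
    "directions_to_coords",
]

MAX_LENGTH = 18

_DIR_CHARS = "UDLR"
_STEP = {"U": (0, 1), "D": (0, -1), "L": (-1, 0), "R": (1, 0)}


def admissible_pairs(L: int) -> list[tuple[int, int]]:
    """All residue pairs (i, j), 1-based, that can form a lattice contact.

    On the square lattice two residues can only be non-bonded neighbors when
    j - i is odd (parity) and at least 3 (non-bonded).  There are 64 such
    pairs at L = 18, so a contact set fits one 64-bit word.
    """
    return [
        (i, j)
        for i in range(1, L + 1)
        for j in range(i + 3, L + 1, 2)
    ]


def _pair_bit_table(L: int) -> np.ndarray:
    """Map 0-based residue pair (i, j) -> bit index, -1 if inadmissible."""
    table = np.full((L, L), -1, dtype=np.int16)
    for b, (i, j) in enumerate(admissible_pairs(L)):
        table[i - 1, j - 1] = b
        table[j - 1, i - 1] = b
    return table


def directions_to_coords(directions: str) -> list[tuple[int, int]]:
    """Lattice coordinates of a walk given its direction string."""
    x, y = 0, 0
    coords = [(0, 0)]
    for ch in directions:
        dx, dy = _STEP[ch]
        x, y = x + dx, y + dy
        coords.append((x, y))
    return coords


@dataclass(frozen=True)
class Conformation:
    """One symmetry-canonical self-avoiding walk.

    Residue indexing is 1-based; ``contacts`` holds (i, j) pairs with
    j - i odd and >= 3 whose residues occupy adjacent lattice sites.
    """

    id: int
    directions: str
    coords: list[tuple[int, int]] = field(repr=False)
    contacts: frozenset[tuple[int, int]]

    @property
    def length(self) -> int:
        return len(self.directions) + 1


class ConformationSet(Sequence):
    """Array-backed, id-ordered collection of all conformations of one length.

    The arrays are the working representation for chain lengths where the
    object-per-walk view would be wasteful (5.8 million walks at L = 18);
    ``__getitem__`` materializes a :class:`Conformation` on demand.
    """

    def __init__(self, L: int, packed_dirs: np.ndarray, masks: np.ndarray):
        self.L = int(L)
        self.packed_dirs = packed_dirs
        self.masks = masks
        self.pairs = admissible_pairs(self.L)

    def __len__(self) -> int:
        return len(self.packed_dirs)

    def directions(self, conf_id: int) -> str:
        packed = int(self.packed_dirs[conf_id])
        chars = []
        for k in range(self.L - 2, -1, -1):
            chars.append(_DIR_CHARS[(packed >> (2 * k)) & 3])
        return "".join(chars)

    def contact_set(self, conf_id: int) -> frozenset[tuple[int, int]]:
        mask = int(self.masks[conf_id])
        return frozenset(
            p for b, p in enumerate(self.pairs) if (mask >> b) & 1
        )

    def __getitem__(self, conf_id: int) -> Conformation:
        if not -len(self) <= conf_id < len(self):
            raise IndexError(conf_id)
        conf_id = int(conf_id) % len(self)
        directions = self.directions(conf_id)
        return Conformation(
            id=conf_id,
            directions=directions,
            coords=directions_to_coords(directions),
            contacts=self.contact_set(conf_id),
        )

    def __iter__(self) -> Iterator[Conformation]:
        for i in range(len(self)):
            yield self[i]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tdirections\tn_contacts\tcontact_list\n")
            for i in range(len(self)):
                contacts = sorted(self.contact_set(i))
                fh.write(
                    f"{i}\t{self.directions(i)}\t{len(contacts)}\t"
                    + ";".join(f"{a}-{b}" for a, b in contacts)
                    + "\n"
                )


class ContactClassSet:
    """Partition of a ConformationSet by identical contact sets.

    ``masks`` holds one 64-bit contact mask per class (ascending order, which
    fixes class ids deterministically), ``multiplicity`` the number of
    conformations sharing it.  ``members(k)`` recovers the conformation ids
    of class ``k``.
    """

    def __init__(self, confs: ConformationSet):
        self.L = confs.L
        masks, inverse, counts = np.unique(
            confs.masks, return_inverse=True, return_counts=True
        )
        self.masks = masks
        self.multiplicity = counts.astype(np.int64)
        self.class_of_conf = inverse.astype(np.int32)
        order = np.argsort(inverse, kind="stable")
        self._member_ids = order.astype(np.int32)
        self._offsets = np.concatenate(([0], np.cumsum(counts)))
        self.popcounts = np.bitwise_count(masks).astype(np.int8)

    def __len__(self) -> int:
        return len(self.masks)

    def members(self, class_id: int) -> np.ndarray:
        lo, hi = self._offsets[class_id], self._offsets[class_id + 1]
        return self._member_ids[lo:hi]

    @property
    def max_contacts(self) -> int:
        return int(self.popcounts.max())


def enumerate_saws(L: int) -> ConformationSet:
    """Enumerate all symmetry-distinct self-avoiding walks of ``L`` monomers.

    Returns one canonical representative per orbit of the 8-element lattice
    symmetry group, ordered (and id-indexed) by direction string under
    U < D < L < R.

    Raises ``ValueError`` outside 2 <= L <= 18.
    """
    if not 2 <= L <= MAX_LENGTH:
        raise ValueError(f"chain length must be in [2, {MAX_LENGTH}], got {L}")
    pair_bit = _pair_bit_table(L)
    empty = np.empty(0, dtype=np.uint64)
    n = _kernels.enumerate_canonical(L, pair_bit, empty, empty, False)
    packed = np.empty(n, dtype=np.uint64)
    masks = np.empty(n, dtype=np.uint64)
    _kernels.enumerate_canonical(L, pair_bit, packed, masks, True)
    order = np.argsort(packed, kind="stable")
    return ConformationSet(L, packed[order], masks[order])


def contact_pairs(conf: Conformation) -> set[tuple[int, int]]:
    """Non-bonded nearest-neighbor residue pairs of a conformation.

    Recomputed from coordinates (not read off the stored contact set), so it
    doubles as an independent check of the enumeration masks.
    """
    coords = conf.coords
    index = {c: i for i, c in enumerate(coords)}
    out: set[tuple[int, int]] = set()
    for i, (x, y) in enumerate(coords):
        for dx, dy in _STEP.values():
            j = index.get((x + dx, y + dy))
            if j is not None and j - i >= 3:
                out.add((i + 1, j + 1))
    return out


def build_contact_classes(confs: ConformationSet) -> ContactClassSet:
    """Group a complete conformation set into contact-map equivalence classes."""
    return ContactClassSet(confs)
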