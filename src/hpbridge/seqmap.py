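"""Exhaustive sequence -> structure thermodynamics for the 2D HP model.

Every sequence of length L over the two-letter alphabet {H, P} is scored
against the complete conformation set of that length.  The only favorable
energy is the hydrophobic-hydrophobic (HH) contact energy eps < 0, so a
conformation with n HH contacts has energy n*eps and Boltzmann weight
exp(-beta_eps * n) with beta_eps = eps/(k_B T) < 0.  The fractional
population of structure c for sequence s is

    P(s, c) = exp(-beta_eps * n(s, c)) / sum_n h_s(n) exp(-beta_eps * n)

where h_s is the density of states of s (number of conformations per HH
contact count).  The native state of s is the set of conformations with the
maximal n(s, c); its size is the native-state degeneracy g.  Sequences with
g = 1 fold uniquely; sequences with 2 <= g <= g_cap are multi-stable.

Sequences are represented as integer bit masks (bit i = 1 means monomer
i + 1 is H; bit 0 is monomer 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import _kernels
from .conformers import (
    ConformationSet,
    ContactClassSet,
    admissible_pairs,
    build_contact_classes,
    enumerate_saws,
)

__all__ = [
    "ModelParams",
    "SequenceThermo",
    "SequenceSpaceMap",
    "seq_to_str",
    "str_to_seq",
    "density_of_states",
    "native_summary",
    "fractional_population",
    "stability_difference",
    "full_map",
]

DEFAULT_BETA_EPS = -2.0
DEFAULT_G_CAP = 6


@dataclass(frozen=True)
class ModelParams:
    """Chain length, reduced HH contact energy and degeneracy cap.

    beta_eps is eps/(k_B T); it must be negative (HH contacts favorable).
    g_cap is the largest native-state degeneracy considered viable; sequences
    above it are excluded from all network analyses.
    """

    L: int
    beta_eps: float = DEFAULT_BETA_EPS
    g_cap: int = DEFAULT_G_CAP

    def __post_init__(self):
        if not self.beta_eps < 0:
            raise ValueError("beta_eps must be negative (favorable HH energy)")
        if self.g_cap < 1:
            raise ValueError("g_cap must be >= 1")


def seq_to_str(seq: int, L: int) -> str:
    """H/P string of a sequence bit mask, monomer 1 first."""
    return "".join("H" if (seq >> i) & 1 else "P" for i in range(L))


def str_to_seq(s: str) -> int:
    """Inverse of :func:`seq_to_str`."""
    seq = 0
    for i, ch in enumerate(s.upper()):
        if ch == "H":
            seq |= 1 << i
        elif ch != "P":
            raise ValueError(f"invalid HP character {ch!r}")
    return seq


@dataclass
class SequenceThermo:
    """Thermodynamic summary of one sequence.

    native_ids is None when g exceeds the degeneracy cap (the identities of
    an over-cap native state are not tracked).  p_native is the fractional
    population of each native structure; all native structures of one
    sequence are equally populated.
    """

    seq: int
    L: int
    dos: np.ndarray
    n_native: int
    g: int
    native_ids: tuple[int, ...] | None
    p_native: float

    @property
    def over_cap(self) -> bool:
        return self.native_ids is None

    @property
    def hp(self) -> str:
        return seq_to_str(self.seq, self.L)


def _pair_arrays(L: int) -> tuple[np.ndarray, np.ndarray]:
    pairs = admissible_pairs(L)
    i = np.array([p[0] - 1 for p in pairs], dtype=np.int64)
    j = np.array([p[1] - 1 for p in pairs], dtype=np.int64)
    return i, j


def _seq_pair_mask(seq: int, pair_i: np.ndarray, pair_j: np.ndarray) -> int:
    m = 0
    for b in range(pair_i.size):
        if (seq >> int(pair_i[b])) & 1 and (seq >> int(pair_j[b])) & 1:
            m |= 1 << b
    return m


def density_of_states(seq: int, classes: ContactClassSet) -> np.ndarray:
    """h[n] = number of conformations with exactly n HH contacts for seq."""
    pair_i, pair_j = _pair_arrays(classes.L)
    out = _kernels.dos_batch(
        np.array([seq], dtype=np.int64), classes.L, pair_i.size, pair_i,
        pair_j, classes.masks, classes.multiplicity, classes.max_contacts,
    )
    return out[0]


def native_summary(
    seq: int, classes: ContactClassSet, g_cap: int = DEFAULT_G_CAP
) -> tuple[int, int, tuple[int, ...] | None]:
    """(n_native, g, native conformation ids or None if g > g_cap)."""
    pair_i, pair_j = _pair_arrays(classes.L)
    smask = _seq_pair_mask(seq, pair_i, pair_j)
    hh = np.bitwise_count(classes.masks & np.uint64(smask))
    n_native = int(hh.max())
    at_max = np.flatnonzero(hh == n_native)
    g = int(classes.multiplicity[at_max].sum())
    if g > g_cap:
        return n_native, g, None
    ids = np.sort(np.concatenate([classes.members(k) for k in at_max]))
    return n_native, g, tuple(int(i) for i in ids)


def fractional_population(
    seq: int, structure_id: int, params: ModelParams,
    classes: ContactClassSet, confs: ConformationSet,
) -> float:
    """Boltzmann probability of one structure in the sequence's ensemble."""
    pair_i, pair_j = _pair_arrays(params.L)
    smask = _seq_pair_mask(seq, pair_i, pair_j)
    n = int(np.bitwise_count(np.uint64(smask) & confs.masks[structure_id]))
    dos = density_of_states(seq, classes)
    return _p_from_dos(n, dos, params.beta_eps)


def _p_from_dos(n: int, dos: np.ndarray, beta_eps: float) -> float:
    ns = np.arange(dos.size)
    # shift by the native exponent for numerical safety at large |beta_eps|
    w = np.exp(-beta_eps * (ns - ns.max()))
    z = float(np.dot(dos, w))
    return float(np.exp(-beta_eps * (n - ns.max())) / z)


def stability_difference(
    seq: int, struct_a: int, struct_b: int, confs: ConformationSet
) -> int:
    """HH-contact stability difference of seq between two structures.

    Defined as n(seq, B) - n(seq, A): negative values favor the first
    structure (A has more HH contacts, hence lower energy), zero marks exact
    bi-stability.  Antisymmetric under swapping the structures.
    """
    pair_i, pair_j = _pair_arrays(confs.L)
    smask = np.uint64(_seq_pair_mask(seq, pair_i, pair_j))
    n_a = int(np.bitwise_count(smask & confs.masks[struct_a]))
    n_b = int(np.bitwise_count(smask & confs.masks[struct_b]))
    return n_b - n_a


class SequenceSpaceMap:
    """Complete native-state census of all 2^L sequences.

    Holds, per sequence: the maximal HH-contact count ``n_native``, the
    native-state degeneracy ``g``, and (for g <= g_cap) the native
    conformation ids.  Densities of states and fractional populations are
    computed lazily per sequence; storing the full 2^L x (n_max+1) table is
    unnecessary for the network analyses.
    """

    def __init__(self, params: ModelParams, confs: ConformationSet,
                 classes: ContactClassSet, n_native: np.ndarray,
                 g: np.ndarray, hits: np.ndarray, nhits: np.ndarray):
        self.params = params
        self.confs = confs
        self.classes = classes
        self.n_native = n_native
        self.g = g
        self._hits = hits
        self._nhits = nhits
        self._pair_i, self._pair_j = _pair_arrays(params.L)
        # class order sorted by descending popcount, as used by the sweep
        self._desc = np.argsort(-classes.popcounts.astype(np.int64),
                                kind="stable")

    # -- basic accessors ---------------------------------------------------
    @property
    def L(self) -> int:
        return self.params.L

    @property
    def n_sequences(self) -> int:
        return 1 << self.L

    @property
    def R(self) -> int:
        """Total conformation count for this chain length."""
        return len(self.confs)

    def native_ids(self, seq: int) -> tuple[int, ...] | None:
        """Conformation ids of the native state; None when g > g_cap."""
        if self.g[seq] > self.params.g_cap:
            return None
        ks = self._desc[self._hits[seq, : self._nhits[seq]]]
        ids = np.sort(np.concatenate([self.classes.members(k) for k in ks]))
        return tuple(int(i) for i in ids)

    def dos(self, seq: int) -> np.ndarray:
        return self.dos_many(np.array([seq], dtype=np.int64))[0]

    def dos_many(self, seqs: np.ndarray) -> np.ndarray:
        return _kernels.dos_batch(
            np.asarray(seqs, dtype=np.int64), self.L, self._pair_i.size,
            self._pair_i, self._pair_j, self.classes.masks,
            self.classes.multiplicity, self.classes.max_contacts,
        )

    def p_native(self, seq: int) -> float:
        """Fractional population of each (equally populated) native structure."""
        return _p_from_dos(int(self.n_native[seq]), self.dos(seq),
                           self.params.beta_eps)

    def p_native_many(self, seqs: np.ndarray) -> np.ndarray:
        seqs = np.asarray(seqs, dtype=np.int64)
        dos = self.dos_many(seqs)
        ns = np.arange(dos.shape[1])
        nmax = ns.max()
        w = np.exp(-self.params.beta_eps * (ns - nmax))
        z = dos @ w
        n_nat = self.n_native[seqs].astype(np.int64)
        return np.exp(-self.params.beta_eps * (n_nat - nmax)) / z

    def contacts_on_structure(self, seqs: np.ndarray, structure_id: int
                              ) -> np.ndarray:
        """n(seq, c) for many sequences on one structure."""
        return _kernels.contacts_for_sequences(
            np.asarray(seqs, dtype=np.int64), self.confs.masks[structure_id],
            self._pair_i.size, self._pair_i, self._pair_j,
        )

    def thermo(self, seq: int) -> SequenceThermo:
        dos = self.dos(seq)
        return SequenceThermo(
            seq=int(seq), L=self.L, dos=dos,
            n_native=int(self.n_native[seq]), g=int(self.g[seq]),
            native_ids=self.native_ids(seq),
            p_native=_p_from_dos(int(self.n_native[seq]), dos,
                                 self.params.beta_eps),
        )

    def degeneracy_histogram(self) -> dict[int, int]:
        """Count of sequences per degeneracy 1..g_cap, plus 'over' beyond cap."""
        out: dict = {}
        for gv in range(1, self.params.g_cap + 1):
            out[gv] = int(np.count_nonzero(self.g == gv))
        out["over"] = int(np.count_nonzero(self.g > self.params.g_cap))
        return out

    def multistable_sequences(self) -> np.ndarray:
        """Sequences with 2 <= g <= g_cap, ascending."""
        return np.flatnonzero((self.g >= 2) & (self.g <= self.params.g_cap))

    def core_sequences(self) -> np.ndarray:
        """Uniquely folding (g = 1) sequences, ascending."""
        return np.flatnonzero(self.g == 1)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["L"] = self.L
            fh.attrs["beta_eps"] = self.params.beta_eps
            fh.attrs["g_cap"] = self.params.g_cap
            fh.create_dataset("packed_dirs", data=self.confs.packed_dirs,
                              compression="gzip")
            fh.create_dataset("conf_masks", data=self.confs.masks,
                              compression="gzip")
            fh.create_dataset("n_native", data=self.n_native,
                              compression="gzip")
            fh.create_dataset("g", data=self.g, compression="gzip")
            fh.create_dataset("hits", data=self._hits, compression="gzip")
            fh.create_dataset("nhits", data=self._nhits, compression="gzip")

    @classmethod
    def load(cls, path) -> "SequenceSpaceMap":
        import h5py

        with h5py.File(path, "r") as fh:
            params = ModelParams(L=int(fh.attrs["L"]),
                                 beta_eps=float(fh.attrs["beta_eps"]),
                                 g_cap=int(fh.attrs["g_cap"]))
            confs = ConformationSet(params.L, fh["packed_dirs"][:],
                                    fh["conf_masks"][:])
            classes = build_contact_classes(confs)
            return cls(params, confs, classes, fh["n_native"][:], fh["g"][:],
                       fh["hits"][:], fh["nhits"][:])

    def to_tsv(self, path, seqs: Iterable[int] | None = None) -> None:
        if seqs is None:
            seqs = range(self.n_sequences)
        with open(path, "w") as fh:
            fh.write("seq\tn_native\tg\tnative_ids\n")
            for s in seqs:
                ids = self.native_ids(s)
                fh.write(
                    f"{seq_to_str(s, self.L)}\t{self.n_native[s]}\t{self.g[s]}"
                    f"\t{'over_cap' if ids is None else ';'.join(map(str, ids))}\n"
                )


def full_map(params: ModelParams, confs: ConformationSet | None = None
             ) -> SequenceSpaceMap:
    """Exhaustive native-state census of all 2^L sequences.

    The sweep evaluates each sequence against contact classes sorted by
    descending contact count, stopping as soon as the remaining classes
    cannot reach the running maximum; this makes the full L=18 map (262,144
    sequences against ~170k classes) a minutes-scale computation.
    """
    if confs is None:
        confs = enumerate_saws(params.L)
    classes = build_contact_classes(confs)
    desc = np.argsort(-classes.popcounts.astype(np.int64), kind="stable")
    masks_d = classes.masks[desc]
    mult_d = classes.multiplicity[desc]
    pop_d = classes.popcounts[desc].astype(np.int64)
    pair_i, pair_j = _pair_arrays(params.L)
    n_seq = 1 << params.L
    out_n = np.zeros(n_seq, dtype=np.int8)
    out_g = np.zeros(n_seq, dtype=np.int64)
    hits = np.zeros((n_seq, params.g_cap), dtype=np.int32)
    nhits = np.zeros(n_seq, dtype=np.int8)
    _kernels.sweep_native(params.L, pair_i.size, pair_i, pair_j, masks_d,
                          mult_d, pop_d, params.g_cap, out_n, out_g, hits,
                          nhits)
    return SequenceSpaceMap(params, confs, classes, out_n, out_g, hits, nhits)
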