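"""Hydrophobic contact density of atomic protein structures.

The lattice model's hydrophobic-contact count has an atomic-level analog:
the fraction f_C of inter-residue atomic contacts that are carbon-carbon,

    f_C = n_CC / n_total

where a contact is any pair of atoms from residues at least ``min_seq_sep``
positions apart along the chain whose distance is below ``cutoff``.  Using
the element (any carbon atom) rather than a residue hydrophobicity scale
makes the measure independent of assignment conventions; buried carbons of
polar side chains contribute.  The signed difference Delta f_C between two
experimentally determined structures of one sequence is a bi-stability
read-out for fold-switch candidates.

The module also implements the screening filters used to rank structure
pairs from conformational-diversity databases as bridge-protein candidates:
a minimal backbone RMSD (to exclude trivial structural variation), a
minimal sequence identity, and a cut on externally computed per-length
stability-score differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "AtomicStructure",
    "ContactDensityResult",
    "UndefinedContactDensityError",
    "read_structure",
    "contact_density",
    "delta_f_C",
    "screen_candidates",
    "DEFAULT_CUTOFF",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 5.0  # Angstrom; configurable, see module docs
DEFAULT_MIN_SEQ_SEP = 3

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class UndefinedContactDensityError(ValueError):
    """No qualifying atom pairs: the contact density is undefined."""


@dataclass
class AtomicStructure:
    """Atoms of one chain of one model, with per-atom residue positions.

    ``residue_pos`` holds author sequence positions (strictly increasing
    along the chain); ``elements`` are upper-case element symbols.
    """

    chain_id: str
    coords: np.ndarray          # (n_atoms, 3) float64, Angstrom
    elements: np.ndarray        # (n_atoms,) str
    residue_pos: np.ndarray     # (n_atoms,) int
    residue_names: np.ndarray   # (n_atoms,) str

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.residue_pos))


@dataclass
class ContactDensityResult:
    """Carbon-contact fraction of one structure."""

    n_cc: int
    n_total: int
    cutoff: float
    min_seq_sep: int

    @property
    def f_c(self) -> float:
        return self.n_cc / self.n_total


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    # PDB atom names start with the element, optionally preceded by a digit
    # (e.g. "1HB"); two-letter elements occupy columns 13-14.
    stripped = stripped.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in {
            "Fe", "Zn", "Mg", "Mn", "Cu", "Na", "Cl", "Ca", "Se", "Br"}:
        return stripped[:2].upper()
    return stripped[0].upper()


def read_structure(path, chain: str | None = None, model: int = 0,
                   include_hydrogens: bool = False,
                   include_hetero: bool = False) -> AtomicStructure:
    """Parse a PDB file into an :class:`AtomicStructure`.

    Selects one model and one chain (the first chain when ``chain`` is
    None).  Waters are always excluded; other heteroatom records are
    excluded unless ``include_hetero``.  Hydrogens are excluded by default
    (crystal structures rarely resolve them; contact counting is over heavy
    atoms).  Missing element symbols are inferred from atom names and
    reported through the module logger.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    models = list(structure)
    if model >= len(models):
        raise ValueError(
            f"model {model} not present ({len(models)} model(s) in file)")
    mdl = models[model]
    chains = {c.id: c for c in mdl}
    if chain is None:
        chain = next(iter(chains))
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not present (available: {sorted(chains)})")
    coords, elements, pos, names = [], [], [], []
    n_inferred = 0
    for residue in chains[chain]:
        hetfield, resseq, _ = residue.id
        if residue.resname.strip() in _WATER_NAMES:
            continue
        if hetfield.strip() and not include_hetero:
            continue
        for atom in residue:
            element = (atom.element or "").strip().upper()
            if not element:
                element = _element_from_name(atom.get_name())
                n_inferred += 1
            if element == "H" and not include_hydrogens:
                continue
            if not element.isalpha():
                raise ValueError(
                    f"unresolvable element for atom {atom.get_fullname()!r} "
                    f"in residue {residue.id}")
            coords.append(atom.coord)
            elements.append(element)
            pos.append(resseq)
            names.append(residue.resname.strip())
    if n_inferred:
        logger.warning(
            "element column absent for %d atom(s) in %s; inferred from "
            "atom names", n_inferred, path)
    if not coords:
        raise ValueError(f"no atoms selected from {path} chain {chain!r}")
    out = AtomicStructure(
        chain_id=chain,
        coords=np.asarray(coords, dtype=np.float64),
        elements=np.asarray(elements),
        residue_pos=np.asarray(pos, dtype=np.int64),
        residue_names=np.asarray(names),
    )
    if not np.all(np.isfinite(out.coords)):
        raise ValueError(f"non-finite coordinates in {path}")
    return out


def contact_density(struct: AtomicStructure,
                    cutoff: float = DEFAULT_CUTOFF,
                    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP
                    ) -> ContactDensityResult:
    """Carbon-contact fraction f_C of one structure.

    Counts all atom pairs from residues >= min_seq_sep positions apart
    whose distance is strictly below ``cutoff``; f_C is the carbon-carbon
    share.  Raises :class:`UndefinedContactDensityError` when no pair
    qualifies (rather than silently reporting zero).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    span = struct.residue_pos.max() - struct.residue_pos.min()
    if span < min_seq_sep:
        raise UndefinedContactDensityError(
            "no residue pair is separated by at least "
            f"{min_seq_sep} positions")
    tree = cKDTree(struct.coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(
            struct.coords[pairs[:, 0]] - struct.coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]  # strict inequality
    if len(pairs) == 0:
        raise UndefinedContactDensityError(
            f"no atom pairs within {cutoff} A at separation "
            f">= {min_seq_sep}")
    sep = np.abs(struct.residue_pos[pairs[:, 0]]
                 - struct.residue_pos[pairs[:, 1]])
    pairs = pairs[sep >= min_seq_sep]
    n_total = len(pairs)
    if n_total == 0:
        raise UndefinedContactDensityError(
            f"no atom pairs within {cutoff} A at separation "
            f">= {min_seq_sep}")
    is_c = struct.elements == "C"
    n_cc = int(np.count_nonzero(is_c[pairs[:, 0]] & is_c[pairs[:, 1]]))
    return ContactDensityResult(n_cc=n_cc, n_total=n_total, cutoff=cutoff,
                                min_seq_sep=min_seq_sep)


def delta_f_C(struct_a: AtomicStructure, struct_b: AtomicStructure,
              cutoff: float = DEFAULT_CUTOFF,
              min_seq_sep: int = DEFAULT_MIN_SEQ_SEP) -> float:
    """Signed contact-density difference f_C(A) - f_C(B).

    Negative values favor the second structure's packing; the measure is
    antisymmetric under swapping the arguments.  Both structures should
    carry the same (or a stated variant of the same) sequence.
    """
    fa = contact_density(struct_a, cutoff, min_seq_sep).f_c
    fb = contact_density(struct_b, cutoff, min_seq_sep).f_c
    return fa - fb


REQUIRED_COLUMNS = ("accession", "rmsd", "identity", "stability_difference")

DEFAULT_RMSD_MIN = 2.0        # Angstrom
DEFAULT_IDENTITY_MIN = 95.0   # percent
DEFAULT_DIFF_PERCENTILE = 10.0


def screen_candidates(records: pd.DataFrame,
                      rmsd_min: float = DEFAULT_RMSD_MIN,
                      identity_min: float = DEFAULT_IDENTITY_MIN,
                      diff_percentile: float = DEFAULT_DIFF_PERCENTILE
                      ) -> pd.DataFrame:
    """Screen structure-pair records for bridge-protein candidates.

    Keeps records with backbone RMSD >= rmsd_min and sequence identity >=
    identity_min; among the survivors keeps those whose stability-score
    difference lies within the lowest ``diff_percentile`` percent, and
    returns them sorted by ascending stability difference (ties broken by
    accession).  ``diff_percentile=100`` ranks without removing anything.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records lack required column(s): {missing}")
    if records.empty:
        return records.copy()
    if (records["rmsd"] < 0).any():
        raise ValueError("negative RMSD in records")
    if not records["identity"].between(0, 100).all():
        raise ValueError("sequence identity outside [0, 100]")
    kept = records[(records["rmsd"] >= rmsd_min)
                   & (records["identity"] >= identity_min)].copy()
    if kept.empty:
        return kept
    threshold = np.percentile(kept["stability_difference"], diff_percentile)
    kept = kept[kept["stability_difference"] <= threshold]
    return kept.sort_values(
        ["stability_difference", "accession"]).reset_index(drop=True)
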