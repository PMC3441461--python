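"""Atomic contact density and candidate screening."""

import numpy as np
import pandas as pd
import pytest

from hpbridge import contacts3d as c3
from hpbridge.synthdata import SyntheticStructureSpec, make_synthetic_structure


@pytest.mark.parametrize("n_cc,n_total,expected", [
    (3, 5, 0.6),
    (4, 4, 1.0),
    (2, 7, 2 / 7),
])
def test_contact_density_matches_construction(synth_pdb, n_cc, n_total,
                                              expected):
    path = synth_pdb(n_cc=n_cc, n_total=n_total, noise=0.2, seed=3)
    res = c3.contact_density(c3.read_structure(path), cutoff=5.0)
    assert res.n_cc == n_cc
    assert res.n_total == n_total
    assert res.f_c == pytest.approx(expected)


def test_no_carbon_structure_has_zero_density(synth_pdb):
    path = synth_pdb(n_cc=0, n_total=4, carbon_backbone=False)
    assert c3.contact_density(c3.read_structure(path)).f_c == 0.0


def test_zero_contacts_is_undefined_not_zero(synth_pdb):
    path = synth_pdb(n_cc=0, n_total=0)
    with pytest.raises(c3.UndefinedContactDensityError):
        c3.contact_density(c3.read_structure(path))


def test_rigid_motion_invariance(synth_pdb, rng):
    path = synth_pdb(n_cc=3, n_total=5, noise=0.1, seed=9)
    struct = c3.read_structure(path)
    base = c3.contact_density(struct)
    # random rotation (QR of a Gaussian matrix) plus translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved = c3.AtomicStructure(
        chain_id=struct.chain_id,
        coords=struct.coords @ q.T + np.array([11.0, -7.0, 3.5]),
        elements=struct.elements,
        residue_pos=struct.residue_pos,
        residue_names=struct.residue_names,
    )
    res = c3.contact_density(moved)
    assert res.n_cc == base.n_cc and res.n_total == base.n_total
    assert abs(res.f_c - base.f_c) < 1e-10


def test_counts_nondecreasing_in_cutoff(synth_pdb):
    path = synth_pdb(n_cc=3, n_total=6, noise=0.3, seed=4)
    struct = c3.read_structure(path)
    last_cc = last_total = 0
    for cutoff in (3.0, 5.0, 8.0, 15.0, 30.0):
        res = c3.contact_density(struct, cutoff=cutoff)
        assert res.n_cc >= last_cc
        assert res.n_total >= last_total
        last_cc, last_total = res.n_cc, res.n_total


def test_delta_f_c_antisymmetric(synth_pdb):
    pa = synth_pdb(n_cc=3, n_total=5)
    pb = synth_pdb(n_cc=2, n_total=5)
    a = c3.read_structure(pa)
    b = c3.read_structure(pb)
    assert c3.delta_f_C(a, b) == pytest.approx(0.2)
    assert c3.delta_f_C(b, a) == pytest.approx(-0.2)
    assert c3.delta_f_C(a, a) == 0.0


def test_min_seq_sep_excludes_close_pairs(synth_pdb):
    path = synth_pdb(n_cc=3, n_total=5)
    struct = c3.read_structure(path)
    # the engineered contacts sit between residues 1 and 4 (separation 3)
    with pytest.raises(c3.UndefinedContactDensityError):
        c3.contact_density(struct, min_seq_sep=4)


def test_read_structure_models_and_chains(tmp_path):
    atom = ("ATOM  {serial:>5d}  CA  GLY {chain}{resseq:>4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
    lines = ["MODEL        1\n"]
    for i in range(3):
        lines.append(atom.format(serial=i + 1, chain="A", resseq=i + 1,
                                 x=3.0 * i, y=0.0, z=0.0))
    lines += ["ENDMDL\n", "MODEL        2\n"]
    for i in range(2):
        lines.append(atom.format(serial=i + 1, chain="A", resseq=i + 1,
                                 x=0.0, y=3.0 * i, z=0.0))
    lines += ["ENDMDL\n", "END\n"]
    path = tmp_path / "multi.pdb"
    path.write_text("".join(lines))
    assert c3.read_structure(path, model=0).n_atoms == 3
    assert c3.read_structure(path, model=1).n_atoms == 2
    with pytest.raises(ValueError):
        c3.read_structure(path, model=5)
    with pytest.raises(ValueError):
        c3.read_structure(path, chain="Z")


def test_element_inferred_when_column_missing(tmp_path):
    # element columns (77-78) left blank; inferred from the atom name
    row = ("ATOM      1  CA  GLY A   1       0.000   0.000   0.000"
           "  1.00  0.00\n"
           "ATOM      2  N   GLY A   2       3.000   0.000   0.000"
           "  1.00  0.00\n")
    path = tmp_path / "noelem.pdb"
    path.write_text(row + "END\n")
    struct = c3.read_structure(path)
    assert list(struct.elements) == ["C", "N"]


TABLE_LIKE = pd.DataFrame([
    # mirrors the screening-input schema: accession, rmsd, identity,
    # per-length stability-score difference
    ("Q8WTS6", 3.53, 98.53, 0.00021),
    ("Q9BMI9", 2.16, 98.18, 0.00046),
    ("P01854", 2.06, 98.18, 0.00063),
    ("P54939", 2.12, 100.00, 0.00131),
    ("Q94734", 13.09, 100.00, 0.00204),
    ("P01008", 17.16, 100.00, 0.02646),
    ("LOWID1", 9.99, 42.00, 0.00001),   # fails identity filter
    ("LOWRMS", 0.50, 99.00, 0.00002),   # fails RMSD filter
], columns=["accession", "rmsd", "identity", "stability_difference"])


def test_screening_filters_and_orders():
    kept = c3.screen_candidates(TABLE_LIKE, rmsd_min=2.0, identity_min=95.0,
                                diff_percentile=100.0)
    assert "LOWID1" not in set(kept.accession)
    assert "LOWRMS" not in set(kept.accession)
    assert kept.accession.iloc[0] == "Q8WTS6"  # smallest difference first
    assert kept.stability_difference.is_monotonic_increasing
    # percentile keeps only the most bi-stable fraction
    top = c3.screen_candidates(TABLE_LIKE, diff_percentile=10.0)
    assert len(top) < len(kept)
    assert top.accession.iloc[0] == "Q8WTS6"


def test_screening_is_order_independent():
    shuffled = TABLE_LIKE.sample(frac=1.0, random_state=7)
    a = c3.screen_candidates(TABLE_LIKE)
    b = c3.screen_candidates(shuffled)
    pd.testing.assert_frame_equal(a, b)


def test_screening_validates_input():
    with pytest.raises(ValueError):
        c3.screen_candidates(pd.DataFrame({"accession": ["X"]}))
    empty = TABLE_LIKE.iloc[0:0]
    assert c3.screen_candidates(empty).empty
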