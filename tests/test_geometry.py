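"""Static structure observables: parsing, carboxylate distances, contacts,
ionic pairs, and rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from necroscan.geometry import (
    LigandPose,
    StructureError,
    carboxylate_distance,
    ionic_pairs,
    ligand_contacts,
    read_structure,
)
from necroscan.synthetic import (
    GeometryError,
    ToyComplexConfig,
    make_symmetric_complex,
    make_toy_complex,
)

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA AALA A   1      10.000   6.000  -6.000  0.60  0.00           C
ATOM      3  CA BALA A   1       9.500   6.100  -6.100  0.40  0.00           C
ATOM      4  C   ALA A   1      10.500   5.000  -5.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_roundtrip_atom_count(self, active_toy, tmp_path):
        path = tmp_path / "toy.pdb"
        active_toy.write(path)
        struct = read_structure(path, bw_map=active_toy.bw_map)
        assert struct.n_atoms == active_toy.structure.n_atoms

    def test_multimodel_keeps_first_model(self, active_toy, tmp_path):
        from necroscan.synthetic import write_pdb

        path = tmp_path / "two_models.pdb"
        coords = np.stack([active_toy.structure.coords,
                           active_toy.structure.coords + 5.0])
        write_pdb(active_toy.structure.atoms, coords, path)
        struct = read_structure(path)
        assert struct.n_atoms == active_toy.structure.n_atoms
        np.testing.assert_allclose(struct.coords,
                                   active_toy.structure.coords, atol=1e-2)

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB)
        struct = read_structure(path)
        ca = struct.atoms[struct.atoms["name"] == "CA"]
        assert len(ca) == 1
        assert float(ca["occupancy"].iloc[0]) == pytest.approx(0.6)
        assert float(ca["x"].iloc[0]) == pytest.approx(10.0)

    def test_no_atoms_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(StructureError, match="no atoms"):
            read_structure(path)


class TestCarboxylateDistance:
    @pytest.mark.parametrize("planted", [10.2, 11.6])
    def test_planted_distance_read_back(self, planted):
        toy = make_toy_complex(ToyComplexConfig(carboxylate_distance=planted))
        assert carboxylate_distance(toy.structure, "3.32", "5.43") == \
            pytest.approx(planted, abs=0.05)

    def test_same_label_distance_zero(self, active_toy):
        assert carboxylate_distance(active_toy.structure, "3.32", "3.32") == 0.0

    def test_symmetry(self, active_toy):
        assert carboxylate_distance(active_toy.structure, "3.32", "5.43") == \
            pytest.approx(
                carboxylate_distance(active_toy.structure, "5.43", "3.32"))

    def test_non_acidic_residue_rejected(self, active_toy):
        with pytest.raises(StructureError, match="not Asp/Glu"):
            carboxylate_distance(active_toy.structure, "3.33", "5.43")

    def test_incomplete_carboxylate_rejected(self, active_toy):
        atoms = active_toy.structure.atoms
        broken = atoms[~((atoms["resid"] == 112) & (atoms["name"] == "OD1"))]
        struct = type(active_toy.structure)(atoms=broken.reset_index(drop=True),
                                            bw_map=active_toy.bw_map)
        with pytest.raises(StructureError, match="incomplete"):
            carboxylate_distance(struct, "3.32", "5.43")

    def test_carbon_convention_available(self, active_toy):
        d = carboxylate_distance(active_toy.structure, "3.32", "5.43",
                                 method="carbon")
        assert d == pytest.approx(10.2, abs=0.5)


def brute_force_contacts(struct, pose, cutoff):
    lig = pose.heavy_coords()
    labels = set()
    receptor = struct.atoms[(struct.atoms["resname"] != pose.resname)
                            & (struct.atoms["element"] != "H")]
    for _, row in receptor.iterrows():
        d = cdist([[row["x"], row["y"], row["z"]]], lig).min()
        if d < cutoff:
            labels.add(struct.bw_map.get(row["resid"],
                                         f"{row['resname']}{row['resid']}"))
    return labels


class TestLigandContacts:
    def test_planted_contact_shell_exact(self, active_toy):
        contacts = ligand_contacts(active_toy.structure, active_toy.pose,
                                   cutoff=3.5)
        assert {c.label for c in contacts} == {"3.32", "3.33", "5.43", "6.51"}
        assert {c.label for c in contacts} == brute_force_contacts(
            active_toy.structure, active_toy.pose, 3.5)

    def test_tiny_cutoff_empty(self, active_toy):
        assert ligand_contacts(active_toy.structure, active_toy.pose,
                               cutoff=0.1) == []

    def test_cutoff_monotonicity(self, active_toy):
        near = {c.label for c in ligand_contacts(active_toy.structure,
                                                 active_toy.pose, 3.5)}
        far = {c.label for c in ligand_contacts(active_toy.structure,
                                                active_toy.pose, 4.5)}
        assert near <= far

    def test_sorted_by_distance(self, active_toy):
        contacts = ligand_contacts(active_toy.structure, active_toy.pose, 4.5)
        dists = [c.min_distance for c in contacts]
        assert dists == sorted(dists)

    def test_acidic_contacts_typed_ionic(self, active_toy):
        contacts = {c.label: c for c in
                    ligand_contacts(active_toy.structure, active_toy.pose, 3.5)}
        assert contacts["3.32"].contact_type == "ionic"
        assert contacts["3.33"].contact_type == "any"


class TestIonicPairs:
    def test_double_salt_bridge_in_active_toy(self, active_toy):
        ion = ionic_pairs(active_toy.structure, active_toy.pose, cutoff=4.0)
        assert ion.double_salt_bridge
        partners = {(p.n_name, p.label) for p in ion.pairs}
        assert ("N1", "3.32") in partners
        assert ("N2", "5.43") in partners

    def test_displaced_ligand_empty(self):
        toy = make_toy_complex(ToyComplexConfig(ligand_offset=(20.0, 0, 0)))
        ion = ionic_pairs(toy.structure, toy.pose)
        assert ion.pairs == ()
        assert not ion.double_salt_bridge
        assert ligand_contacts(toy.structure, toy.pose, 3.5) == []

    def test_symmetric_single_asp_not_double(self):
        sym = make_symmetric_complex()
        ion = ionic_pairs(sym.structure, sym.pose, cutoff=4.0)
        assert {p.n_name for p in ion.pairs} == {"N1", "N2"}
        assert not ion.double_salt_bridge


class TestRigidInvariance:
    def test_observables_invariant_under_rigid_transform(self, active_toy, rng):
        R = Rotation.random(random_state=7).as_matrix()
        t = rng.normal(size=3) * 10
        moved = active_toy.structure.transformed(R, t)
        pose = LigandPose.from_structure(moved)
        assert carboxylate_distance(moved, "3.32", "5.43") == pytest.approx(
            carboxylate_distance(active_toy.structure, "3.32", "5.43"), abs=1e-9)
        assert {c.label for c in ligand_contacts(moved, pose, 3.5)} == \
            {c.label for c in ligand_contacts(active_toy.structure,
                                              active_toy.pose, 3.5)}
        ion0 = ionic_pairs(active_toy.structure, active_toy.pose)
        ion1 = ionic_pairs(moved, pose)
        assert ion1.double_salt_bridge == ion0.double_salt_bridge
        assert len(ion1.pairs) == len(ion0.pairs)


def test_infeasible_toy_geometry_rejected():
    with pytest.raises(GeometryError, match="triangle"):
        make_toy_complex(ToyComplexConfig(carboxylate_distance=5.0,
                                          n_o_distance=2.8))
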