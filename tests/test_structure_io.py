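"""Coordinate I/O: parsing, altloc reduction, roles, selection, writing."""

import gemmi
import numpy as np
import pytest

import b1state as b1
from b1state.errors import (
    CapacityError,
    MissingResidueError,
    RoleAssignmentError,
)
from b1state.structure_io import Atom, Chain, Residue, Selector, StructureModel


def _inventory(model):
    return [
        (c.chain_id, r.author_number, r.name, a.name)
        for c, r, a in model.iter_atoms()
    ]


class TestReadStructure:
    def test_minimal_single_atom(self, minimal_pdb):
        model = b1.read_structure(minimal_pdb)
        assert len(model.chains) == 1
        assert len(model.chains[0]) == 1
        assert model.atom_count() == 1
        atom = model.chains[0].residues[0].atoms[0]
        assert atom.name == "CA"
        np.testing.assert_allclose(atom.position, [11.0, 22.0, 33.0])

    def test_altloc_reduction_and_water_removal(self, altloc_pdb):
        model = b1.read_structure(altloc_pdb)
        (chain,) = model.chains
        (res,) = chain.residues  # water dropped
        names = sorted(a.name for a in res.atoms)
        assert names == ["CA", "N", "OG"]
        # CA: B has the higher occupancy; OG: tie resolved to altloc A
        assert res.atom("CA").position[0] == pytest.approx(11.5)
        assert res.atom("OG").position[0] == pytest.approx(12.0)

    def test_unparseable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a coordinate file\n")
        with pytest.raises(b1.B1StateError):
            b1.read_structure(bad)

    def test_mmcif_uses_author_numbering(self, tmp_path, emulation):
        models, _ = emulation
        pdb_path = tmp_path / "m.pdb"
        b1.write_pdb(models["glp1r_inactive"], pdb_path)
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "m.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        again = b1.read_structure(cif_path)
        assert again.source_format == "mmCIF"
        table = b1.load_tables()["GLP1R"]
        chain = again.chains[0]
        assert chain.residue(table.resolve("6.37b")) is not None


class TestRoundTrip:
    def test_write_then_read_preserves_inventory_and_coords(self, tmp_path, emulation):
        models, _ = emulation
        model = models["gipr_bound"]
        path = tmp_path / "rt.pdb"
        b1.write_pdb(model, path)
        again = b1.read_structure(path)
        assert _inventory(again) == _inventory(model)
        pos_a = np.array([a.position for _, _, a in model.iter_atoms()])
        pos_b = np.array([a.position for _, _, a in again.iter_atoms()])
        np.testing.assert_allclose(pos_a, pos_b, atol=1e-3)

    def test_capacity_error_above_pdb_limit(self, tmp_path):
        atoms = [
            Atom(name="CA", position=np.array([float(i % 100), float(i // 100 % 100), 0.0]))
            for i in range(3)
        ]
        res = [Residue(chain_id="A", author_number=i + 1, name="ALA", atoms=[a])
               for i, a in enumerate(atoms)]
        model = StructureModel(label="tiny", chains=[Chain(chain_id="A", residues=res)])
        # fake a huge count without building 10^5 objects
        model.atom_count = lambda: 100001
        with pytest.raises(CapacityError):
            b1.write_pdb(model, tmp_path / "big.pdb")


class TestAssignRoles:
    def test_synthetic_two_chain_with_hints(self):
        model, truth = b1.make_interface_fixture("GLP1R", n_contacts=2)
        stripped = model.copy()
        for c in stripped.chains:
            c.entity_role = "other"
        assigned = b1.assign_roles(stripped, role_hints=truth.chain_roles)
        assert assigned.receptor_chain.chain_id == "R"
        assert assigned.chains_by_role("Galpha")[0].chain_id == "A"

    def test_receptor_found_without_hint(self):
        model = b1.make_bundle(b1.BundleSpec("GCGR"))
        stripped = model.copy()
        stripped.chains[0].entity_role = "other"
        assigned = b1.assign_roles(stripped)
        assert assigned.receptor_chain.chain_id == "R"

    def test_single_short_chain_errors(self, minimal_pdb):
        model = b1.read_structure(minimal_pdb)
        with pytest.raises(RoleAssignmentError):
            b1.assign_roles(model)


class TestSelectAtoms:
    def test_single_residue_ca(self, tables, emulation):
        models, _ = emulation
        sel = Selector(roles=["receptor"], generic_positions=["6.37b"],
                       atom_names=["CA"], table=tables["GLP1R"])
        picked = b1.select_atoms(models["glp1r_inactive"], sel)
        assert len(picked) == 1
        assert picked[0][1].author_number == 348

    def test_empty_residue_set_gives_empty_list(self, emulation):
        models, _ = emulation
        sel = Selector(author_numbers=[], atom_names=["CA"])
        assert b1.select_atoms(models["glp1r_inactive"], sel) == []

    def test_segment_selection_counts_every_helix_ca(self, tables, emulation):
        models, _ = emulation
        table = tables["GIPR"]
        sel = Selector(roles=["receptor"], segments=["TM6"], atom_names=["CA"], table=table)
        picked = b1.select_atoms(models["gipr_inactive"], sel)
        assert len(picked) == len(table.segment_residues("TM6"))

    def test_strict_selector_names_missing_residue(self, emulation):
        models, _ = emulation
        sel = Selector(author_numbers=[99999], atom_names=["CA"])
        with pytest.raises(MissingResidueError, match="99999"):
            b1.select_atoms(models["glp1r_inactive"], sel)
        tolerant = Selector(author_numbers=[99999], atom_names=["CA"], tolerant=True)
        assert b1.select_atoms(models["glp1r_inactive"], tolerant) == []

    def test_order_is_stable(self, emulation):
        models, _ = emulation
        sel = Selector(roles=["receptor"], atom_names=["CA"])
        a = [(c.chain_id, r.author_number, at.name)
             for c, r, at in b1.select_atoms(models["gcgr_bound"], sel)]
        b = [(c.chain_id, r.author_number, at.name)
             for c, r, at in b1.select_atoms(models["gcgr_bound"], sel)]
        assert a == b
        assert a == sorted(a)
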