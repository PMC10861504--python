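"""Contact detection, motif integrity, SASA and interface summaries."""

import numpy as np
import pytest

import b1state as b1
from b1state.errors import RoleAssignmentError
from b1state.networks import shrake_rupley
from b1state.structure_io import Atom, Chain, Residue, StructureModel


def _two_residue_model(resname_a, atoms_a, resname_b, atoms_b, chain_b="B"):
    ra = Residue(chain_id="A", author_number=1, name=resname_a,
                 atoms=[Atom(name=n, position=np.array(p)) for n, p in atoms_a])
    rb = Residue(chain_id=chain_b, author_number=50, name=resname_b,
                 atoms=[Atom(name=n, position=np.array(p)) for n, p in atoms_b])
    chains = [Chain(chain_id="A", residues=[ra])]
    if chain_b == "A":
        chains[0] = Chain(chain_id="A", residues=[ra, rb])
    else:
        chains.append(Chain(chain_id=chain_b, residues=[rb]))
    model = StructureModel(label="pairtest", chains=chains)
    ca = model.chains[0]
    cb = model.chains[-1]
    group_a = [(ca, ra, a) for a in ra.atoms]
    group_b = [(cb, rb, a) for a in rb.atoms]
    return model, group_a, group_b


class TestFindContacts:
    def test_distant_atoms_give_empty_list(self, criteria):
        model, ga, gb = _two_residue_model(
            "ASN", [("ND2", (0, 0, 0))], "ASP", [("OD1", (10, 0, 0))])
        assert b1.find_contacts(model, criteria, ga, gb) == []

    def test_planted_asn_asp_pair_is_exactly_one_hbond(self, criteria):
        model, ga, gb = _two_residue_model(
            "ASN", [("ND2", (0, 0, 0))], "ASP", [("OD1", (2.9, 0, 0))])
        records = b1.find_contacts(model, criteria, ga, gb)
        assert len(records) == 1
        assert records[0].contact_type == "hbond"
        assert records[0].distance == pytest.approx(2.9)

    def test_salt_bridge_takes_priority_over_hbond(self, criteria):
        model, ga, gb = _two_residue_model(
            "ARG", [("NH1", (0, 0, 0))], "GLU", [("OE1", (3.4, 0, 0))])
        records = b1.find_contacts(model, criteria, ga, gb)
        assert [r.contact_type for r in records] == ["salt_bridge"]

    def test_sidechain_carbons_make_hydrophobic_contact(self, criteria):
        model, ga, gb = _two_residue_model(
            "LEU", [("CD1", (0, 0, 0))], "VAL", [("CG1", (4.2, 0, 0))])
        records = b1.find_contacts(model, criteria, ga, gb)
        assert [r.contact_type for r in records] == ["hydrophobic"]
        # backbone carbons never qualify
        model, ga, gb = _two_residue_model(
            "LEU", [("CA", (0, 0, 0))], "VAL", [("CA", (4.2, 0, 0))])
        assert b1.find_contacts(model, criteria, ga, gb) == []

    def test_short_sequence_separation_suppressed_within_chain(self, criteria):
        model, ga, gb = _two_residue_model(
            "ASN", [("ND2", (0, 0, 0))], "ASP", [("OD1", (2.9, 0, 0))], chain_b="A")
        gb[0][1].author_number = 3  # |3 - 1| < 4 in the same chain
        assert b1.find_contacts(model, criteria, ga, gb) == []

    def test_symmetric_in_group_order(self, criteria, emulation):
        models, _ = emulation
        model = models["glp1r_bound"]
        rec = model.receptor_chain
        ga = model.chains_by_role("Galpha")[0]
        group_r = [(rec, r, a) for r in rec.residues for a in r.heavy_atoms()]
        group_g = [(ga, r, a) for r in ga.residues for a in r.heavy_atoms()]
        fwd = b1.find_contacts(model, criteria, group_r, group_g)
        rev = b1.find_contacts(model, criteria, group_g, group_r)
        assert fwd == rev
        assert len(fwd) > 0


class TestNetworkStatus:
    def test_planted_fraction_arithmetic(self, tables, motifs):
        motif = motifs["cytoplasmic"]
        for drop, expected in (((), 1.0), ((0,), 2 / 3), ((0, 1, 2), 0.0)):
            model, _ = b1.make_network_fixture(motif, intact=True, drop_pairs=drop)
            status = b1.network_status(model, tables["GLP1R"], motif)
            assert status.fraction == pytest.approx(expected)
            assert status.intact == (expected >= 0.5)

    def test_broken_fixture_fraction_zero(self, tables, motifs):
        model, _ = b1.make_network_fixture(motifs["HETY"], intact=False)
        status = b1.network_status(model, tables["GLP1R"], motifs["HETY"])
        assert status.fraction == 0.0
        assert not status.intact

    def test_fraction_never_decreases_when_cutoffs_widen(self, tables, motifs, emulation):
        models, _ = emulation
        model = models["gipr_bound"]
        table = tables["GIPR"]
        loose = b1.ContactCriteria(hbond_max=6.0, salt_bridge_max=6.5, hydrophobic_max=7.0)
        for name in ("HETY", "cytoplasmic", "central", "PxxG"):
            tight_f = b1.network_status(model, table, motifs[name]).fraction
            loose_f = b1.network_status(model, table, motifs[name], loose).fraction
            assert loose_f >= tight_f

    def test_emulation_set_network_truth(self, tables, motifs, emulation):
        models, truth = emulation
        for label, expected in truth.network_fractions.items():
            receptor = label.split("_")[0].upper()
            for motif_name, fraction in expected.items():
                status = b1.network_status(
                    models[label], tables[receptor], motifs[motif_name])
                assert status.fraction == pytest.approx(fraction), (label, motif_name)


class TestSasa:
    def test_isolated_sphere_analytic(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.7]), 1.4, 960)[0]
        exact = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.02)

    def test_two_sphere_overlap_against_fine_refinement(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        radii = np.array([1.70, 1.52])
        coarse = shrake_rupley(coords, radii, 1.4, 960).sum()
        fine = shrake_rupley(coords, radii, 1.4, 10000).sum()
        assert coarse == pytest.approx(fine, rel=0.03)

    def test_buried_area_symmetric_and_zero_when_distant(self, emulation):
        models, _ = emulation
        model = models["glp1r_ligand_free"]
        rec = model.receptor_chain
        ga = model.chains_by_role("Galpha")[0]
        group_r = [(rec, r, a) for r in rec.residues[:40] for a in r.atoms]
        group_g = [(ga, r, a) for r in ga.residues for a in r.atoms]
        ab = b1.buried_area(model, group_r, group_g, sphere_points=240)
        ba = b1.buried_area(model, group_g, group_r, sphere_points=240)
        assert ab == pytest.approx(ba, abs=1e-9)
        far = [(ga, r, Atom(name=a.name, position=a.position + 500.0))
               for _, r, a in group_g]
        assert b1.buried_area(model, group_r, far, sphere_points=240) == 0.0


class TestInterfaceSummary:
    def test_receptor_only_model_raises(self, criteria, emulation):
        models, _ = emulation
        with pytest.raises(RoleAssignmentError):
            b1.interface_summary(models["glp1r_inactive"], criteria)

    @pytest.mark.parametrize("k", [1, 3, 6])
    def test_planted_contact_count_exact(self, criteria, tables, k):
        model, truth = b1.make_interface_fixture("GCGR", n_contacts=k)
        summary = b1.interface_summary(model, criteria, tables["GCGR"], sphere_points=240)
        assert summary.contact_count == k
        assert summary.buried_area > 0.0
        assert sum(summary.per_segment.values()) == k

    def test_bound_interface_stronger_than_ligand_free(self, criteria, tables, emulation):
        models, _ = emulation
        for rid in ("glp1r", "gcgr", "gipr"):
            free = b1.interface_summary(
                models[f"{rid}_ligand_free"], criteria, tables[rid.upper()],
                sphere_points=240)
            bound = b1.interface_summary(
                models[f"{rid}_bound"], criteria, tables[rid.upper()],
                sphere_points=240)
            assert bound.contact_count > free.contact_count
            assert bound.buried_area > free.buried_area
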