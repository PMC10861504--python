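"""Kink angles, paired displacements, cross distances, pocket overlap."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import b1state as b1
from b1state.conformetrics import angle_at_vertex
from b1state.errors import MissingAtomError, RoleAssignmentError
from b1state.superpose import Scope
from b1state.synthetic import BundleSpec, DisplacementOp, HelixSpec


class TestKinkAngle:
    def test_collinear_trace_is_180(self):
        assert angle_at_vertex([0, 0, 0], [0, 0, 5], [0, 0, 10]) == pytest.approx(180.0)

    @pytest.mark.parametrize("angle", [60.0, 98.0, 120.0, 148.0, 175.0])
    def test_planted_helix_bend_recovered(self, angle):
        chain = b1.make_helix(HelixSpec(n_residues=30, kink=(15, angle)))
        pos = np.array([r.atoms[0].position for r in chain.residues])
        assert angle_at_vertex(pos[8], pos[15], pos[22]) == pytest.approx(angle, abs=1e-9)

    def test_noisy_planted_bends_recovered_within_one_degree(self):
        rng = np.random.default_rng(42)
        for seed in range(100):
            angle = float(rng.uniform(70.0, 170.0))
            chain = b1.make_helix(
                HelixSpec(n_residues=30, kink=(15, angle), noise_sigma=0.02), seed=seed
            )
            pos = np.array([r.atoms[0].position for r in chain.residues])
            measured = angle_at_vertex(pos[8], pos[15], pos[22])
            assert measured == pytest.approx(angle, abs=1.0)

    def test_invariant_under_rigid_motion(self, tables, emulation):
        models, _ = emulation
        model = models["gipr_ligand_free"]
        table = tables["GIPR"]
        base = b1.kink_angle(model, table).angle_deg
        for seed in range(5):
            R = Rotation.random(random_state=seed).as_matrix()
            moved = model.transformed(R, np.array([seed * 3.0, -seed * 1.0, 2.0]))
            assert b1.kink_angle(moved, table).angle_deg == pytest.approx(base, abs=1e-6)

    def test_planted_paper_angles(self, tables, emulation):
        models, truth = emulation
        for label, planted in truth.kink_angles.items():
            receptor = label.split("_")[0].upper()
            measured = b1.kink_angle(models[label], tables[receptor]).angle_deg
            assert measured == pytest.approx(planted, abs=1e-6)

    def test_missing_ca_names_the_residue(self, tables, emulation):
        models, _ = emulation
        pruned = models["glp1r_inactive"].copy()
        chain = pruned.receptor_chain
        chain.residues = [r for r in chain.residues if r.author_number != 358]
        with pytest.raises(MissingAtomError, match="358"):
            b1.kink_angle(pruned, tables["GLP1R"])


class TestPairedDisplacement:
    def test_zero_against_itself(self, tables, emulation):
        models, _ = emulation
        m = models["gcgr_inactive"]
        d = b1.paired_displacement(m, m, tables["GCGR"], "6.37b")
        assert d.distance == pytest.approx(0.0, abs=1e-9)

    def test_single_translated_helix_with_frozen_scope(self, tables):
        a, b, truth = b1.make_state_pair(
            BundleSpec("GLP1R"), [DisplacementOp("TM6", "whole", 5.0, "out")]
        )
        scope = Scope("frozen", truth.displacements[0]["scope_segments"])
        d = b1.paired_displacement(a, b, tables["GLP1R"], "6.37b", scope=scope)
        assert d.distance == pytest.approx(5.0, abs=0.1)

    def test_symmetric_in_model_order(self, tables, emulation):
        models, _ = emulation
        scope = Scope("frozen", ["TM1", "TM2", "TM3", "TM4", "TM5", "TM7"])
        fwd = b1.paired_displacement(
            models["glp1r_inactive"], models["glp1r_ligand_free"],
            tables["GLP1R"], "6.37b", scope=scope)
        rev = b1.paired_displacement(
            models["glp1r_ligand_free"], models["glp1r_inactive"],
            tables["GLP1R"], "6.37b", scope=scope)
        assert fwd.distance == pytest.approx(rev.distance, abs=1e-6)

    def test_hundred_random_plans_recovered(self, tables):
        """Planted half/whole-helix translations recovered within 0.1 A."""
        rng = np.random.default_rng(2024)
        table = tables["GCGR"]
        for seed in range(100):
            helix = int(rng.integers(1, 8))
            part = ("whole", "ec", "ic")[int(rng.integers(3))]
            magnitude = float(rng.uniform(2.0, 15.0))
            op = DisplacementOp(f"TM{helix}", part, magnitude,
                                ("out", "in")[int(rng.integers(2))])
            a, b, truth = b1.make_state_pair(BundleSpec("GCGR"), [op], seed=seed)
            row = truth.displacements[len(truth.displacements) // 2]
            scope = Scope("frozen", row["scope_segments"])
            d = b1.paired_displacement(a, b, table, row["position"], scope=scope)
            assert d.distance == pytest.approx(row["distance"], abs=0.1)

    def test_planted_paper_displacements(self, tables, emulation):
        models, truth = emulation
        for row in truth.displacements:
            mobile, reference = row["pair"]
            receptor = mobile.split("_")[0].upper()
            scope = Scope("frozen", row["scope_segments"])
            d = b1.paired_displacement(
                models[mobile], models[reference], tables[receptor],
                row["position"], scope=scope)
            assert d.distance == pytest.approx(row["distance"], abs=1e-6), row


class TestCrossStructureDistance:
    def test_same_residue_same_model_zero(self, tables, emulation):
        models, _ = emulation
        m = models["gipr_inactive"]
        d = b1.cross_structure_distance(m, m, tables["GIPR"], "6.59b", "6.59b")
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_planted_cross_receptor_tip_separations(self, tables, emulation):
        models, truth = emulation
        for row in truth.cross_distances:
            a, b = row["pair"]
            ra, rb = a.split("_")[0].upper(), b.split("_")[0].upper()
            scope = Scope("trio", row["scope_segments"])
            d = b1.cross_structure_distance(
                models[a], models[b], tables[ra],
                row["positions"][0], row["positions"][1],
                scope=scope, table_b=tables[rb])
            assert d == pytest.approx(row["distance"], abs=0.1)


class TestPocketOverlap:
    SCOPE = Scope("TM2-5", ["TM2", "TM3", "TM4", "TM5"])

    def test_loop_far_from_peptide_counts_zero(self, tables, emulation):
        models, _ = emulation
        ov = b1.pocket_overlap(
            models["glp1r_bound"], models["glp1r_bound"], tables["GLP1R"],
            "ECL2", scope=self.SCOPE)
        assert ov.count == 0

    def test_planted_occupancy_matches_truth(self, tables, emulation):
        models, truth = emulation
        for key, expected in truth.overlaps.items():
            label, loop = key.split(":")
            receptor = label.split("_")[0].upper()
            holo = f"{receptor.lower()}_bound"
            ov = b1.pocket_overlap(
                models[label], models[holo], tables[receptor], loop, scope=self.SCOPE)
            assert ov.count == expected, key
            assert ov.count <= ov.total_loop_atoms

    def test_monotone_in_cutoff(self, tables, emulation):
        models, _ = emulation
        counts = [
            b1.pocket_overlap(
                models["gcgr_ligand_free"], models["gcgr_bound"], tables["GCGR"],
                "ECL2", cutoff=c, scope=self.SCOPE).count
            for c in (2.0, 4.5, 8.0, 15.0)
        ]
        assert counts == sorted(counts)

    def test_holo_without_peptide_raises(self, tables, emulation):
        models, _ = emulation
        with pytest.raises(RoleAssignmentError):
            b1.pocket_overlap(
                models["gcgr_ligand_free"], models["gcgr_inactive"],
                tables["GCGR"], "ECL2", scope=self.SCOPE)
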