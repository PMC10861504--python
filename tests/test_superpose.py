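"""Kabsch superposition and RMSD against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.transform import Rotation

import b1state as b1
from b1state.errors import CorrespondenceError, DegenerateGeometryError
from b1state.networks import fibonacci_sphere
from b1state.superpose import Scope, kabsch, rmsd, superpose_models


def _cloud(rng, n=12, spread=8.0):
    return rng.normal(0.0, spread, (n, 3))


class TestRmsd:
    def test_identical_sets_zero(self):
        rng = np.random.default_rng(0)
        P = _cloud(rng)
        assert rmsd(P, P) == 0.0

    def test_uniform_translation_closed_form(self):
        rng = np.random.default_rng(1)
        P = _cloud(rng)
        assert rmsd(P, P + np.array([3.0, 0.0, 0.0])) == pytest.approx(3.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        P, Q = _cloud(rng), _cloud(rng)
        direct = np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1)))
        assert rmsd(P, Q) == pytest.approx(direct, abs=1e-9)

    def test_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        arrays(float, (6, 3), elements=st.floats(-50, 50)),
        arrays(float, (6, 3), elements=st.floats(-50, 50)),
        arrays(float, (3,), elements=st.floats(-20, 20)),
    )
    def test_symmetric_and_translation_equivariant(self, P, Q, t):
        assert rmsd(P, Q) == pytest.approx(rmsd(Q, P), abs=1e-9)
        assert rmsd(P + t, Q + t) == pytest.approx(rmsd(P, Q), abs=1e-7)


class TestKabsch:
    def test_identity_on_equal_sets(self):
        rng = np.random.default_rng(3)
        P = _cloud(rng)
        t = kabsch(P, P)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)
        assert rmsd(t.apply(P), P) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_planted_rotation(self, seed):
        rng = np.random.default_rng(seed)
        Q = _cloud(rng)
        planted = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        shift = rng.normal(0, 5.0, 3)
        P = Q @ planted.T + shift  # P = R_p Q + s
        t = kabsch(P, Q)  # should invert the planted motion
        np.testing.assert_allclose(t.rotation, planted.T, atol=1e-6)
        assert rmsd(t.apply(P), Q) == pytest.approx(0.0, abs=1e-8)

    def test_brute_force_rotation_grid_oracle(self):
        """On a 4-point pair, the fitted RMSD is not beaten by an
        exhaustive rotation search (Fibonacci axes x 2-degree angles)."""
        rng = np.random.default_rng(7)
        P = _cloud(rng, n=4)
        Q = _cloud(rng, n=4)
        t = kabsch(P, Q)
        fitted = rmsd(t.apply(P), Q)

        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        axes = fibonacci_sphere(300)
        angles = np.radians(np.arange(0.0, 360.0, 2.0))
        best = np.inf
        for axis in axes:
            rots = Rotation.from_rotvec(np.outer(angles, axis))
            for R in rots.as_matrix():
                best = min(best, rmsd(Pc @ R.T, Qc))
        assert fitted <= best + 1e-12
        # the grid gets within its angular resolution of the optimum
        assert best - fitted < 0.15

    def test_forward_and_reverse_are_mutually_inverse(self):
        rng = np.random.default_rng(11)
        P, Q = _cloud(rng), _cloud(rng)
        fwd = kabsch(P, Q)
        rev = kabsch(Q, P)
        np.testing.assert_allclose(fwd.rotation @ rev.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(rev.apply(fwd.apply(P)), P, atol=1e-6)

    def test_rmsd_after_fit_never_exceeds_before(self):
        rng = np.random.default_rng(13)
        for seed in range(10):
            local = np.random.default_rng(seed)
            Q = _cloud(local)
            R = Rotation.random(random_state=seed).as_matrix()
            P = Q @ R.T + local.normal(0, 2.0, 3) + local.normal(0, 0.3, Q.shape)
            t = kabsch(P, Q)
            assert rmsd(t.apply(P), Q) <= rmsd(P, Q) + 1e-12

    def test_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(17)
        P, Q = _cloud(rng), _cloud(rng)
        base = rmsd(kabsch(P, Q).apply(P), Q)
        R = Rotation.random(random_state=99).as_matrix()
        s = np.array([4.0, -2.0, 7.0])
        P2, Q2 = P @ R.T + s, Q @ R.T + s
        moved = rmsd(kabsch(P2, Q2).apply(P2), Q2)
        assert moved == pytest.approx(base, abs=1e-9)

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(19)
        P, Q = _cloud(rng), _cloud(rng)
        t = kabsch(P, Q)
        ours = rmsd(t.apply(P), Q)
        rot, _ = Rotation.align_vectors(Q - Q.mean(axis=0), P - P.mean(axis=0))
        theirs = rmsd(rot.apply(P - P.mean(axis=0)), Q - Q.mean(axis=0))
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_too_few_or_collinear_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(DegenerateGeometryError):
            kabsch(line, line)


class TestSuperposeModels:
    def test_model_vs_itself_zero_rmsd(self, tables, emulation):
        models, _ = emulation
        m = models["glp1r_inactive"]
        _, result = superpose_models(m, m, Scope(), tables["GLP1R"])
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert result.atom_count >= 100
        assert result.scope_name == "TMD Ca"
        assert len(result.matched) == result.atom_count

    def test_recovers_planted_rigid_motion_of_bundle(self, tables):
        model = b1.make_bundle(b1.BundleSpec("GIPR"))
        R = Rotation.from_euler("xyz", [20.0, -35.0, 60.0], degrees=True).as_matrix()
        moved = model.transformed(R, np.array([5.0, -3.0, 8.0]))
        fitted, result = superpose_models(moved, model, Scope(), tables["GIPR"])
        assert result.rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(result.transform.rotation, R.T, atol=1e-8)

    def test_cross_receptor_generic_matching(self, tables, emulation):
        models, _ = emulation
        _, result = superpose_models(
            models["glp1r_inactive"], models["gipr_inactive"],
            Scope(), tables["GLP1R"], tables["GIPR"],
        )
        # base bundles coincide at matched generic positions by construction
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_correspondence_raises(self, tables, emulation):
        models, _ = emulation
        pruned = models["glp1r_inactive"].copy()
        chain = pruned.receptor_chain
        chain.residues = [r for r in chain.residues if r.author_number > 990]
        chain.residues.append(
            models["glp1r_inactive"].receptor_chain.residues[0]
        )
        with pytest.raises(CorrespondenceError):
            superpose_models(pruned, models["glp1r_inactive"], Scope(), tables["GLP1R"])
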