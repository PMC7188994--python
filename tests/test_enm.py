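"""Elastic-network model: Hessian, zero modes and directional scores."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import saxsemble as sx
from saxsemble.enm import anm_hessian
from saxsemble.errors import ConnectivityError, DegenerateGeometryError


def cloud(seed, n=10, scale=8.0):
    return np.random.default_rng(seed).normal(scale=scale, size=(n, 3))


class TestBuildEnm:
    def test_two_close_nodes_have_one_contact(self):
        model = sx.build_enm(np.array([[0.0, 0, 0], [5.0, 0, 0]]), cutoff=12)
        assert model.contact_pairs == ((0, 1),)

    def test_two_far_nodes_have_no_contacts_and_are_disconnected(self):
        model = sx.build_enm(np.array([[0.0, 0, 0], [15.0, 0, 0]]), cutoff=12)
        assert model.contact_pairs == ()
        with pytest.raises(ConnectivityError):
            sx.compute_modes(model)

    def test_contact_count_matches_brute_force(self):
        pts = cloud(101, 12)
        model = sx.build_enm(pts, cutoff=10.0)
        brute = sum(
            1
            for j in range(12)
            for k in range(j + 1, 12)
            if np.linalg.norm(pts[j] - pts[k]) <= 10.0
        )
        assert len(model.contact_pairs) == brute
        for j, k in model.contact_pairs:
            assert np.linalg.norm(pts[j] - pts[k]) <= 10.0

    def test_collinear_nodes_rejected(self):
        line = np.outer(np.arange(4.0), [1.0, 1.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            sx.build_enm(line, cutoff=12)


class TestComputeModes:
    def test_two_node_analytic_eigensystem(self):
        # nodes on x: one stretch mode with eigenvalue 2γ, five rigid modes
        gamma = 1.7
        model = sx.build_enm(
            np.array([[0.0, 0, 0], [5.0, 0, 0]]), cutoff=12, gamma=gamma
        )
        modes = sx.compute_modes(model)
        assert modes.n_zero_modes == 5
        nonzero = modes.eigenvalues[modes.n_zero_modes:]
        assert nonzero.size == 1
        assert nonzero[0] == pytest.approx(2.0 * gamma, rel=1e-10)
        stretch = modes.eigenvectors[:, -1].reshape(2, 3)
        # antisymmetric displacement along the bond axis
        np.testing.assert_allclose(stretch[0], -stretch[1], atol=1e-10)
        np.testing.assert_allclose(stretch[:, 1:], 0.0, atol=1e-10)

    def test_connected_network_has_exactly_six_zero_modes(self):
        model = sx.build_enm(cloud(102, 15, scale=4.0), cutoff=15.0)
        modes = sx.compute_modes(model)
        assert modes.n_zero_modes == 6

    def test_hessian_symmetric_and_psd(self):
        model = sx.build_enm(cloud(103, 10, scale=4.0), cutoff=15.0)
        h = anm_hessian(model)
        np.testing.assert_allclose(h, h.T, atol=1e-12)
        evals = np.linalg.eigvalsh(h)
        assert evals.min() > -1e-10 * max(evals.max(), 1.0)

    def test_hessian_matches_finite_difference_of_spring_energy(self):
        """Independent oracle: numerical second derivatives of
        E = Σ (γ/2)(|r_jk| − |r⁰_jk|)² over the contact springs."""
        pts = cloud(104, 6, scale=3.0)
        model = sx.build_enm(pts, cutoff=12.0, gamma=1.3)

        def energy(flat):
            x = flat.reshape(-1, 3)
            e = 0.0
            for j, k in model.contact_pairs:
                r0 = np.linalg.norm(pts[j] - pts[k])
                r = np.linalg.norm(x[j] - x[k])
                e += 0.5 * model.gamma * (r - r0) ** 2
            return e

        n = pts.size
        h_num = np.zeros((n, n))
        eps = 1e-5
        flat0 = pts.ravel()
        for a in range(n):
            for b in range(n):
                pp = flat0.copy(); pp[a] += eps; pp[b] += eps
                pm = flat0.copy(); pm[a] += eps; pm[b] -= eps
                mp = flat0.copy(); mp[a] -= eps; mp[b] += eps
                mm = flat0.copy(); mm[a] -= eps; mm[b] -= eps
                h_num[a, b] = (
                    energy(pp) - energy(pm) - energy(mp) + energy(mm)
                ) / (4 * eps**2)
        np.testing.assert_allclose(anm_hessian(model), h_num, atol=1e-4)

    def test_spectrum_invariant_under_rigid_motion(self):
        pts = cloud(105, 12, scale=4.0)
        rot = Rotation.random(rng=np.random.RandomState(2)).as_matrix()
        moved = pts @ rot.T + np.array([7.0, -3.0, 1.0])
        e1 = sx.compute_modes(sx.build_enm(pts, cutoff=15.0)).eigenvalues
        e2 = sx.compute_modes(sx.build_enm(moved, cutoff=15.0)).eigenvalues
        np.testing.assert_allclose(e1, e2, atol=1e-8 * max(e1.max(), 1.0))


class TestDirectionalScore:
    def test_cosine_one_when_displacement_points_at_target(self):
        model = sx.build_enm(
            np.array([[0.0, 0, 0], [5.0, 0, 0], [2.5, 4.0, 0.0]]), cutoff=12
        )
        modes = sx.compute_modes(model)
        # synthesise a mode displacing node 0 straight at the target
        vec = np.zeros(9)
        vec[0:3] = [1.0, 0.0, 0.0]
        fake = sx.ENMModes(
            eigenvalues=np.append(modes.eigenvalues, 1.0),
            eigenvectors=np.column_stack([modes.eigenvectors, vec]),
            n_zero_modes=modes.n_zero_modes,
        )
        score = sx.directional_motion_score(
            fake, model, 0, np.array([10.0, 0.0, 0.0]),
            mode_rank=fake.eigenvalues.size,
        )
        assert score.cosine == pytest.approx(1.0)

    def test_orthogonal_displacement_scores_zero(self):
        model = sx.build_enm(
            np.array([[0.0, 0, 0], [5.0, 0, 0], [2.5, 4.0, 0.0]]), cutoff=12
        )
        modes = sx.compute_modes(model)
        vec = np.zeros(9)
        vec[0:3] = [0.0, 0.0, 1.0]
        fake = sx.ENMModes(
            eigenvalues=np.append(modes.eigenvalues, 1.0),
            eigenvectors=np.column_stack([modes.eigenvectors, vec]),
            n_zero_modes=modes.n_zero_modes,
        )
        score = sx.directional_motion_score(
            fake, model, 0, np.array([10.0, 0.0, 0.0]),
            mode_rank=fake.eigenvalues.size,
        )
        assert score.cosine == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_orients_toward_target(self, hinge_states):
        s = hinge_states[1]
        model = sx.build_enm(s, cutoff=12.0)
        modes = sx.compute_modes(model, n_modes=3)
        ca = s.select(sx.CA_SELECTOR)
        cat = s.select(sx.AtomSelector(residue_names="CAT"))
        sub = s.select(sx.AtomSelector(residue_names="SUB"))
        node = int(np.argmin(np.linalg.norm(ca.coords - cat.coords[0], axis=1)))
        score = sx.directional_motion_score(
            modes, model, node, sub.coords[0], mode_rank=7
        )
        assert score.cosine >= 0.0
        assert score.cosine == abs(score.raw_cosine)
        assert score.abs_cosine <= 1.0

    @pytest.mark.parametrize("cutoff", [10.0, 12.0, 15.0])
    def test_hinge_tip_moves_toward_opposite_lobe(self, cutoff):
        """Mode 7 of a two-lobe hinge closes it: the catalytic-marker tip
        node moves toward the substrate marker under the oriented sign."""
        s = sx.make_hinge_protein(20, 110.0)
        model = sx.build_enm(s, cutoff=cutoff)
        modes = sx.compute_modes(model, n_modes=3)
        ca = s.select(sx.CA_SELECTOR)
        cat = s.select(sx.AtomSelector(residue_names="CAT"))
        sub = s.select(sx.AtomSelector(residue_names="SUB"))
        node = int(np.argmin(np.linalg.norm(ca.coords - cat.coords[0], axis=1)))
        score = sx.directional_motion_score(
            modes, model, node, sub.coords[0], mode_rank=7
        )
        assert score.cosine > 0.0
        assert score.amplitude > 0.0

    def test_mode_animation_round_trips_through_pdb(self, tmp_path):
        s = sx.make_hinge_protein(12, 110.0)
        model = sx.build_enm(s, cutoff=12.0)
        modes = sx.compute_modes(model, n_modes=3)
        movie = sx.animate_mode(s, modes, mode_rank=7, amplitude=2.0,
                                n_frames=5)
        assert len(movie) == 5
        # extreme frames are symmetric about the input trace
        mid = movie[2].coords
        np.testing.assert_allclose(
            movie[0].coords + movie[4].coords, 2 * mid, atol=1e-9
        )
        path = tmp_path / "mode7.pdb"
        sx.write_ensemble(movie, path)
        back = sx.read_structure(path, model_index="all")
        assert len(back) == 5

    def test_mode_rank_inside_zero_modes_rejected(self):
        model = sx.build_enm(cloud(106, 8, scale=4.0), cutoff=15.0)
        modes = sx.compute_modes(model)
        with pytest.raises(ValueError):
            sx.directional_motion_score(
                modes, model, 0, np.zeros(3), mode_rank=6
            )
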