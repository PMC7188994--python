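"""Debye profiles, curve I/O, trimming, cluster averages and χ²."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import saxsemble as sx
from saxsemble.errors import (
    CurveFormatError,
    EmptyRangeError,
    MissingSigmaError,
)
from saxsemble.saxs import RESIDUE_HEAVY_ATOMS


def bead_structure(coords, resname="GLY"):
    return sx.Structure.from_coords(np.asarray(coords, dtype=float),
                                    residue_name=resname)


class TestDebyeProfile:
    def test_single_bead_profile_is_flat_self_term(self):
        s = bead_structure([[0.0, 0.0, 0.0]])
        q = np.array([0.01, 0.1, 0.3])
        curve = sx.debye_profile(s, q)
        f = RESIDUE_HEAVY_ATOMS["GLY"]
        np.testing.assert_allclose(curve.intensity, f**2)

    def test_two_bead_closed_form(self):
        # per unit form factor: I/f² = 2 + 2·sin(qr)/(qr), q·r = 0.38
        s = bead_structure([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]])
        curve = sx.debye_profile(s, np.array([0.1]))
        f = RESIDUE_HEAVY_ATOMS["GLY"]
        expected_unit = 2.0 + 2.0 * np.sin(0.38) / 0.38
        assert curve.intensity[0] / f**2 == pytest.approx(expected_unit, abs=1e-9)
        assert expected_unit == pytest.approx(3.952213, abs=1e-6)

    def test_uniform_sphere_tracks_analytic_form_factor(self):
        rng = np.random.default_rng(12)
        radius = 30.0
        pts = rng.normal(size=(1000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= radius * rng.random(1000)[:, None] ** (1.0 / 3.0)
        s = bead_structure(pts)
        q = np.linspace(0.01, 3.0 / radius, 40)
        curve = sx.debye_profile(s, q)
        x = q * radius
        analytic = (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
        rel = np.abs(curve.intensity / curve.intensity[0] - analytic) / analytic
        assert np.max(rel) < 0.05

    def test_rigid_motion_invariance(self, hinge_states):
        s = hinge_states[0]
        rot = Rotation.random(rng=np.random.RandomState(5)).as_matrix()
        moved = s.with_coords(s.coords @ rot.T + np.array([10.0, -4.0, 2.0]))
        q = sx.default_q_grid(20)
        a = sx.debye_profile(s, q)
        b = sx.debye_profile(moved, q)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-9)

    def test_forward_limit_is_total_scattering_squared(self, hinge_states):
        from saxsemble.saxs import _residue_beads

        _, f = _residue_beads(hinge_states[0])
        tiny_q = np.array([1e-6])
        curve = sx.debye_profile(hinge_states[0], tiny_q)
        assert curve.intensity[0] == pytest.approx(f.sum() ** 2, rel=1e-6)

    def test_intensity_positive(self, hinge_states):
        curve = sx.debye_profile(hinge_states[1], sx.default_q_grid(50))
        assert np.all(curve.intensity > 0)

    def test_all_atom_representation_uses_atomic_numbers(self):
        s = sx.Structure.from_coords(
            np.array([[0.0, 0.0, 0.0]]), atom_name="SG", element="S",
            residue_name="CYS",
        )
        curve = sx.debye_profile(s, np.array([0.1]), "all-atom-constant-f")
        assert curve.intensity[0] == pytest.approx(16.0**2)

    def test_rejects_nonpositive_q(self, hinge_states):
        with pytest.raises(ValueError):
            sx.debye_profile(hinge_states[0], np.array([0.0, 0.1]))


class TestCurveIO:
    def test_three_column_file_echoes_values(self, tmp_path):
        p = tmp_path / "c.dat"
        p.write_text("0.01 10.0 0.1\n0.02 9.0 0.1\n0.03 8.5 0.2\n")
        curve = sx.read_saxs_curve(p)
        assert len(curve) == 3
        np.testing.assert_allclose(curve.q, [0.01, 0.02, 0.03])
        np.testing.assert_allclose(curve.sigma, [0.1, 0.1, 0.2])

    def test_header_lines_skipped(self, tmp_path):
        p = tmp_path / "h.dat"
        p.write_text(
            "Sample description\n q(A-1)  I  sigma\n0.01 10.0 0.1\n0.02 9.0 0.1\n"
        )
        curve = sx.read_saxs_curve(p)
        assert len(curve) == 2

    def test_two_column_file_has_no_sigma_and_chi2_refuses(self, tmp_path):
        p = tmp_path / "t.dat"
        p.write_text("0.01 10.0\n0.02 9.0\n")
        curve = sx.read_saxs_curve(p)
        assert curve.sigma is None
        with pytest.raises(MissingSigmaError):
            sx.chi_square(curve, curve)

    def test_unusable_file_raises(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text("no numbers here\nstill none\n")
        with pytest.raises(CurveFormatError):
            sx.read_saxs_curve(p)

    def test_write_read_round_trip(self, tmp_path, hinge_states):
        curve = sx.debye_profile(hinge_states[0], sx.default_q_grid(10))
        p = tmp_path / "rt.dat"
        sx.write_saxs_curve(curve, p, header="model")
        back = sx.read_saxs_curve(p)
        np.testing.assert_allclose(back.q, curve.q, rtol=1e-6)
        np.testing.assert_allclose(back.intensity, curve.intensity, rtol=1e-6)


class TestTrim:
    def test_trims_to_usable_range_inclusive(self):
        q = np.linspace(0.005, 0.35, 70)
        curve = sx.ScatteringCurve(q=q, intensity=np.ones_like(q))
        trimmed = sx.trim_curve(curve, 0.01, 0.2)
        assert trimmed.q.min() >= 0.01
        assert trimmed.q.max() <= 0.2
        assert len(trimmed) == np.sum((q >= 0.01) & (q <= 0.2))

    def test_wide_trim_keeps_curve(self):
        q = np.linspace(0.05, 0.1, 10)
        curve = sx.ScatteringCurve(q=q, intensity=np.ones_like(q))
        assert len(sx.trim_curve(curve, 0.001, 1.0)) == 10

    def test_empty_range_raises(self):
        q = np.linspace(0.05, 0.1, 10)
        curve = sx.ScatteringCurve(q=q, intensity=np.ones_like(q))
        with pytest.raises(EmptyRangeError):
            sx.trim_curve(curve, 0.2, 0.3)


class TestClusterAverages:
    def test_identical_frames_average_to_member_profile(self, hinge_states):
        ens = sx.Ensemble([hinge_states[0]] * 5)
        clusters = sx.cluster_ensemble(ens, cutoff=1.5)
        q = sx.default_q_grid(15)
        profiles = sx.average_cluster_profiles(ens, clusters, q)
        member = sx.debye_profile(hinge_states[0], q)
        np.testing.assert_allclose(
            profiles.profiles[0].intensity, member.intensity, rtol=1e-12
        )

    def test_average_is_arithmetic_mean(self, hinge_states):
        ens = sx.Ensemble(hinge_states[:2])
        labels = np.zeros(2, dtype=int)
        clusters = sx.ClusterResult(
            labels=labels, n_clusters=1, populations=np.array([1.0]),
            medoid_frames=np.array([0]), cutoff=1.5,
        )
        q = sx.default_q_grid(10)
        profiles = sx.average_cluster_profiles(ens, clusters, q)
        i1 = sx.debye_profile(hinge_states[0], q).intensity
        i2 = sx.debye_profile(hinge_states[1], q).intensity
        np.testing.assert_allclose(
            profiles.profiles[0].intensity, (i1 + i2) / 2.0, rtol=1e-12
        )

    def test_cluster_averages_match_state_profiles(self, small_planted_ensemble):
        ens, truth = small_planted_ensemble
        clusters = sx.cluster_ensemble(ens, cutoff=1.5)
        q = sx.default_q_grid(30)
        profiles = sx.average_cluster_profiles(ens, clusters, q)
        state_profiles = [
            sx.debye_profile(s, q) for s in truth.state_structures
        ]
        # match clusters to states through the planted labels
        for c in range(clusters.n_clusters):
            state = truth.frame_labels[clusters.frames_of(c)[0]]
            np.testing.assert_allclose(
                profiles.profiles[c].intensity,
                state_profiles[state].intensity,
                rtol=0.02,
            )


class TestChiSquare:
    def test_model_equal_experiment_gives_zero(self):
        q = np.linspace(0.01, 0.2, 10)
        exp = sx.ScatteringCurve(q=q, intensity=np.ones(10), sigma=np.ones(10))
        model = sx.ScatteringCurve(q=q, intensity=np.ones(10))
        assert sx.chi_square(model, exp) == 0.0

    def test_unit_residuals_hand_example(self):
        # L = 3, residual = σ at every point → χ² = 3 / (3−1) = 1.5
        q = np.array([0.01, 0.02, 0.03])
        exp = sx.ScatteringCurve(
            q=q, intensity=np.array([1.0, 2.0, 3.0]),
            sigma=np.array([0.5, 0.5, 0.5]),
        )
        model = sx.ScatteringCurve(q=q, intensity=exp.intensity + 0.5)
        assert sx.chi_square(model, exp) == pytest.approx(1.5, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_scaling_residuals_and_sigma_leaves_chi2(self, scale):
        q = np.linspace(0.01, 0.2, 8)
        local = np.random.default_rng(0)
        base = 10.0 + local.random(8)
        sigma = 0.1 + local.random(8)
        exp1 = sx.ScatteringCurve(q=q, intensity=base, sigma=sigma)
        model1 = sx.ScatteringCurve(q=q, intensity=base + sigma * 0.7)
        exp2 = sx.ScatteringCurve(q=q, intensity=base, sigma=sigma * scale)
        model2 = sx.ScatteringCurve(q=q, intensity=base + sigma * scale * 0.7)
        assert sx.chi_square(model1, exp1) == pytest.approx(
            sx.chi_square(model2, exp2), rel=1e-9
        )

    def test_mismatched_grids_require_resampling(self):
        exp = sx.ScatteringCurve(
            q=np.linspace(0.01, 0.2, 10), intensity=np.ones(10),
            sigma=np.ones(10),
        )
        model = sx.ScatteringCurve(
            q=np.linspace(0.01, 0.2, 20), intensity=np.ones(20)
        )
        with pytest.raises(ValueError):
            sx.chi_square(model, exp)
        assert sx.chi_square(model.resample_to(exp.q), exp) == 0.0
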