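"""Loop metrics: alignment, opening angle, distances, helicity, tau."""

import numpy as np
import pytest

from aaadyn.loop_geometry import (ThetaDefinition, align_principal_axis_z,
                                  correlation_time, helical_content,
                                  integrated_tau, kabsch_sander_hbonds,
                                  min_distance, opening_angle,
                                  opening_angle_series)
from aaadyn.synthetic_data import gen_ideal_helix
from aaadyn.trajectory_io import FrameEnsemble

from conftest import make_ensemble


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


class TestAlignment:
    def test_rod_along_x_rotates_to_z(self):
        coords = np.column_stack([np.linspace(0, 10, 11),
                                  np.zeros(11), np.zeros(11)])
        coords += np.random.default_rng(0).normal(0, 0.01, coords.shape)
        ens = make_ensemble(coords, box=(30, 30, 30))
        out = align_principal_axis_z(ens, list(range(11)))
        c = out.frames[0]
        assert np.abs(c[:, :2]).max() < 0.1  # x, y collapsed
        assert np.allclose(c.mean(axis=0), 0, atol=1e-9)

    def test_z_rod_is_fixed_point(self):
        coords = np.column_stack([np.zeros(5), np.zeros(5),
                                  np.linspace(-4, 4, 5)])
        coords += np.random.default_rng(1).normal(0, 0.01, coords.shape)
        ens = make_ensemble(coords, box=(30, 30, 30))
        out = align_principal_axis_z(ens, list(range(5)))
        expected = coords[:, 2] - coords[:, 2].mean()
        got = out.frames[0][:, 2]
        # identity up to the sign convention for a symmetric rod
        err = min(np.abs(got - expected).max(), np.abs(got + expected).max())
        assert err < 0.05

    def test_random_rigid_rotations_align_identically(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(-5, 5, size=(12, 3))
        base[:, 2] *= 4  # make z clearly the longest axis
        frames = []
        for _ in range(6):
            ax = rng.normal(size=3)
            R = _rotation(ax, rng.uniform(0, 2 * np.pi))
            frames.append(base @ R.T + rng.uniform(-3, 3, 3))
        ens = FrameEnsemble(make_ensemble(base).atoms, np.stack(frames),
                            np.full(3, 60.0))
        out = align_principal_axis_z(ens, list(range(12)))
        for fi in range(1, 6):
            np.testing.assert_allclose(out.frames[fi], out.frames[0],
                                       atol=1e-6)

    def test_degenerate_selection_raises(self):
        ens = make_ensemble(np.zeros((4, 3)), box=(10, 10, 10))
        with pytest.raises(ValueError):
            align_principal_axis_z(ens, [0, 1, 2, 3])


class TestOpeningAngle:
    def _theta(self, anchor, tip, zref):
        td = ThetaDefinition(reference_center=np.array([9., 9., zref]))
        return opening_angle(None, np.asarray(anchor, float),
                             np.asarray(tip, float), td)

    def test_parallel_vectors_zero(self):
        # anchor at origin; tip along +z; reference center above the anchor
        assert self._theta([0, 0, 0], [0, 0, 5], 7.0) == pytest.approx(0.0)

    def test_perpendicular_vectors_ninety(self):
        assert self._theta([0, 0, 0], [3, 0, 0], 7.0) == pytest.approx(90.0)

    def test_arbitrary_known_angle(self):
        # v1 = (1,0,1)/sqrt2 vs v2 = +z: 45 degrees
        assert self._theta([0, 0, 0], [2, 0, 2], 5.0) == pytest.approx(45.0)

    def test_zero_length_vector_raises(self):
        with pytest.raises(ValueError):
            self._theta([0, 0, 3], [0, 0, 3], 3.0)

    def test_requires_reference_center(self):
        td = ThetaDefinition()
        with pytest.raises(ValueError, match="reference center"):
            opening_angle(None, np.zeros(3), np.ones(3), td)

    def test_rigid_motion_absorbed_by_alignment(self):
        # theta computed after alignment is invariant to pre-rotation
        from aaadyn.synthetic_data import LoopTrajSpec, gen_loop_trajectory
        ens, _ = gen_loop_trajectory(LoopTrajSpec(n_frames=5, seed=3))
        td = ThetaDefinition(
            tip_selection="name CA and resid 358").with_reference_from(ens)
        base = opening_angle_series(ens, td)
        R = _rotation([1, 2, 3], 0.7)
        rot = FrameEnsemble(ens.atoms, ens.frames @ R.T + 4.0,
                            ens.box, ens.frame_interval)
        al_base = align_principal_axis_z(ens, "name CA")
        al_rot = align_principal_axis_z(rot, "name CA")
        td2 = ThetaDefinition(
            tip_selection="name CA and resid 358").with_reference_from(
                al_base)
        t1 = opening_angle_series(al_base, td2)
        t2 = opening_angle_series(al_rot, td2)
        np.testing.assert_allclose(t1, t2, atol=1e-6)
        assert base.shape == t1.shape


class TestMinDistance:
    def test_two_atoms(self):
        frame = np.array([[0., 0., 0.], [3., 0., 0.]])
        assert min_distance(frame, [0], [1]) == 3.0

    def test_overlapping_groups_zero(self):
        frame = np.array([[1., 1., 1.], [2., 2., 2.]])
        assert min_distance(frame, [0, 1], [1]) == 0.0

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(4)
        frame = rng.uniform(0, 30, size=(100, 3))
        a, b = list(range(50)), list(range(50, 100))
        naive = min(np.linalg.norm(frame[i] - frame[j])
                    for i in a for j in b)
        assert min_distance(frame, a, b) == pytest.approx(naive, abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            min_distance(np.zeros((2, 3)), [], [0])


class TestHelicalContent:
    def test_ideal_alpha_helix_interior_assigned(self):
        ens = gen_ideal_helix(12, -57.0, -47.0)
        frac = helical_content(ens, (1, 12))
        assert frac >= 8 / 12

    def test_extended_chain_zero(self):
        ens = gen_ideal_helix(12, 180.0, 180.0)
        assert helical_content(ens, (1, 12)) == 0.0

    def test_two_residue_range_zero(self):
        ens = gen_ideal_helix(12, -57.0, -47.0)
        assert helical_content(ens, (1, 2)) == 0.0

    def test_mirror_image_same_content(self):
        # Kabsch-Sander energy uses distances only, so a mirrored structure
        # scores identically (documented limitation of helix-only DSSP)
        ens = gen_ideal_helix(12, -57.0, -47.0)
        mirrored = FrameEnsemble(ens.atoms, ens.frames * [1, 1, -1] + 50,
                                 ens.box, ens.frame_interval)
        assert helical_content(mirrored, (1, 12)) == helical_content(
            ens, (1, 12))

    def test_hbond_pattern_is_i_to_i_plus_4(self):
        ens = gen_ideal_helix(10, -57.0, -47.0)
        residues = [(r, {a.name: a.index for a in ens.atoms
                         if a.residue_number == r}) for r in range(1, 11)]
        hb = kabsch_sander_hbonds(ens.frames[0], residues)
        donors, acceptors = np.nonzero(hb)
        assert set(donors - acceptors) == {4}

    def test_missing_backbone_raises(self):
        ens = make_ensemble(np.zeros((1, 3)), names=["CA"],
                            resnames=["ALA"], resnums=[1])
        with pytest.raises(ValueError):
            helical_content(ens, (1, 1))


class TestCorrelationTime:
    def test_white_noise_gives_half_dt(self):
        rng = np.random.default_rng(5)
        est = correlation_time(rng.standard_normal(100000), dt=2.0)
        assert est.tau == pytest.approx(1.0, rel=0.1)

    def test_ou_series_recovers_tau(self):
        # AR(1) with known relaxation time 100 steps
        rng = np.random.default_rng(6)
        tau_true, n = 100.0, 100000
        phi = np.exp(-1 / tau_true)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eta = rng.standard_normal(n) * np.sqrt(1 - phi ** 2)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eta[t]
        est = correlation_time(x, dt=1.0)
        assert est.tau == pytest.approx(tau_true, rel=0.2)

    def test_exact_exponential_acf_quadrature(self):
        # estimator applied to an exact exponential ACF: < 2% at tau >= 10 dt
        for tau in (10.0, 30.0, 200.0):
            k = np.arange(int(50 * tau))
            rho = np.exp(-k / tau)
            est = integrated_tau(rho, dt=1.0)
            assert est.tau == pytest.approx(tau, rel=0.02)

    def test_constant_series_raises(self):
        with pytest.raises(ValueError):
            correlation_time(np.ones(1000), dt=1.0)

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            correlation_time(np.arange(10.0), dt=1.0)
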