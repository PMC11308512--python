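"""Generators: energies against hand-built oracles, determinism, geometry."""

import numpy as np
import pytest
from scipy import stats as sps

from aaadyn.constants import COULOMB
from aaadyn.synthetic_data import (CavityChannelSpec, LjFluidSpec,
                                   LoopTrajSpec, WaterBoxSpec,
                                   default_loop_endpoints, gen_cavity_channel,
                                   gen_ideal_helix, gen_lj_fluid,
                                   gen_loop_trajectory, gen_water_box,
                                   water_config_energy, water_geometry,
                                   WATER_O_EPSILON, WATER_O_RMIN_HALF,
                                   WATER_Q)


class TestWaterBox:
    def test_two_molecule_energy_hand_sum(self):
        # fixed two-molecule configuration: site-site Coulomb(+RF) + O-O LJ
        L, rc, eps_rf = 20.0, 9.0, 78.5
        geom = water_geometry()
        pos = np.stack([geom + [5.0, 5.0, 5.0], geom + [8.0, 5.0, 5.0]])
        krf = (eps_rf - 1) / (2 * eps_rf + 1) / rc ** 3
        crf = 1 / rc + krf * rc ** 2
        e_hand = 0.0
        roo = np.linalg.norm(pos[1, 0] - pos[0, 0])
        rmin = 2 * WATER_O_RMIN_HALF
        e_hand += WATER_O_EPSILON * ((rmin / roo) ** 12 - 2 * (rmin / roo) ** 6)
        for a in range(3):
            for b in range(3):
                r = np.linalg.norm(pos[1, b] - pos[0, a])
                e_hand += COULOMB * WATER_Q[a] * WATER_Q[b] * (
                    1 / r + krf * r ** 2 - crf)
        assert water_config_energy(pos, L, rc, eps_rf) == pytest.approx(
            e_hand, abs=1e-8)

    def test_beyond_cutoff_zero(self):
        geom = water_geometry()
        pos = np.stack([geom + [2.0, 2.0, 2.0], geom + [14.0, 2.0, 2.0]])
        assert water_config_energy(pos, 30.0, 9.0, 78.5) == 0.0

    def test_acceptance_band_and_determinism(self, water_box_small):
        assert 0.2 < water_box_small.metadata["acceptance"] < 0.7
        again = gen_water_box(WaterBoxSpec(mc_sweeps=200,
                                           equilibration_sweeps=300,
                                           sampling_interval=20, seed=5))
        np.testing.assert_array_equal(again.frames, water_box_small.frames)

    def test_density_sets_box_length(self):
        spec = WaterBoxSpec()
        assert spec.box_length == pytest.approx(18.65, abs=0.05)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            WaterBoxSpec(n_molecules=1)
        with pytest.raises(ValueError):
            WaterBoxSpec(density=-1.0)
        with pytest.raises(ValueError):
            gen_water_box(WaterBoxSpec(cutoff=12.0))  # > L/2


class TestLjFluid:
    def test_ideal_gas_positions_uniform(self):
        spec = LjFluidSpec(n_particles=200, epsilon=0.0, mc_sweeps=100,
                           equilibration_sweeps=50, sampling_interval=20,
                           seed=4)
        ens = gen_lj_fluid(spec)
        L = ens.metadata["box_length"]
        xs = ens.frames[:, :, 0].ravel() / L
        # chi-square uniformity at the 1% level
        counts, _ = np.histogram(xs, bins=10, range=(0, 1))
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < sps.chi2.ppf(0.99, df=9)

    def test_pair_energy_matches_naive(self, lj_fluid_small):
        from aaadyn._kernels import lj_fluid_total_energy
        ens = lj_fluid_small
        spec = ens.metadata["spec"]
        L = ens.metadata["box_length"]
        rc = ens.metadata["cutoff"]
        rmin = 2 * spec.rmin_half
        a_coef = spec.epsilon * rmin ** 12
        b_coef = 2 * spec.epsilon * rmin ** 6
        pos = ens.frames[0]
        e_naive = 0.0
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = pos[j] - pos[i]
                d -= L * np.rint(d / L)
                r2 = d @ d
                if r2 < rc * rc:
                    r6 = r2 ** 3
                    e_naive += a_coef / r6 ** 2 - b_coef / r6
        e = lj_fluid_total_energy(pos.copy(), L, rc, a_coef, b_coef)
        assert e == pytest.approx(e_naive, rel=1e-10)

    def test_determinism(self):
        s = LjFluidSpec(n_particles=20, mc_sweeps=50,
                        equilibration_sweeps=20, sampling_interval=10,
                        seed=8)
        np.testing.assert_array_equal(gen_lj_fluid(s).frames,
                                      gen_lj_fluid(s).frames)

    def test_density_cap(self):
        with pytest.raises(ValueError):
            LjFluidSpec(reduced_density=0.95)


class TestCavityChannel:
    def test_geometry_and_labels(self):
        spec = CavityChannelSpec(cavity_radius=10.0, channel_radius=4.0,
                                 box_length=32.0, shell_layers=1)
        ens = gen_cavity_channel(spec)
        center = ens.metadata["center"]
        r = np.linalg.norm(ens.frames[0] - center, axis=1)
        resnames = {a.residue_name for a in ens.atoms}
        assert resnames == {"SPH", "CHW"}
        sph = [i for i, a in enumerate(ens.atoms) if a.residue_name == "SPH"]
        np.testing.assert_allclose(r[sph], 10.0, atol=1e-9)
        # no shell atom blocks the channel mouth
        d_axis = np.hypot(ens.frames[0][sph, 1] - center[1],
                          ens.frames[0][sph, 2] - center[2])
        on_channel_side = ens.frames[0][sph, 0] > center[0]
        assert (d_axis[on_channel_side] >= 4.0).all()

    def test_sealed_when_channel_radius_zero(self):
        ens = gen_cavity_channel(CavityChannelSpec(channel_radius=0.0,
                                                   box_length=36.0,
                                                   shell_layers=1))
        assert {a.residue_name for a in ens.atoms} == {"SPH"}

    def test_watertight_invariant(self):
        with pytest.raises(ValueError):
            CavityChannelSpec(wall_spacing=5.0)
        with pytest.raises(ValueError):
            CavityChannelSpec(channel_radius=15.0, cavity_radius=12.0)


class TestLoopTrajectory:
    def test_frozen_coordinate_reproduces_endpoint(self):
        spec = LoopTrajSpec(noise_sd=0.0, mean_s=0.0, sd_s=0.0,
                            n_frames=10, seed=0)
        ens, gt = gen_loop_trajectory(spec)
        expected = spec.endpoint_a + gt["offset"]
        for f in ens.frames:
            np.testing.assert_allclose(f, expected, atol=1e-12)
        assert (gt["s"] == 0).all()

    def test_tau_recovery_within_20_percent(self):
        tau = 10.0
        spec = LoopTrajSpec(tau_true=tau, n_frames=int(2000 * tau), seed=1)
        _, gt = gen_loop_trajectory(spec)
        from aaadyn.loop_geometry import correlation_time
        est = correlation_time(gt["s"], dt=1.0)
        assert est.tau == pytest.approx(tau, rel=0.2)

    def test_cluster_recovery_of_basins(self):
        # two runs dwelling near opposite endpoints, pooled — the combined-
        # trajectory design: clusters must track the ground-truth basins
        from aaadyn.conformational_landscape import gromos_cluster, kabsch_fit
        from aaadyn.trajectory_io import FrameEnsemble
        eA, eB = default_loop_endpoints()
        fitted = kabsch_fit(eB, eA, list(range(20)))
        D = np.sqrt(np.mean(np.sum((fitted - eA) ** 2, axis=1)))
        runs = [gen_loop_trajectory(LoopTrajSpec(
            tau_true=20, mean_s=m, sd_s=0.12, n_frames=300, seed=s))
            for m, s in ((0.15, 11), (0.85, 12))]
        frames = np.concatenate([
            runs[0][0].frames,
            runs[1][0].frames - runs[1][1]["offset"] + runs[0][1]["offset"]])
        ens = FrameEnsemble(runs[0][0].atoms, frames,
                            np.tile(runs[0][0].box[0], (600, 1)))
        basins = np.concatenate([runs[0][1]["basin"], runs[1][1]["basin"]])
        cs = gromos_cluster(ens, "name CA", cutoff=0.45 * D)
        assert len(cs.centers) >= 2
        agree = sum(
            (basins[cs.labels == c] ==
             np.bincount(basins[cs.labels == c]).argmax()).sum()
            for c in range(len(cs.centers)))
        assert agree / 600 >= 0.9

    def test_determinism_and_endpoint_validation(self):
        s = LoopTrajSpec(n_frames=50, seed=3)
        e1, g1 = gen_loop_trajectory(s)
        e2, g2 = gen_loop_trajectory(LoopTrajSpec(n_frames=50, seed=3))
        np.testing.assert_array_equal(e1.frames, e2.frames)
        with pytest.raises(ValueError):
            LoopTrajSpec(endpoint_a=np.zeros((5, 3)),
                         endpoint_b=np.zeros((6, 3)))
        with pytest.raises(ValueError):
            LoopTrajSpec(tau_true=0.5)


class TestIdealHelix:
    def test_alpha_rise_per_residue(self):
        ens = gen_ideal_helix(12, -57.0, -47.0)
        ca = ens.frames[0][[i for i, a in enumerate(ens.atoms)
                            if a.name == "CA"]]
        c = ca - ca.mean(axis=0)
        w, v = np.linalg.eigh(c.T @ c)
        proj = c @ v[:, -1]
        rise = (proj.max() - proj.min()) / 11
        assert rise == pytest.approx(1.5, abs=0.15)

    def test_extended_end_to_end(self):
        ens = gen_ideal_helix(12, 180.0, 180.0)
        ca = ens.frames[0][[i for i, a in enumerate(ens.atoms)
                            if a.name == "CA"]]
        per_res = np.linalg.norm(ca[-1] - ca[0]) / 11
        assert per_res == pytest.approx(3.5, abs=0.4)

    def test_single_residue_valid(self):
        ens = gen_ideal_helix(1)
        assert ens.n_atoms == 4
        assert {a.name for a in ens.atoms} == {"N", "CA", "C", "O"}

    def test_backbone_geometry(self):
        ens = gen_ideal_helix(5, -57.0, -47.0)
        idx = {(a.residue_number, a.name): a.index for a in ens.atoms}
        f = ens.frames[0]
        for r in range(1, 6):
            assert np.linalg.norm(f[idx[r, "N"]] - f[idx[r, "CA"]]) == \
                pytest.approx(1.458, abs=1e-6)
            assert np.linalg.norm(f[idx[r, "C"]] - f[idx[r, "O"]]) == \
                pytest.approx(1.231, abs=1e-6)
        for r in range(1, 5):
            assert np.linalg.norm(f[idx[r, "C"]] - f[idx[r + 1, "N"]]) == \
                pytest.approx(1.329, abs=1e-6)


def test_generators_roundtrip_through_io(tmp_path, lj_fluid_small):
    from aaadyn.trajectory_io import load_trajectory, write_trajectory_dcd
    top = tmp_path / "t.pdb"
    dcd = tmp_path / "t.dcd"
    write_trajectory_dcd(lj_fluid_small, top, dcd)
    back = load_trajectory(top, dcd, allow_missing_parameters=True)
    assert back.n_frames == lj_fluid_small.n_frames
    assert back.n_atoms == lj_fluid_small.n_atoms
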