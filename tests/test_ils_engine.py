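"""ILS free-energy maps against the Widom-insertion oracle and limits."""

import numpy as np
import pytest

from aaadyn.constants import KB
from aaadyn.ils_engine import (IlsConfig, bulk_reference, compute_ils_map,
                               compute_occupancy_map)
from aaadyn.probe_model import (ProbeModel, generate_orientations,
                                OrientationSet, rotation_from_z)
from aaadyn.trajectory_io import FrameEnsemble

from conftest import make_ensemble
from test_probe_model import naive_insertion_energy

KT = KB * 300.0


def naive_widom_map(ensemble, probe, orientations, config):
    """Independent per-voxel Widom average (pure Python double loops)."""
    from aaadyn.ils_engine import _grid_geometry
    origin, dims = _grid_geometry(ensemble, config)
    rmh, eps = ensemble.lj_arrays()
    kt = KB * config.temperature
    G = np.empty(dims)
    occ = np.zeros(dims, dtype=bool)
    n = ensemble.n_frames * len(orientations)
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                c = origin + config.grid_spacing * np.array([i, j, k])
                w = 0.0
                for m in range(ensemble.n_frames):
                    for ax in orientations.axes:
                        e = naive_insertion_energy(
                            ensemble.frames[m], probe, c, ax, config.cutoff,
                            ensemble.box[m], rmh, eps)
                        if e <= config.energy_cap:
                            w += np.exp(-e / kt)
                if w == 0.0:
                    occ[i, j, k] = True
                    G[i, j, k] = 30.0
                else:
                    G[i, j, k] = -kt * np.log(w / n)
    return G, occ


@pytest.fixture(scope="module")
def tiny_fluid():
    from aaadyn.synthetic_data import LjFluidSpec, gen_lj_fluid
    ens = gen_lj_fluid(LjFluidSpec(n_particles=30, mc_sweeps=40,
                                   equilibration_sweeps=50,
                                   sampling_interval=10, seed=9))
    assert ens.n_frames == 4
    return ens


def test_vacuum_gives_zero_everywhere():
    ens = make_ensemble(np.full((1, 3), 5.0), box=(12, 12, 12))  # eps = 0
    cfg = IlsConfig(grid_spacing=3.0, cutoff=5.0, orientation_count=3)
    pmf = compute_ils_map(ens, ProbeModel.o2(), generate_orientations(3), cfg)
    np.testing.assert_array_equal(pmf.values, 0.0)
    assert not pmf.occluded_mask.any()


def test_single_sample_log_exp_identity():
    # 1 frame, 1 orientation, single-site probe, one atom: G = min(dE, cap)
    ens = make_ensemble([[6.0, 6.0, 6.0]], box=(12, 12, 12), rmh=1.7,
                        eps=0.12)
    probe = ProbeModel.single_site(1.7, 0.12)
    cfg = IlsConfig(grid_spacing=1.0, cutoff=6.0, orientation_count=1)
    pmf = compute_ils_map(ens, probe, generate_orientations(1), cfg)
    rmh, eps = ens.lj_arrays()
    for v in [(0, 0, 0), (5, 5, 5), (3, 6, 6), (6, 6, 2)]:
        c = pmf.grid.voxel_center(v)
        de = naive_insertion_energy(ens.frames[0], probe, c, [0, 0, 1],
                                    6.0, ens.box[0], rmh, eps)
        if de > cfg.energy_cap:
            assert pmf.occluded_mask[v]
        else:
            assert pmf.values[v] == pytest.approx(de, abs=1e-10)


def test_matches_naive_widom_oracle(tiny_fluid):
    probe = ProbeModel.o2()
    orients = generate_orientations(3)
    L = tiny_fluid.box[0, 0]
    cfg = IlsConfig(grid_spacing=2.5, cutoff=6.0, orientation_count=3,
                    region=((0.0, 0.0, 0.0), (L, L, L)))
    pmf = compute_ils_map(tiny_fluid, probe, orients, cfg)
    G, occ = naive_widom_map(tiny_fluid, probe, orients, cfg)
    np.testing.assert_array_equal(pmf.occluded_mask, occ)
    ok = ~occ
    np.testing.assert_allclose(pmf.values[ok], G[ok], atol=1e-10)


def test_c2_mirror_orientations_leave_G_unchanged(tiny_fluid):
    probe = ProbeModel.o2()
    base = generate_orientations(4)
    # add the antipode of each axis: C2 symmetry means no new information
    doubled = OrientationSet.__new__(OrientationSet)
    doubled.axes = np.vstack([base.axes, -base.axes])
    cfg = IlsConfig(grid_spacing=3.0, cutoff=6.0)
    p1 = compute_ils_map(tiny_fluid, probe, base, cfg)
    p2 = compute_ils_map(tiny_fluid, probe, doubled, cfg)
    ok = ~p1.occluded_mask
    np.testing.assert_allclose(p1.values[ok], p2.values[ok], atol=1e-12)


def test_frame_duplication_leaves_G_unchanged(tiny_fluid):
    probe = ProbeModel.o2()
    orients = generate_orientations(3)
    cfg = IlsConfig(grid_spacing=3.0, cutoff=6.0)
    p1 = compute_ils_map(tiny_fluid, probe, orients, cfg)
    doubled = FrameEnsemble(tiny_fluid.atoms,
                            np.concatenate([tiny_fluid.frames] * 2),
                            np.concatenate([tiny_fluid.box] * 2))
    p2 = compute_ils_map(doubled, probe, orients, cfg)
    np.testing.assert_array_equal(p1.occluded_mask, p2.occluded_mask)
    # identical samples twice: equal up to float accumulation order
    np.testing.assert_allclose(p1.values, p2.values, rtol=0, atol=1e-12)


def test_cap_independence_of_open_voxels(tiny_fluid):
    probe = ProbeModel.o2()
    orients = generate_orientations(3)
    lo = IlsConfig(grid_spacing=3.0, cutoff=6.0, energy_cap=60.0)
    hi = IlsConfig(grid_spacing=3.0, cutoff=6.0, energy_cap=1e6)
    p_lo = compute_ils_map(tiny_fluid, probe, orients, lo)
    p_hi = compute_ils_map(tiny_fluid, probe, orients, hi)
    # voxels where every sampled energy stayed below the lower cap agree
    stable = ~p_lo.occluded_mask & (p_lo.values == p_hi.values)
    assert stable.any()


def test_high_temperature_limit_mean_energy():
    # beta -> 0: G -> <dE> to first order, single far-away atom
    ens = make_ensemble([[10.0, 10.0, 14.0]], box=(20, 20, 20), rmh=1.7,
                        eps=0.12)
    probe = ProbeModel.single_site(1.7, 0.12)
    cfg = IlsConfig(temperature=3e6, grid_spacing=2.0, cutoff=9.0,
                    region=((9.0, 9.0, 9.0), (11.0, 11.0, 11.0)))
    pmf = compute_ils_map(ens, probe, generate_orientations(1), cfg)
    rmh, eps = ens.lj_arrays()
    de = naive_insertion_energy(ens.frames[0], probe,
                                pmf.grid.voxel_center((0, 0, 0)),
                                [0, 0, 1], 9.0, ens.box[0], rmh, eps)
    assert pmf.values[0, 0, 0] == pytest.approx(de, rel=1e-3)


def test_zero_frames_or_orientations_rejected(tiny_fluid):
    cfg = IlsConfig(grid_spacing=3.0)
    with pytest.raises(ValueError):
        compute_ils_map(tiny_fluid, ProbeModel.o2(),
                        OrientationSet(np.zeros((0, 3))), cfg)


# --- bulk reference ----------------------------------------------------------

def _uniform_pmf(c, dims=(4, 4, 4)):
    from aaadyn.ils_engine import PmfMap
    from aaadyn.trajectory_io import VolumetricMap
    vm = VolumetricMap(origin=np.zeros(3), spacing=1.0, dims=dims,
                       values=np.full(np.prod(dims), c))
    return PmfMap(grid=vm, occluded_mask=np.zeros(dims, bool),
                  metadata={"temperature": 300.0})


def test_bulk_uniform_map_mean_c_sd_zero(water_box_small):
    pmf = _uniform_pmf(1.5)
    bulk = bulk_reference(pmf, water_box_small)
    assert bulk.mean_G == pytest.approx(1.5, abs=1e-9)
    assert bulk.sd == pytest.approx(0.0, abs=1e-9)
    # pure solvent: every voxel qualifies
    assert bulk.voxel_count == 64


def test_bulk_excludes_near_solute_voxels():
    # one non-solvent atom at the center: nearby voxels must drop out
    ens = make_ensemble([[2.0, 2.0, 2.0]], box=(4, 4, 4))
    pmf = _uniform_pmf(2.0)
    bulk = bulk_reference(pmf, ens, min_distance_from_solute=1.0)
    assert bulk.voxel_count < 64
    with pytest.raises(ValueError):
        bulk_reference(pmf, ens, min_distance_from_solute=10.0)


def test_bulk_pools_widom_weights_not_plain_mean():
    # two voxel values: pooled estimator re-exponentiates
    from aaadyn.ils_engine import PmfMap
    from aaadyn.trajectory_io import VolumetricMap
    vals = np.array([0.0, 1.0] * 32)
    vm = VolumetricMap(origin=np.zeros(3), spacing=1.0, dims=(4, 4, 4),
                       values=vals)
    pmf = PmfMap(grid=vm, occluded_mask=np.zeros((4, 4, 4), bool),
                 metadata={"temperature": 300.0})
    ens = make_ensemble(np.zeros((0, 3)), box=(4, 4, 4))
    bulk = bulk_reference(pmf, ens)
    expected = -KT * np.log(0.5 * (1 + np.exp(-1.0 / KT)))
    assert bulk.mean_G == pytest.approx(expected, abs=1e-9)


# --- occupancy ---------------------------------------------------------------

def test_occupancy_fixed_atom():
    coords = np.tile(np.array([[2.5, 2.5, 2.5]]), (5, 1, 1))
    ens = FrameEnsemble(make_ensemble(coords[0]).atoms, coords,
                        np.full(3, 5.0))
    occ = compute_occupancy_map(ens, [0], spacing=1.0)
    assert occ.values[2, 2, 2] == 1.0
    assert occ.values.sum() == 1.0


def test_occupancy_empty_selection_raises(water_box_small):
    with pytest.raises(ValueError, match="empty selection"):
        compute_occupancy_map(water_box_small, [], spacing=1.0)


def test_occupancy_uniform_gas_binomial_expectation():
    rng = np.random.default_rng(11)
    n_frames, n_atoms, L = 100, 64, 8.0
    coords = rng.uniform(0, L, size=(n_frames, n_atoms, 3))
    ens = FrameEnsemble(make_ensemble(coords[0]).atoms, coords, np.full(3, L))
    occ = compute_occupancy_map(ens, list(range(n_atoms)), spacing=2.0)
    p_vox = (2.0 / L) ** 3
    expect = 1 - (1 - p_vox) ** n_atoms
    sd = np.sqrt(expect * (1 - expect) / n_frames / occ.values.size)
    assert occ.values.mean() == pytest.approx(expect, abs=3 * sd)
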