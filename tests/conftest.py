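import numpy as np
import pytest

from aaadyn.synthetic_data import (LjFluidSpec, WaterBoxSpec, gen_lj_fluid,
                                   gen_water_box)
from aaadyn.trajectory_io import AtomRecord, FrameEnsemble


@pytest.fixture(scope="session")
def lj_fluid_small():
    """50-particle LJ fluid, 20 frames — shared Widom-oracle substrate."""
    return gen_lj_fluid(LjFluidSpec(n_particles=50, mc_sweeps=100,
                                    equilibration_sweeps=100,
                                    sampling_interval=5, seed=3))


@pytest.fixture(scope="session")
def water_box_small():
    """216-molecule water box, short run — structure/energy checks only."""
    return gen_water_box(WaterBoxSpec(mc_sweeps=200, equilibration_sweeps=300,
                                      sampling_interval=20, seed=5))


def make_ensemble(coords, box=(20.0, 20.0, 20.0), names=None, resnames=None,
                  resnums=None, chains=None, rmh=0.0, eps=0.0):
    """Build a single-frame ensemble from bare coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    n = coords.shape[0]
    atoms = [
        AtomRecord(
            index=i,
            name=(names[i] if names else "X"),
            residue_name=(resnames[i] if resnames else "DUM"),
            residue_number=(resnums[i] if resnums else i + 1),
            chain_id=(chains[i] if chains else "A"),
            lj_rmin_half=rmh, lj_epsilon=eps, partial_charge=0.0)
        for i in range(n)
    ]
    return FrameEnsemble(atoms, coords[None, :, :], np.asarray(box))


@pytest.fixture
def two_chain_protein():
    """Synthetic 2-chain Cα-only protein spanning residues 300-400."""
    rng = np.random.default_rng(0)
    atoms, coords = [], []
    idx = 0
    for chain in "AB":
        for resid in range(300, 401):
            atoms.append(AtomRecord(index=idx, name="CA",
                                    residue_name="ALA",
                                    residue_number=resid, chain_id=chain))
            coords.append(rng.uniform(0, 50, 3))
            idx += 1
    return FrameEnsemble(atoms, np.array(coords)[None], np.full(3, 60.0))
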