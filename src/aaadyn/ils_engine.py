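"""Implicit ligand sampling: 3D gas free-energy maps from MD frames.

The per-voxel free energy is the Widom test-particle estimate

    G(r) = -kB T ln[ (1/(N C)) sum_m sum_k exp(-dE_{m,k}(r) / kB T) ]

where dE_{m,k}(r) is the LJ interaction energy of inserting the probe at r
with orientation k into frame m, N is the number of frames and C the number
of orientations.  G is referenced to vacuum (dE = 0 everywhere gives G = 0);
the value in bulk solvent is the probe's solvation free energy, and
subtracting it converts barrier heights to the cost of transfer from bulk.

Insertions with dE above the energy cap contribute zero Boltzmann weight;
a voxel where every sample is capped is flagged occluded and displayed at a
fixed +30 kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .constants import KB
from .probe_model import OrientationSet, ProbeModel, rotated_site_offsets
from .trajectory_io import FrameEnsemble, VolumetricMap, select_atoms

__all__ = ["IlsConfig", "PmfMap", "BulkReference", "compute_ils_map",
           "bulk_reference", "compute_occupancy_map", "OCCLUDED_DISPLAY"]

#: display value (kcal/mol) written into fully occluded voxels
OCCLUDED_DISPLAY = 30.0

_SOLVENT_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC", "H2O", "NA", "CL", "SOD",
     "CLA", "K", "POT"})


@dataclass
class IlsConfig:
    """Settings of an ILS run.

    region: ((xmin, ymin, zmin), (xmax, ymax, zmax)) in Å, or None for the
    first frame's box.  energy_cap defaults to 87 kB T, the Boltzmann-weight
    underflow threshold.
    """

    temperature: float = 300.0
    grid_spacing: float = 1.0
    cutoff: float = 10.0
    energy_cap: Optional[float] = None
    orientation_count: int = 21
    frame_stride: int = 1
    region: Optional[tuple] = None
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.energy_cap is None:
            self.energy_cap = 87.0 * KB * self.temperature
        if self.energy_cap <= 0:
            raise ValueError("energy_cap must be positive")

    @property
    def kt(self) -> float:
        return KB * self.temperature


@dataclass
class PmfMap:
    """3D probe free-energy map (kcal/mol, vacuum reference)."""

    grid: VolumetricMap
    occluded_mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class BulkReference:
    """Pooled bulk-region free energy (the probe's solvation free energy)."""

    mean_G: float
    sd: float
    voxel_count: int
    region: str = ""


def _grid_geometry(ensemble: FrameEnsemble, config: IlsConfig):
    if config.region is not None:
        lo = np.asarray(config.region[0], dtype=np.float64)
        hi = np.asarray(config.region[1], dtype=np.float64)
    else:
        lo = np.zeros(3)
        hi = ensemble.box[0].astype(np.float64)
    if np.any(hi <= lo):
        raise ValueError("region upper bound must exceed lower bound")
    h = config.grid_spacing
    dims = tuple(int(max(1, math.floor((hi[d] - lo[d]) / h + 1e-9)))
                 for d in range(3))
    origin = lo + h / 2.0
    return origin, dims


def compute_ils_map(ensemble: FrameEnsemble, probe: ProbeModel,
                    orientations: OrientationSet,
                    config: IlsConfig) -> PmfMap:
    """Run ILS over the configured grid region.

    Frames are used at config.frame_stride.  Only LJ-active atoms
    (epsilon > 0) interact with the apolar probe.
    """
    if len(orientations) < 1:
        raise ValueError("need at least one orientation")
    frames = ensemble.frames[:: config.frame_stride]
    boxes = ensemble.box[:: config.frame_stride]
    if frames.shape[0] < 1:
        raise ValueError("need at least one frame")

    origin, dims = _grid_geometry(ensemble, config)
    nx, ny, nz = dims
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    centers = origin + config.grid_spacing * np.stack(
        [ii, jj, kk], axis=-1).reshape(-1, 3)

    rmh, eps = ensemble.lj_arrays()
    active = eps > 0  # LJ-inactive atoms cannot interact with the apolar probe
    frames = frames[:, active, :]
    rmh, eps = rmh[active], eps[active]
    offsets = rotated_site_offsets(probe, orientations)
    beta = 1.0 / config.kt

    wsum, n_ok = _kernels.ils_accumulate(
        np.ascontiguousarray(frames), np.ascontiguousarray(boxes),
        rmh, eps, np.ascontiguousarray(centers),
        np.ascontiguousarray(offsets), probe.site_rmin_half,
        probe.site_epsilon, float(config.cutoff), beta,
        float(config.energy_cap))

    n_samples = frames.shape[0] * len(orientations)
    # a voxel is occluded when every sample was capped, or when the weights
    # underflowed to zero (possible only for caps far above 87 kBT)
    occluded = (n_ok == 0) | (wsum <= 0.0)
    G = np.full(wsum.shape, OCCLUDED_DISPLAY)
    ok = ~occluded
    G[ok] = -config.kt * np.log(wsum[ok] / n_samples)

    grid = VolumetricMap(origin=origin, spacing=config.grid_spacing,
                         dims=dims, values=G, units_label="kcal/mol")
    meta = {"n_frames": int(frames.shape[0]),
            "n_orientations": int(len(orientations)),
            "temperature": config.temperature,
            "cutoff": config.cutoff,
            "energy_cap": config.energy_cap,
            "grid_spacing": config.grid_spacing,
            "probe": probe.to_dict()}
    return PmfMap(grid=grid, occluded_mask=occluded.reshape(dims),
                  metadata=meta)


def bulk_reference(pmf: PmfMap, ensemble: FrameEnsemble,
                   min_distance_from_solute: float = 12.0,
                   solvent_resnames=_SOLVENT_RESNAMES,
                   n_blocks: int = 5) -> BulkReference:
    """Pool bulk-region voxels into one solvation free energy.

    Bulk voxels lie farther than ``min_distance_from_solute`` from every
    non-solvent atom in every frame (minimum image).  The pooled estimator
    re-exponentiates: mean_G = -kT ln <exp(-G/kT)>_voxels, i.e. the pooled
    Widom average over the region; occluded voxels stay in the pool with
    zero weight (dropping them would bias the volume average toward open
    voxels).  The sd comes from block averaging over ``n_blocks`` voxel
    sub-blocks.
    """
    kt = pmf.metadata.get("temperature", 300.0) * KB
    centers = pmf.grid.voxel_centers()
    solute_idx = [a.index for a in ensemble.atoms
                  if a.residue_name not in solvent_resnames]
    qualify = np.ones(centers.shape[0], dtype=bool)
    if solute_idx:
        d2min = np.full(centers.shape[0], np.inf)
        for fi in range(ensemble.n_frames):
            pos = ensemble.frames[fi][solute_idx]
            box = ensemble.box[fi]
            for chunk in range(0, centers.shape[0], 4096):
                c = centers[chunk:chunk + 4096]
                d = c[:, None, :] - pos[None, :, :]
                d -= box * np.rint(d / box)
                d2 = np.min(np.einsum("ijk,ijk->ij", d, d), axis=1)
                d2min[chunk:chunk + 4096] = np.minimum(
                    d2min[chunk:chunk + 4096], d2)
        qualify &= d2min > min_distance_from_solute ** 2
    if not np.any(qualify):
        raise ValueError("no bulk voxels qualify; reduce "
                         "min_distance_from_solute or enlarge the grid")
    g = pmf.values.reshape(-1)[qualify]
    occ = pmf.occluded_mask.reshape(-1)[qualify]
    weights = np.where(occ, 0.0, np.exp(-g / kt))

    def pooled(w):
        m = np.mean(w)
        if m <= 0:
            raise ValueError("bulk region fully occluded")
        return float(-kt * np.log(m))

    mean_G = pooled(weights)
    if weights.size >= n_blocks:
        blocks = np.array_split(weights, n_blocks)
        estimates = np.array([pooled(b) for b in blocks])
        sd = float(np.std(estimates, ddof=1))
    else:
        sd = float("nan")
    return BulkReference(mean_G=mean_G, sd=sd, voxel_count=int(g.size),
                         region=f">{min_distance_from_solute} Å from solute")


def compute_occupancy_map(ensemble: FrameEnsemble, selection,
                          spacing: float = 1.0,
                          region: Optional[tuple] = None) -> VolumetricMap:
    """Fraction of frames in which >=1 selected atom falls inside each voxel."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if isinstance(selection, str):
        idx = select_atoms(ensemble, selection)
    else:
        idx = list(selection)
    if not idx:
        raise ValueError("empty selection")
    if region is not None:
        lo = np.asarray(region[0], dtype=np.float64)
        hi = np.asarray(region[1], dtype=np.float64)
    else:
        lo = np.zeros(3)
        hi = ensemble.box[0].astype(np.float64)
    dims = tuple(int(max(1, math.floor((hi[d] - lo[d]) / spacing + 1e-9)))
                 for d in range(3))
    counts = np.zeros(dims, dtype=np.int64)
    for fi in range(ensemble.n_frames):
        pos = ensemble.frames[fi][idx]
        ijk = np.floor((pos - lo) / spacing).astype(np.int64)
        ok = np.all((ijk >= 0) & (ijk < np.array(dims)), axis=1)
        ijk = np.unique(ijk[ok], axis=0)
        if ijk.size:
            counts[ijk[:, 0], ijk[:, 1], ijk[:, 2]] += 1
    values = counts / ensemble.n_frames
    return VolumetricMap(origin=lo + spacing / 2.0, spacing=spacing,
                         dims=dims, values=values, units_label="occupancy")
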