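"""Gas migration pathways on a free-energy grid.

A migration barrier is a minimax (bottleneck) path problem: among all
26-connected voxel paths from the active site to the bulk/boundary, find
the one whose maximum free energy is smallest; that maximum is the barrier
an O2 molecule must cross.  Entrance pathways are read off sub-isovalue
connected components that link the site to the map boundary.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .ils_engine import PmfMap, BulkReference
from .trajectory_io import FrameEnsemble

__all__ = ["GridPath", "Channel", "PathwayReport", "minimax_barrier",
           "enumerate_pathways", "lining_residues"]

# offsets of the 26-connected neighborhood, fixed lexicographic order
_NEIGHBORS = [(di, dj, dk)
              for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
              if (di, dj, dk) != (0, 0, 0)]
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GridPath:
    """Ordered 26-connected voxel path with its bottleneck free energy."""

    voxels: list[tuple[int, int, int]]
    bottleneck: float
    disconnected: bool = False

    def __post_init__(self):
        for a, b in zip(self.voxels, self.voxels[1:]):
            if max(abs(a[0] - b[0]), abs(a[1] - b[1]), abs(a[2] - b[2])) != 1:
                raise ValueError("consecutive path voxels must be adjacent")


@dataclass
class Channel:
    """One entrance pathway: the sub-isovalue component and one exit patch."""

    component_voxels: np.ndarray  # (n, 3) int
    exit_voxels: np.ndarray  # (m, 3) int, boundary patch
    isovalue: float


@dataclass
class PathwayReport:
    barrier_abs: float
    barrier_rel: float
    path: GridPath
    exit_voxel: Optional[tuple]
    lining: list = field(default_factory=list)


def _values_and_passable(pmf) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pmf, PmfMap):
        return pmf.values, ~pmf.occluded_mask
    values = np.asarray(pmf, dtype=np.float64)
    return values, np.isfinite(values)


def minimax_barrier(pmf, start_voxel, goal_region) -> GridPath:
    """Exact widest-path (bottleneck) search on the voxel lattice.

    The cost of a path is the maximum G over its voxels (start and goal
    included).  A best-first search with key (bottleneck, length, voxel)
    returns the path minimizing that maximum; ties break by shorter path,
    then lexicographic voxel order.  Occluded voxels are impassable.
    goal_region: set/list of voxel triples or a boolean mask.
    """
    values, passable = _values_and_passable(pmf)
    dims = values.shape
    start = tuple(int(x) for x in start_voxel)
    if not all(0 <= start[d] < dims[d] for d in range(3)):
        raise ValueError("start voxel outside grid")
    if isinstance(goal_region, np.ndarray) and goal_region.dtype == bool:
        goal_mask = goal_region
    else:
        goal_mask = np.zeros(dims, dtype=bool)
        for g in goal_region:
            goal_mask[tuple(int(x) for x in g)] = True
    if not passable[start]:
        return GridPath([start], float("inf"), disconnected=True)

    best = np.full(dims, np.inf)
    best_len = np.full(dims, np.iinfo(np.int64).max, dtype=np.int64)
    prev: dict[tuple, tuple] = {}
    b0 = float(values[start])
    best[start] = b0
    best_len[start] = 1
    heap = [(b0, 1, start)]
    visited = np.zeros(dims, dtype=bool)
    while heap:
        bott, plen, vox = heapq.heappop(heap)
        if visited[vox]:
            continue
        visited[vox] = True
        if goal_mask[vox]:
            path = [vox]
            while vox in prev:
                vox = prev[vox]
                path.append(vox)
            path.reverse()
            return GridPath(path, bott)
        i, j, k = vox
        for di, dj, dk in _NEIGHBORS:
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < dims[0] and 0 <= nj < dims[1]
                    and 0 <= nk < dims[2]):
                continue
            nb = (ni, nj, nk)
            if visited[nb] or not passable[nb]:
                continue
            cand = max(bott, float(values[nb]))
            if cand < best[nb] or (cand == best[nb]
                                   and plen + 1 < best_len[nb]):
                best[nb] = cand
                best_len[nb] = plen + 1
                prev[nb] = vox
                heapq.heappush(heap, (cand, plen + 1, nb))
    return GridPath([start], float("inf"), disconnected=True)


def enumerate_pathways(pmf, isovalue: float, site_voxel) -> list[Channel]:
    """Entrance pathways at an isovalue.

    Flood-fills voxels with G <= isovalue (26-connectivity, occluded voxels
    excluded) and takes the component containing ``site_voxel``.  Each
    26-connected patch of that component's boundary-touching voxels is one
    exit, i.e. one pathway.  Returns [] when the site is above the isovalue
    or its component never reaches the map boundary.
    """
    if not np.isfinite(isovalue):
        raise ValueError("isovalue must be finite")
    values, passable = _values_and_passable(pmf)
    site = tuple(int(x) for x in site_voxel)
    sub = (values <= isovalue) & passable
    if not sub[site]:
        return []
    labels, _ = ndimage.label(sub, structure=_CONN26)
    comp = labels == labels[site]
    boundary = np.zeros_like(comp)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    exits = comp & boundary
    if not np.any(exits):
        return []
    exit_labels, n_exits = ndimage.label(exits, structure=_CONN26)
    comp_voxels = np.argwhere(comp)
    channels = []
    for e in range(1, n_exits + 1):
        channels.append(Channel(component_voxels=comp_voxels,
                                exit_voxels=np.argwhere(exit_labels == e),
                                isovalue=float(isovalue)))
    return channels


def lining_residues(path: GridPath, pmf_grid, ensemble: FrameEnsemble,
                    radius: float = 4.5,
                    frame_fraction: float = 0.5) -> list[dict]:
    """Residues lining a pathway.

    A residue lines the path when any of its heavy atoms comes within
    ``radius`` of any path voxel center in at least ``frame_fraction`` of
    the frames.  Returns dicts sorted by overall minimum distance.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not path.voxels:
        raise ValueError("empty path")
    centers = np.array([pmf_grid.voxel_center(v) for v in path.voxels])
    heavy = [a for a in ensemble.atoms
             if not (a.element or a.name).upper().startswith("H")]
    if not heavy:
        return []
    heavy_idx = np.array([a.index for a in heavy])
    res_keys = [(a.chain_id, a.residue_number, a.residue_name) for a in heavy]
    unique_res = sorted(set(res_keys))
    res_of_atom = np.array([unique_res.index(k) for k in res_keys])
    n_res = len(unique_res)
    hit_frames = np.zeros(n_res, dtype=np.int64)
    dmin_overall = np.full(n_res, np.inf)
    for fi in range(ensemble.n_frames):
        pos = ensemble.frames[fi][heavy_idx]
        d = np.sqrt(np.min(
            np.sum((pos[:, None, :] - centers[None, :, :]) ** 2, axis=2),
            axis=1))
        res_min = np.full(n_res, np.inf)
        np.minimum.at(res_min, res_of_atom, d)
        hit_frames += res_min <= radius
        dmin_overall = np.minimum(dmin_overall, res_min)
    need = frame_fraction * ensemble.n_frames
    out = []
    for r in range(n_res):
        if hit_frames[r] >= need and np.isfinite(dmin_overall[r]):
            chain, resnum, resname = unique_res[r]
            out.append({"residue_number": resnum, "residue_name": resname,
                        "chain": chain, "min_distance": float(dmin_overall[r])})
    out.sort(key=lambda d: d["min_distance"])
    return out


def pathway_report(pmf: PmfMap, bulk: BulkReference, start_voxel,
                   goal_region, ensemble: Optional[FrameEnsemble] = None,
                   lining_radius: float = 4.5) -> PathwayReport:
    """Barrier (absolute and bulk-relative) plus lining residues."""
    path = minimax_barrier(pmf, start_voxel, goal_region)
    lining = []
    if ensemble is not None and not path.disconnected:
        lining = lining_residues(path, pmf.grid, ensemble, lining_radius)
    exit_voxel = path.voxels[-1] if not path.disconnected else None
    return PathwayReport(barrier_abs=path.bottleneck,
                         barrier_rel=path.bottleneck - bulk.mean_G,
                         path=path, exit_voxel=exit_voxel, lining=lining)
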