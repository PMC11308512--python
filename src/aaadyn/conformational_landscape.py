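"""Loop conformational landscape: Cα PCA, 2D free-energy surfaces, and
GROMOS RMSD clustering.

PCA is run on the pooled covariance of loop Cα coordinates after each frame
has been least-squares fit (Kabsch) onto a reference using a fit selection —
by default the non-loop core, so that loop motion is measured in the enzyme
frame.  GROMOS clustering greedily picks the frame with the most RMSD
neighbors within the cutoff as a cluster center, removes it and its
neighbors, and repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import KB
from .trajectory_io import FrameEnsemble, select_atoms

__all__ = ["ProjectionResult", "FreeEnergySurface", "ClusterSet",
           "kabsch_fit", "pca_loop", "fes_2d", "gromos_cluster",
           "pairwise_rmsd"]


@dataclass
class ProjectionResult:
    mean_coords: np.ndarray  # (3n,) mean of fitted loop coordinates
    eigenvectors: np.ndarray  # (3n, 3n) columns, descending eigenvalue
    eigenvalues: np.ndarray  # (3n,) Å², descending
    explained: np.ndarray  # fractions summing to 1
    projections: np.ndarray  # (n_frames, 3n)

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")


@dataclass
class FreeEnergySurface:
    """F = -kT ln(p / p_max) over 2D bins; empty bins carry NaN."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # (nx, ny), NaN where empty
    temperature: float

    @property
    def empty_mask(self) -> np.ndarray:
        return ~np.isfinite(self.free_energy)


@dataclass
class ClusterSet:
    labels: np.ndarray  # per-frame cluster id, 0-based in greedy order
    centers: np.ndarray  # per-cluster central member frame index
    populations: np.ndarray  # fractions, greedy (descending) order
    cutoff: float


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation mapping centered P onto centered Q (Kabsch)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_fit(coords: np.ndarray, ref: np.ndarray,
               fit_idx: Sequence[int]) -> np.ndarray:
    """Least-squares fit a frame onto a reference using the fit atoms."""
    fit_idx = list(fit_idx)
    p = coords[fit_idx]
    q = ref[fit_idx]
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    R = kabsch_rotation(p - pc, q - qc)
    return (coords - pc) @ R.T + qc


def _fitted_frames(ensemble: FrameEnsemble, fit_idx, ref_frame=0):
    ref = ensemble.frames[ref_frame]
    return np.stack([kabsch_fit(ensemble.frames[fi], ref, fit_idx)
                     for fi in range(ensemble.n_frames)])


def pca_loop(ensemble: FrameEnsemble, ca_selection,
             fit_selection=None, fit: bool = True) -> ProjectionResult:
    """PCA of loop Cα coordinates after least-squares fitting each frame.

    fit_selection defaults to the analysis selection itself; pass the
    protein-core Cα to measure loop motion in the enzyme frame.  ``fit=False``
    skips the superposition (for inputs that are already in a common frame).
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    ca_idx = select_atoms(ensemble, ca_selection) \
        if isinstance(ca_selection, str) else list(ca_selection)
    if len(ca_idx) < 1:
        raise ValueError("empty analysis selection")
    if fit_selection is None:
        fit_idx = ca_idx
    else:
        fit_idx = select_atoms(ensemble, fit_selection) \
            if isinstance(fit_selection, str) else list(fit_selection)
    if fit and len(fit_idx) < 3:
        raise ValueError("fit selection needs >= 3 atoms")
    fitted = _fitted_frames(ensemble, fit_idx) if fit else ensemble.frames
    X = fitted[:, ca_idx, :].reshape(ensemble.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (ensemble.n_frames - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.maximum(w[order], 0.0)
    v = v[:, order]
    total = w.sum()
    explained = w / total if total > 0 else np.zeros_like(w)
    return ProjectionResult(mean_coords=mean, eigenvectors=v, eigenvalues=w,
                            explained=explained, projections=Xc @ v)


def fes_2d(projections: np.ndarray, bins: int = 50,
           temperature: float = 300.0,
           ranges=None) -> FreeEnergySurface:
    """Free-energy surface over the first two projection columns."""
    proj = np.asarray(projections)
    if proj.ndim != 2 or proj.shape[0] < 1 or proj.shape[1] < 2:
        raise ValueError("need a non-empty (n, >=2) projection array")
    if np.isscalar(bins) and bins < 2:
        raise ValueError("need >= 2 bins per axis")
    counts, xe, ye = np.histogram2d(proj[:, 0], proj[:, 1], bins=bins,
                                    range=ranges)
    kt = KB * temperature
    F = np.full(counts.shape, np.nan)
    nz = counts > 0
    F[nz] = -kt * np.log(counts[nz] / counts.max())
    return FreeEnergySurface(x_edges=xe, y_edges=ye, free_energy=F,
                             temperature=temperature)


def pairwise_rmsd(ensemble: FrameEnsemble, selection,
                  fit_selection=None) -> np.ndarray:
    """All-pairs Cα RMSD (Å) after Kabsch fitting on the fit selection."""
    sel = select_atoms(ensemble, selection) \
        if isinstance(selection, str) else list(selection)
    if not sel:
        raise ValueError("empty selection")
    fit_idx = sel if fit_selection is None else (
        select_atoms(ensemble, fit_selection)
        if isinstance(fit_selection, str) else list(fit_selection))
    n = ensemble.n_frames
    rmsd = np.zeros((n, n))
    coords = ensemble.frames
    for i in range(n):
        for j in range(i + 1, n):
            fit_j = kabsch_fit(coords[j], coords[i], fit_idx)
            diff = fit_j[sel] - coords[i][sel]
            rmsd[i, j] = rmsd[j, i] = np.sqrt(
                np.mean(np.sum(diff * diff, axis=1)))
    return rmsd


def gromos_cluster(ensemble: FrameEnsemble, selection, cutoff: float = 6.2,
                   fit_selection=None,
                   rmsd_matrix: Optional[np.ndarray] = None) -> ClusterSet:
    """Greedy neighbor-counting (GROMOS) clustering on pairwise RMSD.

    Repeatedly the unassigned frame with the most unassigned neighbors
    within the cutoff becomes a cluster center; it and its neighbors are
    assigned and removed.  Ties break on the lowest frame index.
    """
    if ensemble.n_frames < 1:
        raise ValueError("empty ensemble")
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd(ensemble, selection, fit_selection)
    n = rmsd_matrix.shape[0]
    within = rmsd_matrix <= cutoff
    np.fill_diagonal(within, True)
    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=np.int64)
    centers = []
    cid = 0
    while np.any(unassigned):
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = within[center] & unassigned
        labels[members] = cid
        centers.append(center)
        unassigned &= ~members
        cid += 1
    populations = np.array([(labels == c).sum() for c in range(cid)]) / n
    return ClusterSet(labels=labels, centers=np.array(centers),
                      populations=populations, cutoff=float(cutoff))
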