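"""Catalytic-loop metrics: alignment, opening angle, contact distance,
helical content and correlation time.

The loop opening angle θ is measured at an anchor residue (Cα): the angle
between the vector to a tip residue (Cα) and the vector to the z-axis
projection of the loop-Cα center of a designated closed-reference structure.
Frames must first be aligned so the dimer's longest principal axis lies
along z with the centroid at the origin; θ then reports how far the loop
has swung away from the reference closed position over the active-site
mouth.

Helical content uses the Kabsch–Sander backbone H-bond energy

    E = 27.888 (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol, r in Å]

with an H-bond assigned below -0.5 kcal/mol; α-helix from two consecutive
i→i+4 turns and 3-10 helix from two consecutive i→i+3 turns.  Only helix
classes are assigned.  The energy involves distances only, so assignment is
invariant under mirror reflection — acceptable for helical content but not
a full chirality-aware DSSP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .trajectory_io import FrameEnsemble, select_atoms

__all__ = ["ThetaDefinition", "LoopMetricSeries", "TauEstimate",
           "align_principal_axis_z", "opening_angle", "min_distance",
           "helical_content", "correlation_time", "kabsch_sander_hbonds"]


@dataclass
class ThetaDefinition:
    """Geometry of the loop opening angle.

    reference_center: loop-Cα centroid of the closed-reference structure in
    the aligned frame convention; its z-axis projection (0, 0, z) anchors
    the closed direction.
    """

    anchor_selection: str = "name CA and resid 342"
    tip_selection: str = "name CA and resid 348"
    loop_selection: str = "name CA and resid 342-361"
    reference_center: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.anchor_selection == self.tip_selection:
            raise ValueError("anchor and tip must differ")
        if self.reference_center is not None:
            self.reference_center = np.asarray(self.reference_center,
                                               dtype=np.float64)

    def with_reference_from(self, closed_ref: FrameEnsemble,
                            frame: int = 0) -> "ThetaDefinition":
        """Compute the reference center from an aligned closed structure."""
        idx = select_atoms(closed_ref, self.loop_selection)
        if not idx:
            raise ValueError("loop selection matched no atoms in reference")
        center = closed_ref.frames[frame][idx].mean(axis=0)
        return ThetaDefinition(self.anchor_selection, self.tip_selection,
                               self.loop_selection, center)


@dataclass
class LoopMetricSeries:
    """Per-frame, per-monomer loop metrics."""

    time_ns: np.ndarray
    monomer: np.ndarray
    theta_deg: np.ndarray
    d_angstrom: np.ndarray
    helical_fraction: np.ndarray

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "time_ns": self.time_ns, "monomer": self.monomer,
            "theta_deg": self.theta_deg, "d_angstrom": self.d_angstrom,
            "helical_fraction": self.helical_fraction})


@dataclass
class TauEstimate:
    tau: float
    truncation_lag: int
    method: str = "integrated-acf"

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")


# ---------------------------------------------------------------------------
# alignment


def _principal_frame(coords: np.ndarray, prev_axes=None) -> np.ndarray:
    """Right-handed principal-axes basis (columns: x, y, z = shortest to
    longest gyration axis) with deterministic signs.

    Axis signs are fixed by the selection's third central moment along each
    axis (a rotation-invariant, structure-intrinsic choice), falling back on
    continuity with the previous frame's axes when the skewness is
    negligible.
    """
    c = coords - coords.mean(axis=0)
    gyr = c.T @ c / len(c)
    w, v = np.linalg.eigh(gyr)  # ascending: v[:,2] is the longest axis
    if w[2] - w[0] < 1e-12 * max(w[2], 1.0):
        raise ValueError("degenerate selection: no unique principal axis")
    axes = []
    for k in range(3):
        a = v[:, k]
        m3 = float(np.sum((c @ a) ** 3))
        scale = float(np.mean((c @ a) ** 2)) ** 1.5 * len(c)
        if abs(m3) > 1e-9 * max(scale, 1e-30):
            if m3 < 0:
                a = -a
        elif prev_axes is not None and float(a @ prev_axes[:, k]) < 0:
            a = -a
        axes.append(a)
    basis = np.column_stack(axes)
    if np.linalg.det(basis) < 0:
        basis[:, 0] = np.cross(basis[:, 1], basis[:, 2])
    return basis


def align_principal_axis_z(ensemble: FrameEnsemble,
                           selection) -> FrameEnsemble:
    """Rotate each frame into the selection's principal-axes frame, longest
    gyration axis along +z, centroid at the origin.

    All three axes are fixed (not just z) so the aligned coordinates — and
    any angle measured against the z axis — are independent of the input
    frame's rigid-body pose.
    """
    idx = select_atoms(ensemble, selection) if isinstance(selection, str) \
        else list(selection)
    if len(idx) < 3:
        raise ValueError("selection needs >= 3 atoms")
    out = np.empty_like(ensemble.frames)
    prev = None
    for fi in range(ensemble.n_frames):
        coords = ensemble.frames[fi]
        sel = coords[idx]
        basis = _principal_frame(sel, prev)
        prev = basis
        centroid = sel.mean(axis=0)
        out[fi] = (coords - centroid) @ basis  # = basis.T @ (x - c), rowwise
    return FrameEnsemble(ensemble.atoms, out, ensemble.box.copy(),
                         ensemble.frame_interval)


# ---------------------------------------------------------------------------
# per-frame metrics


def opening_angle(frame_coords: np.ndarray, anchor: np.ndarray,
                  tip: np.ndarray, theta_def: ThetaDefinition) -> float:
    """θ in degrees between (tip - anchor) and ((0,0,z_ref) - anchor).

    Coordinates must already be in the aligned frame convention; z_ref is
    the z component of the closed-reference loop center.
    """
    if theta_def.reference_center is None:
        raise ValueError("theta definition lacks a reference center; call "
                         "with_reference_from on the closed structure first")
    v1 = np.asarray(tip, dtype=np.float64) - np.asarray(anchor,
                                                        dtype=np.float64)
    ref = np.array([0.0, 0.0, theta_def.reference_center[2]])
    v2 = ref - np.asarray(anchor, dtype=np.float64)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length vector in opening angle")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def opening_angle_series(ensemble: FrameEnsemble,
                         theta_def: ThetaDefinition) -> np.ndarray:
    anchor_idx = select_atoms(ensemble, theta_def.anchor_selection)
    tip_idx = select_atoms(ensemble, theta_def.tip_selection)
    if len(anchor_idx) != 1 or len(tip_idx) != 1:
        raise ValueError("anchor/tip selections must match exactly one atom")
    return np.array([
        opening_angle(ensemble.frames[fi], ensemble.frames[fi][anchor_idx[0]],
                      ensemble.frames[fi][tip_idx[0]], theta_def)
        for fi in range(ensemble.n_frames)])


def min_distance(frame_coords: np.ndarray, groupA: Sequence[int],
                 groupB: Sequence[int]) -> float:
    """Minimum Euclidean cross-group atom distance (no periodic imaging)."""
    if len(groupA) == 0 or len(groupB) == 0:
        raise ValueError("both groups must be non-empty")
    a = np.asarray(frame_coords)[list(groupA)]
    b = np.asarray(frame_coords)[list(groupB)]
    return float(cdist(a, b).min())


# ---------------------------------------------------------------------------
# Kabsch–Sander helical content

_KS_FACTOR = 27.888  # kcal/mol * Å: 0.42 * 0.20 * 332 (q1 q2 f)
_HBOND_CUTOFF = -0.5


def _backbone_indices(ensemble: FrameEnsemble, residue_range,
                      chain: Optional[str] = None):
    lo, hi = residue_range
    residues = []
    for rnum in range(lo, hi + 1):
        atoms = {}
        for a in ensemble.atoms:
            if a.residue_number == rnum and (chain is None
                                             or a.chain_id == chain):
                atoms[a.name] = a.index
        residues.append((rnum, atoms))
    return residues


def _amide_h(n_pos, ca_pos, c_prev_pos) -> np.ndarray:
    """Rebuild the amide H 1.01 Å from N, opposing the C_prev/CA bisector."""
    d1 = n_pos - c_prev_pos
    d2 = n_pos - ca_pos
    d1 /= np.linalg.norm(d1)
    d2 /= np.linalg.norm(d2)
    h_dir = d1 + d2
    h_dir /= np.linalg.norm(h_dir)
    return n_pos + 1.01 * h_dir


def kabsch_sander_hbonds(frame_coords: np.ndarray, residues) -> np.ndarray:
    """Backbone H-bond matrix: hb[i, j] True when N-H(i) ... O=C(j).

    residues: list of (resnum, {atom_name: index}) in chain order.  The
    donor H is taken from the structure when present, rebuilt from geometry
    otherwise (impossible for the first residue and prolines).
    """
    n = len(residues)
    hb = np.zeros((n, n), dtype=bool)
    pos = np.asarray(frame_coords)
    for i in range(n):
        _, di = residues[i]
        if not {"N", "CA"} <= di.keys():
            raise ValueError("missing backbone atoms for donor residue")
        if "H" in di or "HN" in di:
            h = pos[di.get("H", di.get("HN"))]
        else:
            if i == 0:
                continue
            _, dprev = residues[i - 1]
            if "C" not in dprev:
                continue
            h = _amide_h(pos[di["N"]].copy(), pos[di["CA"]], pos[dprev["C"]])
        npos = pos[di["N"]]
        for j in range(n):
            if abs(i - j) < 2:
                continue
            _, dj = residues[j]
            if not {"C", "O"} <= dj.keys():
                raise ValueError("missing backbone atoms for acceptor residue")
            o = pos[dj["O"]]
            c = pos[dj["C"]]
            r_on = np.linalg.norm(o - npos)
            r_ch = np.linalg.norm(c - h)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(c - npos)
            if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
                continue
            e = _KS_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if e < _HBOND_CUTOFF:
                hb[i, j] = True
    return hb


def helical_content(ensemble: FrameEnsemble, residue_range,
                    frame: int = 0, chain: Optional[str] = None) -> float:
    """Fraction of range residues assigned α- or 3-10-helix.

    A p-turn at i means an H-bond from N-H(i+p) to C=O(i); a minimal helix
    needs two consecutive turns (at i-1 and i), marking residues i..i+p-1
    helical (p = 4 for α, 3 for 3-10).
    """
    residues = _backbone_indices(ensemble, residue_range, chain)
    n = len(residues)
    if n == 0:
        raise ValueError("empty residue range")
    for rnum, d in residues:
        if not {"N", "CA", "C", "O"} <= d.keys():
            raise ValueError(f"missing backbone atoms in residue {rnum}")
    if n < 3:
        return 0.0
    hb = kabsch_sander_hbonds(ensemble.frames[frame], residues)
    helical = np.zeros(n, dtype=bool)
    for p in (4, 3):
        turn = np.zeros(n, dtype=bool)
        for i in range(n - p):
            if hb[i + p, i]:
                turn[i] = True
        for i in range(1, n - p):
            if turn[i - 1] and turn[i]:
                helical[i:i + p] = True
    return float(np.count_nonzero(helical)) / n


def helical_content_series(ensemble: FrameEnsemble, residue_range,
                           chain: Optional[str] = None) -> np.ndarray:
    return np.array([helical_content(ensemble, residue_range, fi, chain)
                     for fi in range(ensemble.n_frames)])


# ---------------------------------------------------------------------------
# correlation time


def autocorrelation(series: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation function via FFT."""
    x = np.asarray(series, dtype=np.float64)
    x = x - x.mean()
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    if acov[0] <= 0:
        raise ValueError("series has zero variance")
    return acov / acov[0]


def integrated_tau(rho: np.ndarray, dt: float = 1.0) -> TauEstimate:
    """τ = dt (1/2 + Σ_{k=1}^{K-1} ρ_k), truncated at the first negative ρ_k.

    On an exact exponential ACF ρ_k = exp(-k dt/τ) this recovers τ to the
    quadrature error of the sum; on white noise (ρ_k = δ_k0) it gives dt/2.
    """
    rho = np.asarray(rho, dtype=np.float64)
    neg = np.nonzero(rho[1:] < 0)[0]
    K = int(neg[0]) + 1 if neg.size else len(rho)
    tau = dt * (0.5 + float(np.sum(rho[1:K])))
    return TauEstimate(tau=max(tau, 1e-12 * dt), truncation_lag=K)


def correlation_time(series: np.ndarray, dt: float = 1.0) -> TauEstimate:
    """Integrated-ACF correlation time with initial-positive truncation."""
    x = np.asarray(series, dtype=np.float64)
    if len(x) < 50:
        raise ValueError("series too short (need >= 50 points)")
    return integrated_tau(autocorrelation(x), dt)


# ---------------------------------------------------------------------------
# bundled per-monomer metrics


def loop_metrics(ensemble: FrameEnsemble, theta_def: ThetaDefinition,
                 contact_a_selection: str, contact_b_selection: str,
                 helix_range=None, monomer_label: str = "A",
                 chain: Optional[str] = None) -> LoopMetricSeries:
    """θ, d and helical fraction per frame for one monomer.

    helix_range=None (e.g. Cα-only input without backbone N/C/O) records
    NaN helical fractions.
    """
    theta = opening_angle_series(ensemble, theta_def)
    ia = select_atoms(ensemble, contact_a_selection)
    ib = select_atoms(ensemble, contact_b_selection)
    d = np.array([min_distance(ensemble.frames[fi], ia, ib)
                  for fi in range(ensemble.n_frames)])
    if helix_range is None:
        hel = np.full(ensemble.n_frames, np.nan)
    else:
        hel = helical_content_series(ensemble, helix_range, chain)
    time_ns = np.arange(ensemble.n_frames) * ensemble.frame_interval / 1000.0
    return LoopMetricSeries(time_ns=time_ns,
                            monomer=np.array([monomer_label]
                                             * ensemble.n_frames),
                            theta_deg=theta, d_angstrom=d,
                            helical_fraction=hel)
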