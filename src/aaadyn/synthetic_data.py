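"""Seeded generators for every input class the pipeline consumes.

Four synthetic systems cover the pipeline's assumptions without external
downloads:

* a rigid three-site water box sampled by Metropolis Monte Carlo — the bulk
  solvent for gas-solvation free energies;
* a single-site Lennard-Jones fluid — the oracle substrate for Widom
  insertion cross-checks;
* a static cavity-plus-channel wall system — the geometric stand-in for a
  protein matrix with a gas migration pathway;
* loop trajectories interpolating two endpoint conformations under an
  Ornstein-Uhlenbeck (OU) collective coordinate with known relaxation time
  — the stand-in for open/closed catalytic-loop dynamics.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .constants import COULOMB, KB
from .trajectory_io import AtomRecord, FrameEnsemble

__all__ = [
    "WaterBoxSpec", "LjFluidSpec", "CavityChannelSpec", "LoopTrajSpec",
    "gen_water_box", "gen_lj_fluid", "gen_cavity_channel",
    "gen_loop_trajectory", "gen_ideal_helix", "water_geometry",
    "default_loop_endpoints",
]

# rigid three-site water: TIP3P geometry and charges, CHARMM O-site LJ
WATER_Q = np.array([-0.834, 0.417, 0.417])  # e: O, H1, H2
WATER_O_RMIN_HALF = 1.7682  # Å
WATER_O_EPSILON = 0.1521  # kcal/mol
WATER_OH = 0.9572  # Å
WATER_HOH = np.radians(104.52)
WATER_MOLAR_MASS = 18.01528  # g/mol
AVOGADRO = 6.02214076e23


def water_geometry() -> np.ndarray:
    """Site coordinates of one water, O at the origin (Å)."""
    half = WATER_HOH / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [WATER_OH * np.sin(half), 0.0, WATER_OH * np.cos(half)],
        [-WATER_OH * np.sin(half), 0.0, WATER_OH * np.cos(half)],
    ])


@dataclass
class WaterBoxSpec:
    n_molecules: int = 216
    temperature: float = 300.0
    density: float = 0.997  # g/cm^3
    mc_sweeps: int = 50000  # production sweeps
    equilibration_sweeps: int = 3000
    sampling_interval: int = 100  # sweeps between stored frames
    cutoff: float = 9.0  # Å, molecule-based, with reaction field
    eps_rf: float = 78.5  # reaction-field dielectric
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 2:
            raise ValueError("need at least 2 molecules")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def box_length(self) -> float:
        vol = self.n_molecules * WATER_MOLAR_MASS / (
            self.density * AVOGADRO) * 1e24  # Å^3
        return vol ** (1.0 / 3.0)

    @property
    def n_frames(self) -> int:
        return self.mc_sweeps // self.sampling_interval


def _water_lj_ab():
    rmin = 2.0 * WATER_O_RMIN_HALF
    a = WATER_O_EPSILON * rmin ** 12
    b = 2.0 * WATER_O_EPSILON * rmin ** 6
    return a, b


def _rf_constants(rc: float, eps_rf: float):
    krf = (eps_rf - 1.0) / (2.0 * eps_rf + 1.0) / rc ** 3
    crf = 1.0 / rc + krf * rc * rc
    return krf, crf


def _water_atoms(n_molecules: int) -> list[AtomRecord]:
    atoms = []
    names = ["O", "H1", "H2"]
    rmh = [WATER_O_RMIN_HALF, 0.0, 0.0]
    eps = [WATER_O_EPSILON, 0.0, 0.0]
    for m in range(n_molecules):
        for s in range(3):
            atoms.append(AtomRecord(index=3 * m + s, name=names[s],
                                    residue_name="HOH",
                                    residue_number=m + 1, chain_id="W",
                                    element=names[s][0],
                                    lj_rmin_half=rmh[s], lj_epsilon=eps[s],
                                    partial_charge=float(WATER_Q[s])))
    return atoms


def _lattice_waters(n: int, L: float, rng: np.random.Generator) -> np.ndarray:
    per_side = math.ceil(n ** (1.0 / 3.0))
    spacing = L / per_side
    geom = water_geometry()
    pos = np.empty((n, 3, 3))
    m = 0
    for i in range(per_side):
        for j in range(per_side):
            for k in range(per_side):
                if m >= n:
                    break
                center = (np.array([i, j, k]) + 0.5) * spacing
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = rng.uniform(0, 2 * np.pi)
                R = _axis_angle_matrix(axis, angle)
                pos[m] = center + geom @ R.T
                m += 1
    return pos


def _axis_angle_matrix(axis, angle) -> np.ndarray:
    ax = np.asarray(axis, dtype=np.float64)
    ax = ax / np.linalg.norm(ax)
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]],
                  [-ax[1], ax[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def water_config_energy(pos: np.ndarray, L: float, cutoff: float,
                        eps_rf: float) -> float:
    """Total energy (kcal/mol) of a rigid-water configuration."""
    a, b = _water_lj_ab()
    krf, crf = _rf_constants(cutoff, eps_rf)
    return float(_kernels.water_total_energy(
        np.ascontiguousarray(pos), L, cutoff, WATER_Q, a, b, krf, crf))


def gen_water_box(spec: WaterBoxSpec) -> FrameEnsemble:
    """Sample a rigid-water box by Metropolis MC at fixed density.

    Electrostatics use a molecule-based cutoff with a reaction-field
    correction (dielectric ``eps_rf``); O-O dispersion is truncated
    unshifted at the same cutoff.  Frames are written every
    ``sampling_interval`` sweeps after equilibration.
    """
    L = spec.box_length
    if spec.cutoff > L / 2:
        raise ValueError("cutoff exceeds the minimum-image bound L/2")
    rng = np.random.default_rng(spec.seed)
    pos0 = _lattice_waters(spec.n_molecules, L, rng)
    a, b = _water_lj_ab()
    krf, crf = _rf_constants(spec.cutoff, spec.eps_rf)
    beta = 1.0 / (KB * spec.temperature)
    frames, acceptance = _kernels.run_water_mc(
        np.ascontiguousarray(pos0), L, spec.cutoff, WATER_Q, a, b, krf, crf,
        beta, spec.equilibration_sweeps, spec.n_frames,
        spec.sampling_interval, spec.seed % (2 ** 31), 0.15, 0.25)
    ens = FrameEnsemble(_water_atoms(spec.n_molecules),
                        frames.reshape(spec.n_frames, -1, 3),
                        np.full(3, L),
                        frame_interval=float(spec.sampling_interval))
    ens.metadata = {"acceptance": float(acceptance), "box_length": L,
                    "spec": spec}
    return ens


# ---------------------------------------------------------------------------
# LJ fluid


@dataclass
class LjFluidSpec:
    n_particles: int = 100
    rmin_half: float = 1.7
    epsilon: float = 0.12
    reduced_density: float = 0.5  # rho * sigma^3, sigma = Rmin/2^(1/6)
    temperature: float = 300.0
    mc_sweeps: int = 2000
    equilibration_sweeps: int = 500
    sampling_interval: int = 10
    cutoff: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.reduced_density >= 0.9:
            raise ValueError("reduced density must be < 0.9")

    @property
    def sigma(self) -> float:
        return 2.0 * self.rmin_half / 2.0 ** (1.0 / 6.0)

    @property
    def box_length(self) -> float:
        if self.reduced_density <= 0:
            raise ValueError("reduced density must be positive")
        return (self.n_particles * self.sigma ** 3
                / self.reduced_density) ** (1.0 / 3.0)

    @property
    def n_frames(self) -> int:
        return self.mc_sweeps // self.sampling_interval


def gen_lj_fluid(spec: LjFluidSpec) -> FrameEnsemble:
    """Metropolis MC of a single-site LJ fluid in a periodic cube."""
    L = spec.box_length
    rc = spec.cutoff if spec.cutoff is not None else min(3 * spec.sigma,
                                                         L / 2)
    rng = np.random.default_rng(spec.seed)
    pos0 = rng.uniform(0, L, size=(spec.n_particles, 3))
    rmin = 2.0 * spec.rmin_half
    if spec.epsilon > 0:
        a = spec.epsilon * rmin ** 12
        b = 2.0 * spec.epsilon * rmin ** 6
    else:
        a = b = 0.0
    beta = 1.0 / (KB * spec.temperature)
    frames, acceptance = _kernels.run_lj_mc(
        np.ascontiguousarray(pos0), L, rc, a, b, beta,
        spec.equilibration_sweeps, spec.n_frames, spec.sampling_interval,
        spec.seed % (2 ** 31), 0.3 * spec.sigma)
    atoms = [AtomRecord(index=i, name="AR", residue_name="LJP",
                        residue_number=i + 1, chain_id="L", element="Ar",
                        lj_rmin_half=spec.rmin_half, lj_epsilon=spec.epsilon,
                        partial_charge=0.0)
             for i in range(spec.n_particles)]
    ens = FrameEnsemble(atoms, frames, np.full(3, L),
                        frame_interval=float(spec.sampling_interval))
    ens.metadata = {"acceptance": float(acceptance), "box_length": L,
                    "cutoff": rc, "spec": spec}
    return ens


# ---------------------------------------------------------------------------
# cavity + channel wall system


@dataclass
class CavityChannelSpec:
    cavity_radius: float = 12.0  # Å
    channel_radius: float = 4.5  # Å, 0 seals the cavity
    channel_length: Optional[float] = None  # Å, default: to the box face
    wall_rmin_half: float = 1.7
    wall_epsilon: float = 0.15
    wall_spacing: float = 1.0  # Å between wall sites (watertight for O2)
    box_length: float = 40.0
    shell_layers: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.channel_radius >= self.cavity_radius:
            raise ValueError("channel radius must be < cavity radius")
        contact = 2 * self.wall_rmin_half
        if self.wall_spacing >= contact:
            raise ValueError("wall spacing must stay below the probe "
                             "contact distance (watertight walls)")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def gen_cavity_channel(spec: CavityChannelSpec) -> FrameEnsemble:
    """Static wall-atom system: a spherical cavity with one bored channel.

    Wall sites sit on ``shell_layers`` concentric spherical shells spaced
    ``wall_spacing`` apart, with a cylindrical hole of ``channel_radius``
    along +x continued as a tube of wall sites out to the box face.  Shell
    sites carry resname SPH (grouped into pseudo-residues of ~24 sites);
    channel-tube rings carry resname CHW, one residue per ring — so
    pathway-lining analysis can name the wall patches it finds.
    """
    center = np.full(3, spec.box_length / 2.0)
    coords = []
    resnames = []
    resnums = []
    resnum = 1
    for layer in range(spec.shell_layers):
        r = spec.cavity_radius + layer * spec.wall_spacing
        n_sites = max(8, int(np.ceil(4 * np.pi * r * r
                                     / spec.wall_spacing ** 2)))
        pts = _fibonacci_sphere(n_sites) * r
        if spec.channel_radius > 0:
            keep = ~((pts[:, 0] > 0)
                     & (np.hypot(pts[:, 1], pts[:, 2])
                        < spec.channel_radius + spec.wall_spacing / 2))
            pts = pts[keep]
        for start in range(0, len(pts), 24):
            chunk = pts[start:start + 24]
            coords.append(chunk + center)
            resnames.extend(["SPH"] * len(chunk))
            resnums.extend([resnum] * len(chunk))
            resnum += 1
    if spec.channel_radius > 0:
        x0 = math.sqrt(max(spec.cavity_radius ** 2
                           - spec.channel_radius ** 2, 0.0))
        x1 = (spec.box_length / 2.0 if spec.channel_length is None
              else x0 + spec.channel_length)
        n_ring = max(6, int(np.ceil(2 * np.pi * spec.channel_radius
                                    / spec.wall_spacing)))
        ang = 2 * np.pi * np.arange(n_ring) / n_ring
        for lay in range(spec.shell_layers):
            rr = spec.channel_radius + lay * spec.wall_spacing
            xs = np.arange(x0, x1 + 1e-9, spec.wall_spacing)
            for x in xs:
                ring = np.column_stack([np.full(n_ring, x),
                                        rr * np.cos(ang),
                                        rr * np.sin(ang)])
                coords.append(ring + center)
                resnames.extend(["CHW"] * n_ring)
                resnums.extend([resnum] * n_ring)
                resnum += 1
    pts = np.vstack(coords)
    atoms = [AtomRecord(index=i, name="W", residue_name=resnames[i],
                        residue_number=resnums[i], chain_id="X", element="C",
                        lj_rmin_half=spec.wall_rmin_half,
                        lj_epsilon=spec.wall_epsilon, partial_charge=0.0)
             for i in range(len(pts))]
    ens = FrameEnsemble(atoms, pts[None, :, :],
                        np.full(3, spec.box_length), frame_interval=0.0)
    ens.metadata = {"center": center, "spec": spec}
    return ens


# ---------------------------------------------------------------------------
# loop trajectories


def default_loop_endpoints(n_atoms: int = 20, opening_deg: float = 90.0,
                           hinge: int = 10) -> tuple:
    """A hinged Cα arc in two conformations: closed (A) and open (B).

    The first ``hinge`` atoms are shared; in B the distal segment swings
    about the hinge atom by ``opening_deg`` (rotation about y).  Because
    only part of the chain moves, the A→B difference survives least-squares
    superposition — it is a genuine conformational change, not a rigid-body
    motion — and the opening angle of the tip varies monotonically with the
    interpolation coordinate.
    """
    t = np.linspace(0, 1, n_atoms)
    # gentle arc rising in +z, Cα spacing ~3.8 Å
    length = 3.8 * (n_atoms - 1)
    arc = np.column_stack([np.sin(t * 1.2) / 1.2,
                           0.15 * np.sin(t * 2 * np.pi),
                           (1 - np.cos(t * 1.2)) / 1.2 + t])
    arc -= arc[0]
    arc *= length / np.linalg.norm(arc[-1] - arc[0]) / 1.6
    pivot = arc[hinge].copy()
    R = _axis_angle_matrix([0, 1, 0], np.radians(opening_deg))
    endpoint_b = arc.copy()
    endpoint_b[hinge:] = (arc[hinge:] - pivot) @ R.T + pivot
    return arc, endpoint_b


@dataclass
class LoopTrajSpec:
    endpoint_a: Optional[np.ndarray] = None  # (n_atoms, 3), closed
    endpoint_b: Optional[np.ndarray] = None  # (n_atoms, 3), open
    tau_true: float = 50.0  # OU relaxation time, frames
    mean_s: float = 0.5  # OU stationary mean of the coordinate
    sd_s: float = 0.2  # OU stationary sd
    noise_sd: float = 0.3  # per-atom thermal noise, Å
    n_frames: int = 2000
    dt: float = 0.01  # ns per frame
    first_resid: int = 342
    seed: int = 0

    def __post_init__(self):
        if self.tau_true < 1:
            raise ValueError("tau_true must be >= 1 frame")
        if self.endpoint_a is None or self.endpoint_b is None:
            a, b = default_loop_endpoints()
            self.endpoint_a = a if self.endpoint_a is None else self.endpoint_a
            self.endpoint_b = b if self.endpoint_b is None else self.endpoint_b
        self.endpoint_a = np.asarray(self.endpoint_a, dtype=np.float64)
        self.endpoint_b = np.asarray(self.endpoint_b, dtype=np.float64)
        if self.endpoint_a.shape != self.endpoint_b.shape:
            raise ValueError("endpoints must have the same atom count")


def _reflected_ou(spec: LoopTrajSpec, rng: np.random.Generator) -> np.ndarray:
    """Exact AR(1) discretization of an OU process, reflected into [0, 1]."""
    phi = math.exp(-1.0 / spec.tau_true)
    innov_sd = spec.sd_s * math.sqrt(1.0 - phi * phi)
    s = np.empty(spec.n_frames)
    x = spec.mean_s + spec.sd_s * rng.standard_normal()
    for t in range(spec.n_frames):
        x = spec.mean_s + phi * (x - spec.mean_s) \
            + innov_sd * rng.standard_normal()
        # reflect into [0, 1]
        y = x % 2.0
        s[t] = y if y <= 1.0 else 2.0 - y
    return s


def gen_loop_trajectory(spec: LoopTrajSpec) -> tuple[FrameEnsemble, dict]:
    """Loop Cα trajectory between two conformations with known dynamics.

    frames = A + s_t (B - A) + Gaussian noise, with s_t a reflected OU
    process of relaxation time ``tau_true`` (frames).  The ground-truth dict
    records s_t, tau_true and per-frame basin labels (s < 1/2 -> 0, else 1).
    """
    rng = np.random.default_rng(spec.seed)
    s = _reflected_ou(spec, rng)
    n_atoms = spec.endpoint_a.shape[0]
    disp = spec.endpoint_b - spec.endpoint_a
    noise = spec.noise_sd * rng.standard_normal(
        size=(spec.n_frames, n_atoms, 3))
    frames = (spec.endpoint_a[None, :, :]
              + s[:, None, None] * disp[None, :, :] + noise)
    span = np.abs(frames.reshape(-1, 3)).max() * 2 + 20
    frames += span / 2.0  # keep coordinates positive inside the box
    atoms = [AtomRecord(index=i, name="CA", residue_name="ALA",
                        residue_number=spec.first_resid + i, chain_id="A",
                        element="C")
             for i in range(n_atoms)]
    ens = FrameEnsemble(atoms, frames, np.full(3, span),
                        frame_interval=spec.dt * 1000.0)
    ground_truth = {"s": s, "tau_true": spec.tau_true,
                    "basin": (s >= 0.5).astype(int),
                    "offset": span / 2.0, "spec": spec}
    ens.metadata = dict(ground_truth)
    return ens, ground_truth


# ---------------------------------------------------------------------------
# ideal backbone builder

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = np.radians(111.2)
_ANG_CA_C_N = np.radians(116.2)
_ANG_C_N_CA = np.radians(121.7)
_ANG_CA_C_O = np.radians(120.8)


def _place_atom(a, b, c, bond, angle, dihedral) -> np.ndarray:
    """NeRF: position d given three predecessors and internal coordinates."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(angle),
                   bond * np.sin(angle) * np.cos(dihedral),
                   bond * np.sin(angle) * np.sin(dihedral)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def gen_ideal_helix(n_residues: int, phi: float = -57.0,
                    psi: float = -47.0, omega: float = 180.0,
                    resname: str = "ALA") -> FrameEnsemble:
    """Poly-peptide backbone (N, CA, C, O) at fixed (φ, ψ) dihedrals.

    (−57°, −47°) builds an ideal α-helix; (180°, 180°) a fully extended
    chain.  Single frame, box padded around the chain.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    phi_r, psi_r, omega_r = map(np.radians, (phi, psi, omega))
    # first residue seeded in the xy plane
    n0 = np.zeros(3)
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    c0 = ca0 + _BOND_CA_C * np.array([np.cos(np.pi - _ANG_N_CA_C),
                                      np.sin(np.pi - _ANG_N_CA_C), 0.0])
    backbone = [[n0, ca0, c0]]
    for _ in range(1, n_residues):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_new = _place_atom(n_prev, ca_prev, c_prev, _BOND_C_N,
                            _ANG_CA_C_N, psi_r)
        ca_new = _place_atom(ca_prev, c_prev, n_new, _BOND_N_CA,
                             _ANG_C_N_CA, omega_r)
        c_new = _place_atom(c_prev, n_new, ca_new, _BOND_CA_C,
                            _ANG_N_CA_C, phi_r)
        backbone.append([n_new, ca_new, c_new])
    coords = []
    atoms = []
    idx = 0
    for ri, (n, ca, c) in enumerate(backbone):
        o = _place_atom(n, ca, c, _BOND_C_O, _ANG_CA_C_O, psi_r + np.pi)
        for name, pos in (("N", n), ("CA", ca), ("C", c), ("O", o)):
            atoms.append(AtomRecord(index=idx, name=name, residue_name=resname,
                                    residue_number=ri + 1, chain_id="A",
                                    element=name[0]))
            coords.append(pos)
            idx += 1
    coords = np.asarray(coords)
    pad = 20.0
    shift = coords.min(axis=0) - pad / 2
    coords = coords - shift
    box = coords.max(axis=0) + pad / 2
    return FrameEnsemble(atoms, coords[None, :, :], box, frame_interval=0.0)
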