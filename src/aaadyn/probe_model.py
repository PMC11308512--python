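"""The diatomic O2 probe: geometry, LJ parameters, orientations, energies.

The probe is a rigid, apolar Lennard-Jones molecule.  The default O2 model
uses two identical sites at ±0.605 Å (bond length 1.21 Å) along the
molecular axis, each with Rmin/2 = 1.7 Å and a well depth of 0.12 kcal/mol.
The literature value "σ = 1.7 Å" is interpreted as the CHARMM Rmin/2
convention by default — note that σ usually denotes the 12-6 zero crossing;
pass ``sigma_convention="lj"`` to ``ProbeModel.o2`` for that reading
(Rmin/2 = 2^(1/6)·σ/2).

Because a homonuclear diatomic has C2 rotary symmetry, orientations are
drawn from one hemisphere only: a deterministic spherical-Fibonacci set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProbeModel",
    "OrientationSet",
    "generate_orientations",
    "lj_pair_energy",
    "probe_insertion_energy",
    "rotation_from_z",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class ProbeModel:
    """Rigid multi-site LJ probe.

    site_offsets: (S, 3) offsets from the probe center in the local frame,
    whose z axis is mapped onto the orientation axis.
    """

    site_offsets: np.ndarray
    site_rmin_half: np.ndarray
    site_epsilon: np.ndarray
    symmetry_order: int = 1
    name: str = "probe"

    def __post_init__(self):
        self.site_offsets = np.atleast_2d(
            np.asarray(self.site_offsets, dtype=np.float64))
        self.site_rmin_half = np.atleast_1d(
            np.asarray(self.site_rmin_half, dtype=np.float64))
        self.site_epsilon = np.abs(np.atleast_1d(
            np.asarray(self.site_epsilon, dtype=np.float64)))
        s = self.site_offsets.shape[0]
        if self.site_rmin_half.shape != (s,) or self.site_epsilon.shape != (s,):
            raise ValueError("per-site LJ arrays must match the site count")

    @property
    def n_sites(self) -> int:
        return self.site_offsets.shape[0]

    @classmethod
    def o2(cls, rmin_half: float = 1.7, epsilon: float = 0.12,
           bond_length: float = 1.21,
           sigma_convention: str = "rmin_half") -> "ProbeModel":
        """Molecular oxygen: two identical LJ sites, no charges."""
        if sigma_convention == "rmin_half":
            rmh = rmin_half
        elif sigma_convention == "lj":
            rmh = 2.0 ** (1.0 / 6.0) * rmin_half / 2.0
        else:
            raise ValueError("sigma_convention must be 'rmin_half' or 'lj'")
        h = bond_length / 2.0
        return cls(site_offsets=np.array([[0.0, 0.0, -h], [0.0, 0.0, h]]),
                   site_rmin_half=np.array([rmh, rmh]),
                   site_epsilon=np.array([abs(epsilon)] * 2),
                   symmetry_order=2, name="O2")

    @classmethod
    def single_site(cls, rmin_half: float, epsilon: float,
                    name: str = "atom") -> "ProbeModel":
        return cls(np.zeros((1, 3)), np.array([rmin_half]),
                   np.array([abs(epsilon)]), symmetry_order=1, name=name)

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeModel":
        if "bond_length" in d:
            return cls.o2(rmin_half=d.get("rmin_half", 1.7),
                          epsilon=d.get("epsilon", 0.12),
                          bond_length=d["bond_length"],
                          sigma_convention=d.get("sigma_convention",
                                                 "rmin_half"))
        sites = d["sites"]
        return cls(np.array([s["offset"] for s in sites]),
                   np.array([s["rmin_half"] for s in sites]),
                   np.array([s["epsilon"] for s in sites]),
                   symmetry_order=d.get("symmetry_order", 1),
                   name=d.get("name", "probe"))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "symmetry_order": int(self.symmetry_order),
            "sites": [
                {"offset": list(map(float, o)), "rmin_half": float(r),
                 "epsilon": float(e)}
                for o, r, e in zip(self.site_offsets, self.site_rmin_half,
                                   self.site_epsilon)
            ],
        }


@dataclass
class OrientationSet:
    """Unit axes over which probe orientations are Boltzmann-averaged."""

    axes: np.ndarray

    def __post_init__(self):
        self.axes = np.atleast_2d(np.asarray(self.axes, dtype=np.float64))
        norms = np.linalg.norm(self.axes, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientation axes must be unit vectors")
        dots = self.axes @ self.axes.T
        off = dots - np.eye(len(self.axes))
        if np.any(np.abs(off) > 1.0 - 1e-9):
            raise ValueError("duplicate or antipodal orientation axes")

    def __len__(self) -> int:
        return self.axes.shape[0]


def generate_orientations(count: int) -> OrientationSet:
    """Deterministic spherical-Fibonacci axes on the upper hemisphere.

    C2 symmetry of a homonuclear diatomic means axis and -axis are the same
    orientation, so only one hemisphere is covered.  count=1 gives (0,0,1).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    i = np.arange(count, dtype=np.float64)
    z = 1.0 - i / count  # in (0, 1]: strictly upper hemisphere
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * _GOLDEN_ANGLE
    axes = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return OrientationSet(axes)


def lj_pair_energy(rmin_half_i: float, eps_i: float, rmin_half_j: float,
                   eps_j: float, r: float) -> float:
    """12-6 LJ energy in CHARMM convention (kcal/mol).

    Rmin_ij = rmin_half_i + rmin_half_j, eps_ij = sqrt(eps_i*eps_j),
    E(r) = eps_ij [(Rmin/r)^12 - 2 (Rmin/r)^6]; the minimum is -eps_ij at
    r = Rmin_ij.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    rmin = rmin_half_i + rmin_half_j
    epsij = np.sqrt(abs(eps_i) * abs(eps_j))
    sr6 = (rmin / r) ** 6
    return epsij * (sr6 * sr6 - 2.0 * sr6)


def rotation_from_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix mapping +z onto the given unit axis."""
    axis = np.asarray(axis, dtype=np.float64)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, axis))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # axis = -z: rotate by pi about x
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, axis)
    vx = np.array([[0.0, -v[2], v[1]],
                   [v[2], 0.0, -v[0]],
                   [-v[1], v[0], 0.0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def rotated_site_offsets(probe: ProbeModel,
                         orientations: OrientationSet) -> np.ndarray:
    """Probe-site offsets in the lab frame, shape (C, S, 3)."""
    out = np.empty((len(orientations), probe.n_sites, 3))
    for k, axis in enumerate(orientations.axes):
        out[k] = probe.site_offsets @ rotation_from_z(axis).T
    return out


def probe_insertion_energy(frame: np.ndarray, probe: ProbeModel,
                           position, axis, cutoff: float, box,
                           rmin_half: np.ndarray,
                           epsilon: np.ndarray) -> float:
    """Interaction energy of inserting the probe at ``position``/``axis``.

    frame: (n_atoms, 3) coordinates; rmin_half/epsilon: per-atom LJ terms
    (epsilon 0 excludes an atom).  Minimum-image convention, pairwise
    truncation at ``cutoff`` (unshifted).  Overlaps give large positive
    values; the caller caps them.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    axis = np.asarray(axis, dtype=np.float64)
    n = np.linalg.norm(axis)
    if abs(n - 1.0) > 1e-6:
        raise ValueError("axis must be unit-norm")
    frame = np.asarray(frame, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    position = np.asarray(position, dtype=np.float64)
    if frame.size == 0:
        return 0.0
    R = rotation_from_z(axis)
    sites = position + probe.site_offsets @ R.T
    active = epsilon > 0
    if not np.any(active):
        return 0.0
    pos = frame[active]
    rmh = rmin_half[active]
    eps = epsilon[active]
    e = 0.0
    for s in range(probe.n_sites):
        d = pos - sites[s]
        d -= box * np.rint(d / box)
        r2 = np.einsum("ij,ij->i", d, d)
        mask = (r2 < cutoff * cutoff) & (r2 > 0)
        if not np.any(mask):
            continue
        rmin = rmh[mask] + probe.site_rmin_half[s]
        epsij = np.sqrt(eps[mask] * probe.site_epsilon[s])
        sr6 = (rmin * rmin / r2[mask]) ** 3
        e += float(np.sum(epsij * (sr6 * sr6 - 2.0 * sr6)))
    return e
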