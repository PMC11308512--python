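"""Structure, trajectory, parameter-table and volumetric-map I/O.

Coordinates are ångström everywhere.  Atom indices are 0-based internally;
residue numbers stay 1-based as authored in the PDB.  Boxes are orthorhombic
only: the CRYST1 record is read when present, otherwise the box must be
supplied explicitly (systems simulated in triclinic cells have to be wrapped
into an orthorhombic cell before analysis).

Lennard-Jones parameters come from a plain CSV table with columns
``residue_name, atom_name, rmin_half, epsilon, charge`` so that no
force-field file dialect is baked in.  Epsilon is stored as a magnitude; the
well-depth sign convention is applied in the energy functions only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "FrameEnsemble",
    "VolumetricMap",
    "load_parameter_table",
    "load_structure",
    "load_trajectory",
    "write_structure",
    "write_trajectory_dcd",
    "select_atoms",
    "read_volumetric_map",
    "write_volumetric_map",
]


class SelectionError(ValueError):
    """Raised for malformed atom-selection expressions."""


class TopologyError(ValueError):
    """Raised for topology/trajectory inconsistencies."""


@dataclass
class AtomRecord:
    """One atom of the topology with its per-atom force-field terms."""

    index: int
    name: str
    residue_name: str
    residue_number: int
    chain_id: str = "A"
    element: str = ""
    lj_rmin_half: float = 0.0  # Å (CHARMM Rmin/2)
    lj_epsilon: float = 0.0  # kcal/mol, stored as magnitude >= 0
    partial_charge: Optional[float] = None

    def __post_init__(self):
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon is stored as a magnitude (>= 0)")
        if self.lj_epsilon > 0 and self.lj_rmin_half <= 0:
            raise ValueError("lj_rmin_half must be > 0 for an LJ-active atom")


@dataclass
class FrameEnsemble:
    """Topology plus ordered coordinate frames with a periodic box.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``box`` has shape
    (n_frames, 3) holding orthorhombic box lengths in Å.  ``frame_interval``
    is the time between stored frames in ps.
    """

    atoms: list[AtomRecord]
    frames: np.ndarray
    box: np.ndarray
    frame_interval: float = 10.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.frames.shape[1] != len(self.atoms):
            raise TopologyError(
                f"every frame must have exactly {len(self.atoms)} positions, "
                f"got {self.frames.shape[1]}"
            )
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.n_frames, 1))
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")
        idx = [a.index for a in self.atoms]
        if len(set(idx)) != len(idx):
            raise ValueError("atom indices must be unique")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def lj_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-atom (rmin_half, epsilon) arrays for the energy kernels."""
        rmh = np.array([a.lj_rmin_half for a in self.atoms], dtype=np.float64)
        eps = np.array([a.lj_epsilon for a in self.atoms], dtype=np.float64)
        return rmh, eps

    def subset(self, indices: Sequence[int]) -> "FrameEnsemble":
        indices = list(indices)
        atoms = []
        for new_i, old_i in enumerate(indices):
            a = self.atoms[old_i]
            atoms.append(
                AtomRecord(new_i, a.name, a.residue_name, a.residue_number,
                           a.chain_id, a.element, a.lj_rmin_half,
                           a.lj_epsilon, a.partial_charge)
            )
        return FrameEnsemble(atoms, self.frames[:, indices, :].copy(),
                             self.box.copy(), self.frame_interval)


@dataclass
class VolumetricMap:
    """Scalar field on a regular grid (OpenDX-compatible).

    Voxel center (i, j, k) sits at ``origin + spacing * (i, j, k)``.
    """

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    values: np.ndarray
    units_label: str = "kcal/mol"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        nx, ny, nz = self.dims
        if min(self.dims) < 1:
            raise ValueError("dims must all be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.size != nx * ny * nz:
            raise ValueError(
                f"values length {self.values.size} != dims product {nx*ny*nz}")
        self.values = self.values.reshape(self.dims)

    def voxel_center(self, ijk) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(ijk, dtype=np.float64)

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers, shape (nx*ny*nz, 3), C-order (x fastest-varying last)."""
        nx, ny, nz = self.dims
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        grid = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.origin + self.spacing * grid


# ---------------------------------------------------------------------------
# parameter tables


def load_parameter_table(path) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Read a CSV LJ table keyed by (residue_name, atom_name)."""
    df = pd.read_csv(path)
    required = {"residue_name", "atom_name", "rmin_half", "epsilon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    table = {}
    for row in df.itertuples(index=False):
        charge = getattr(row, "charge", 0.0)
        if charge is None or (isinstance(charge, float) and np.isnan(charge)):
            charge = 0.0
        table[(str(row.residue_name).strip(), str(row.atom_name).strip())] = (
            float(row.rmin_half), abs(float(row.epsilon)), float(charge))
    return table


def write_parameter_table(table, path) -> None:
    rows = [
        {"residue_name": rn, "atom_name": an, "rmin_half": r, "epsilon": e,
         "charge": q}
        for (rn, an), (r, e, q) in table.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _apply_parameters(atoms: list[AtomRecord], table, allow_missing: bool) -> None:
    if table is None:
        return
    for a in atoms:
        key = (a.residue_name, a.name)
        if key in table:
            a.lj_rmin_half, a.lj_epsilon, a.partial_charge = table[key]
        elif allow_missing:
            a.lj_rmin_half, a.lj_epsilon, a.partial_charge = 0.0, 0.0, 0.0
        else:
            raise TopologyError(
                f"atom {a.name} of residue {a.residue_name} {a.residue_number} "
                "has no entry in the parameter table (pass "
                "allow_missing_parameters=True for a zero-parameter fallback)")


# ---------------------------------------------------------------------------
# PDB / trajectory I/O (MDAnalysis does the format work)


def _mda_universe(topology_path, trajectory_path=None):
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            return mda.Universe(str(topology_path))
        return mda.Universe(str(topology_path), str(trajectory_path))


def _atoms_from_universe(u) -> list[AtomRecord]:
    atoms = []
    for i, at in enumerate(u.atoms):
        try:
            chain = str(at.chainID) or "A"
        except Exception:
            try:
                chain = str(at.segid) or "A"
            except Exception:
                chain = "A"
        try:
            element = str(at.element)
        except Exception:
            element = re.sub(r"[^A-Za-z]", "", at.name)[:1].upper()
        atoms.append(AtomRecord(i, str(at.name), str(at.resname),
                                int(at.resid), chain, element))
    return atoms


def _frame_box(ts, fallback) -> np.ndarray:
    dims = ts.dimensions
    if dims is not None and np.all(dims[:3] > 0):
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise ValueError(
                "only orthorhombic boxes are supported; wrap triclinic cells first")
        return np.array(dims[:3], dtype=np.float64)
    if fallback is None:
        raise ValueError(
            "no box in file (missing CRYST1?); supply box=(lx, ly, lz)")
    return np.asarray(fallback, dtype=np.float64)


def load_structure(path, parameter_table=None, *, box=None,
                   allow_missing_parameters: bool = False) -> FrameEnsemble:
    """Load a single-frame PDB into a FrameEnsemble.

    ``parameter_table`` maps (residue_name, atom_name) to
    (rmin_half, epsilon, charge); atoms without an entry raise unless
    ``allow_missing_parameters`` requests the zero-parameter fallback.
    """
    u = _mda_universe(path)
    atoms = _atoms_from_universe(u)
    _apply_parameters(atoms, parameter_table, allow_missing_parameters)
    ts = u.trajectory[0]
    b = _frame_box(ts, box)
    coords = np.array(u.atoms.positions, dtype=np.float64)[None, :, :]
    return FrameEnsemble(atoms, coords, b[None, :], frame_interval=0.0)


def load_trajectory(topology_path, trajectory_path, *, stride: int = 1,
                    parameter_table=None, box=None,
                    allow_missing_parameters: bool = False,
                    frame_interval: float = 10.0) -> FrameEnsemble:
    """Load a DCD/XTC/multi-model-PDB trajectory, keeping every stride-th frame."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    u = _mda_universe(topology_path, trajectory_path)
    atoms = _atoms_from_universe(u)
    _apply_parameters(atoms, parameter_table, allow_missing_parameters)
    n_top = len(atoms)
    if u.trajectory.n_atoms != n_top:
        raise TopologyError(
            f"topology has {n_top} atoms but trajectory frames have "
            f"{u.trajectory.n_atoms}")
    frames, boxes = [], []
    fallback = box
    for i, ts in enumerate(u.trajectory):
        if i % stride:
            continue
        frames.append(np.array(u.atoms.positions, dtype=np.float64))
        b = _frame_box(ts, fallback)
        fallback = b  # multi-model PDB carries CRYST1 once, up front
        boxes.append(b)
    if not frames:
        raise ValueError("empty trajectory")
    return FrameEnsemble(atoms, np.stack(frames), np.stack(boxes),
                         frame_interval=frame_interval * stride)


def write_structure(ensemble: FrameEnsemble, path, frame: int = 0) -> None:
    """Write one frame as a PDB file with a CRYST1 record."""
    _write_pdb_frames(ensemble, path, [frame])


def write_multimodel_pdb(ensemble: FrameEnsemble, path) -> None:
    """Write all frames as a multi-model PDB trajectory."""
    _write_pdb_frames(ensemble, path, range(ensemble.n_frames))


def _write_pdb_frames(ens: FrameEnsemble, path, frame_indices) -> None:
    frame_indices = list(frame_indices)
    multi = len(frame_indices) > 1
    with open(path, "w") as fh:
        for m, fi in enumerate(frame_indices):
            if multi:
                fh.write(f"MODEL     {m + 1:4d}\n")
            lx, ly, lz = ens.box[fi]
            fh.write(f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}"
                     f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
            for a, pos in zip(ens.atoms, ens.frames[fi]):
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    "ATOM  {serial:5d} {name:<4s} {res:<4s}{chain:1s}{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    "{el:>2s}\n".format(
                        serial=(a.index + 1) % 100000, name=name[:4],
                        res=a.residue_name[:4], chain=(a.chain_id or "A")[:1],
                        resid=a.residue_number % 10000,
                        x=pos[0], y=pos[1], z=pos[2], occ=1.0, b=0.0,
                        el=(a.element or a.name[:1])[:2]))
            fh.write("ENDMDL\n" if multi else "END\n")


def write_trajectory_dcd(ensemble: FrameEnsemble, topology_path, dcd_path) -> None:
    """Write the topology as PDB and the frames as a CHARMM DCD."""
    import MDAnalysis as mda
    write_structure(ensemble, topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path))
        with mda.Writer(str(dcd_path), n_atoms=ensemble.n_atoms) as w:
            for fi in range(ensemble.n_frames):
                u.atoms.positions = ensemble.frames[fi].astype(np.float32)
                u.dimensions = np.array(
                    [*ensemble.box[fi], 90.0, 90.0, 90.0], dtype=np.float32)
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# atom selection
#
# Grammar:  expr   := term (('and'|'or') term)*
#           term   := ['not'] ( '(' expr ')' | primary )
#           primary:= 'name' TOKEN+ | 'resname' TOKEN+ | 'chain' TOKEN+
#                   | 'resid' RANGE+ | 'all' | 'none'
# Ranges are written 10-20 (inclusive) or single numbers; 'and' binds
# tighter than 'or'.

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _Parser:
    def __init__(self, ens: FrameEnsemble, text: str):
        self.ens = ens
        self.tokens = _TOKEN_RE.findall(text)
        self.pos = 0
        if not self.tokens:
            raise SelectionError("empty selection")

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "and":
            self.next()
            mask = mask & self.term()
        return mask

    def term(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.term()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primary()

    _KEYWORDS = {"and", "or", "not", "(", ")"}

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in self._KEYWORDS:
            vals.append(self.next())
        if not vals:
            raise SelectionError("keyword needs at least one value")
        return vals

    def primary(self) -> np.ndarray:
        tok = self.next()
        ens = self.ens
        n = ens.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "none":
            return np.zeros(n, dtype=bool)
        if tok == "name":
            vals = set(self._values())
            return np.array([a.name in vals for a in ens.atoms])
        if tok == "resname":
            vals = set(self._values())
            return np.array([a.residue_name in vals for a in ens.atoms])
        if tok == "chain":
            vals = set(self._values())
            return np.array([a.chain_id in vals for a in ens.atoms])
        if tok == "resid":
            mask = np.zeros(n, dtype=bool)
            for v in self._values():
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
                if not m:
                    raise SelectionError(f"bad resid token {v!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                mask |= np.array(
                    [lo <= a.residue_number <= hi for a in ens.atoms])
            return mask
        raise SelectionError(f"unknown selection keyword {tok!r}")


def select_atoms(ensemble: FrameEnsemble, selection: str) -> list[int]:
    """Evaluate a selection expression; returns sorted unique 0-based indices."""
    mask = _Parser(ensemble, selection).parse()
    return [int(i) for i in np.nonzero(mask)[0]]


# ---------------------------------------------------------------------------
# OpenDX scalar maps (via gridDataFormats, the de-facto DX library)


def write_volumetric_map(vmap: VolumetricMap, path) -> None:
    from gridData import Grid
    g = Grid(vmap.values, origin=vmap.origin,
             delta=np.full(3, vmap.spacing))
    g.export(str(path), file_format="dx")


def read_volumetric_map(path) -> VolumetricMap:
    from gridData import Grid
    try:
        g = Grid(str(path))
    except Exception as exc:  # malformed header / size mismatch
        raise ValueError(f"cannot read DX map {path}: {exc}") from exc
    delta = np.asarray(g.delta)
    if delta.ndim == 2:
        delta = np.diag(delta)
    if not np.allclose(delta, delta[0]):
        raise ValueError("anisotropic grid spacing is not supported")
    return VolumetricMap(origin=np.asarray(g.origin), spacing=float(delta[0]),
                         dims=tuple(int(d) for d in g.grid.shape),
                         values=np.asarray(g.grid, dtype=np.float64))
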