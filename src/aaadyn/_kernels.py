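"""Numba inner loops: LJ energies, ILS accumulation, rigid-water and LJ-fluid MC.

All kernels use the minimum-image convention in an orthorhombic box and
truncated, unshifted interactions.  They are direct pair loops — for the
system sizes this package analyses (hundreds to a few thousand atoms per
frame) a cell list buys nothing and the straight loop doubles as the
reference the vectorised callers are checked against.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .constants import COULOMB, KB


@njit(cache=True, inline="always")
def _min_image(d, L):
    return d - L * np.rint(d / L)


@njit(cache=True)
def lj_energy_sites(frame, box, rmh, eps, sites, site_rmh, site_eps, cutoff2):
    """LJ energy of probe sites against all LJ-active frame atoms.

    CHARMM convention: Rmin_ij = rmh_i + rmh_j, eps_ij = sqrt(eps_i * eps_j),
    E = eps_ij * ((Rmin/r)^12 - 2 (Rmin/r)^6), truncated (unshifted) at the
    cutoff applied per site-atom pair.
    """
    e = 0.0
    n_atoms = frame.shape[0]
    n_sites = sites.shape[0]
    for s in range(n_sites):
        sx, sy, sz = sites[s, 0], sites[s, 1], sites[s, 2]
        for a in range(n_atoms):
            if eps[a] <= 0.0:
                continue
            dx = _min_image(frame[a, 0] - sx, box[0])
            dy = _min_image(frame[a, 1] - sy, box[1])
            dz = _min_image(frame[a, 2] - sz, box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cutoff2 or r2 == 0.0:
                continue
            rmin = rmh[a] + site_rmh[s]
            epsij = np.sqrt(eps[a] * site_eps[s])
            sr2 = rmin * rmin / r2
            sr6 = sr2 * sr2 * sr2
            e += epsij * (sr6 * sr6 - 2.0 * sr6)
    return e


@njit(cache=True)
def ils_accumulate(frames, boxes, rmh, eps, centers, rotated_offsets,
                   site_rmh, site_eps, cutoff, beta, cap):
    """Accumulate Boltzmann weights of probe insertions per voxel.

    rotated_offsets has shape (C, S, 3): per orientation, the probe-site
    offsets already rotated into the lab frame.  Returns (weight_sum,
    n_uncapped) per voxel; insertions with energy above `cap` get zero
    weight.
    """
    n_frames = frames.shape[0]
    n_vox = centers.shape[0]
    n_orient = rotated_offsets.shape[0]
    n_sites = rotated_offsets.shape[1]
    wsum = np.zeros(n_vox)
    n_ok = np.zeros(n_vox, dtype=np.int64)
    cutoff2 = cutoff * cutoff
    sites = np.empty((n_sites, 3))
    for m in range(n_frames):
        frame = frames[m]
        box = boxes[m]
        for v in range(n_vox):
            for k in range(n_orient):
                for s in range(n_sites):
                    for d in range(3):
                        sites[s, d] = centers[v, d] + rotated_offsets[k, s, d]
                e = lj_energy_sites(frame, box, rmh, eps, sites,
                                    site_rmh, site_eps, cutoff2)
                if e <= cap:
                    wsum[v] += np.exp(-beta * e)
                    n_ok[v] += 1
    return wsum, n_ok


# ---------------------------------------------------------------------------
# rigid three-site water Monte Carlo


@njit(cache=True)
def _water_pair_energy(pos, i, j, L, rc2, q, lj_a, lj_b, krf, crf):
    """Energy between molecules i and j (molecule-based O-O cutoff).

    Electrostatics: Coulomb with reaction-field correction inside rc,
    applied to all 9 site pairs using the O-O minimum image shift.
    """
    dx = pos[j, 0, 0] - pos[i, 0, 0]
    dy = pos[j, 0, 1] - pos[i, 0, 1]
    dz = pos[j, 0, 2] - pos[i, 0, 2]
    sx = -L * np.rint(dx / L)
    sy = -L * np.rint(dy / L)
    sz = -L * np.rint(dz / L)
    ox = dx + sx
    oy = dy + sy
    oz = dz + sz
    r2 = ox * ox + oy * oy + oz * oz
    if r2 >= rc2:
        return 0.0
    # O-O Lennard-Jones
    r6 = r2 * r2 * r2
    e = lj_a / (r6 * r6) - lj_b / r6
    # site-site Coulomb + reaction field
    for a in range(3):
        for b in range(3):
            ddx = pos[j, b, 0] + sx - pos[i, a, 0]
            ddy = pos[j, b, 1] + sy - pos[i, a, 1]
            ddz = pos[j, b, 2] + sz - pos[i, a, 2]
            rr2 = ddx * ddx + ddy * ddy + ddz * ddz
            rr = np.sqrt(rr2)
            e += COULOMB * q[a] * q[b] * (1.0 / rr + krf * rr2 - crf)
    return e


@njit(cache=True)
def _water_mol_energy(pos, i, L, rc2, q, lj_a, lj_b, krf, crf):
    e = 0.0
    n = pos.shape[0]
    for j in range(n):
        if j != i:
            e += _water_pair_energy(pos, i, j, L, rc2, q, lj_a, lj_b, krf, crf)
    return e


@njit(cache=True)
def water_total_energy(pos, L, rc, q, lj_a, lj_b, krf, crf):
    e = 0.0
    n = pos.shape[0]
    rc2 = rc * rc
    for i in range(n):
        for j in range(i + 1, n):
            e += _water_pair_energy(pos, i, j, L, rc2, q, lj_a, lj_b, krf, crf)
    return e


@njit(cache=True)
def _rotate_about(pos, i, ax, ay, az, angle):
    """Rotate molecule i's H sites about an axis through its O site."""
    c = np.cos(angle)
    s = np.sin(angle)
    for site in range(1, 3):
        vx = pos[i, site, 0] - pos[i, 0, 0]
        vy = pos[i, site, 1] - pos[i, 0, 1]
        vz = pos[i, site, 2] - pos[i, 0, 2]
        dot = ax * vx + ay * vy + az * vz
        cx = ay * vz - az * vy
        cy = az * vx - ax * vz
        cz = ax * vy - ay * vx
        pos[i, site, 0] = pos[i, 0, 0] + vx * c + cx * s + ax * dot * (1 - c)
        pos[i, site, 1] = pos[i, 0, 1] + vy * c + cy * s + ay * dot * (1 - c)
        pos[i, site, 2] = pos[i, 0, 2] + vz * c + cz * s + az * dot * (1 - c)


@njit(cache=True)
def _random_axis():
    while True:
        x = 2.0 * np.random.random() - 1.0
        y = 2.0 * np.random.random() - 1.0
        z = 2.0 * np.random.random() - 1.0
        n2 = x * x + y * y + z * z
        if 1e-12 < n2 <= 1.0:
            n = np.sqrt(n2)
            return x / n, y / n, z / n


@njit(cache=True)
def run_water_mc(pos0, L, rc, q, lj_a, lj_b, krf, crf, beta,
                 equil_sweeps, n_frames, interval, seed,
                 dtrans0, drot0):
    """Metropolis MC of rigid waters: translations + rotations.

    Move sizes adapt toward ~40% acceptance during equilibration and are
    frozen for production (detailed balance).  Returns (frames, acceptance).
    """
    np.random.seed(seed)
    pos = pos0.copy()
    n = pos.shape[0]
    rc2 = rc * rc
    dtrans = dtrans0
    drot = drot0
    frames = np.empty((n_frames, n, 3, 3))
    acc = 0
    tot = 0
    acc_win = 0
    tot_win = 0
    total_sweeps = equil_sweeps + n_frames * interval
    frame_idx = 0
    for sweep in range(total_sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            e_old = _water_mol_energy(pos, i, L, rc2, q, lj_a, lj_b, krf, crf)
            old = pos[i].copy()
            move = np.random.random()
            if move < 0.45:
                ddx = dtrans * (2.0 * np.random.random() - 1.0)
                ddy = dtrans * (2.0 * np.random.random() - 1.0)
                ddz = dtrans * (2.0 * np.random.random() - 1.0)
                for site in range(3):
                    pos[i, site, 0] += ddx
                    pos[i, site, 1] += ddy
                    pos[i, site, 2] += ddz
                # wrap the O site back into the primary box
                for d in range(3):
                    shift = -L * np.floor(pos[i, 0, d] / L)
                    if shift != 0.0:
                        for site in range(3):
                            pos[i, site, d] += shift
            elif move < 0.9:
                ax, ay, az = _random_axis()
                angle = drot * (2.0 * np.random.random() - 1.0)
                _rotate_about(pos, i, ax, ay, az, angle)
            else:
                # jump: teleport the molecule to a uniform random position
                # (symmetric proposal; decorrelates cavity structure fast)
                ddx = np.random.random() * L - pos[i, 0, 0]
                ddy = np.random.random() * L - pos[i, 0, 1]
                ddz = np.random.random() * L - pos[i, 0, 2]
                for site in range(3):
                    pos[i, site, 0] += ddx
                    pos[i, site, 1] += ddy
                    pos[i, site, 2] += ddz
            e_new = _water_mol_energy(pos, i, L, rc2, q, lj_a, lj_b, krf, crf)
            de = e_new - e_old
            tot += 1
            tot_win += 1
            if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                acc += 1
                acc_win += 1
            else:
                pos[i] = old
        if sweep < equil_sweeps:
            if (sweep + 1) % 50 == 0 and tot_win > 0:
                frac = acc_win / tot_win
                scale = 1.1 if frac > 0.4 else 0.9
                dtrans = min(max(dtrans * scale, 0.01), L / 4.0)
                drot = min(max(drot * scale, 0.01), np.pi)
                acc_win = 0
                tot_win = 0
            if sweep == equil_sweeps - 1:
                acc = 0
                tot = 0
        else:
            if (sweep - equil_sweeps + 1) % interval == 0:
                frames[frame_idx] = pos
                frame_idx += 1
    return frames, acc / max(tot, 1)


# ---------------------------------------------------------------------------
# single-site LJ fluid Monte Carlo


@njit(cache=True)
def _lj_site_energy(pos, i, L, rc2, lj_a, lj_b):
    e = 0.0
    n = pos.shape[0]
    for j in range(n):
        if j == i:
            continue
        dx = _min_image(pos[j, 0] - pos[i, 0], L)
        dy = _min_image(pos[j, 1] - pos[i, 1], L)
        dz = _min_image(pos[j, 2] - pos[i, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2 and r2 > 0.0:
            r6 = r2 * r2 * r2
            e += lj_a / (r6 * r6) - lj_b / r6
    return e


@njit(cache=True)
def lj_fluid_total_energy(pos, L, rc, lj_a, lj_b):
    e = 0.0
    n = pos.shape[0]
    rc2 = rc * rc
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[j, 0] - pos[i, 0], L)
            dy = _min_image(pos[j, 1] - pos[i, 1], L)
            dz = _min_image(pos[j, 2] - pos[i, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2 and r2 > 0.0:
                r6 = r2 * r2 * r2
                e += lj_a / (r6 * r6) - lj_b / r6
    return e


@njit(cache=True)
def run_lj_mc(pos0, L, rc, lj_a, lj_b, beta, equil_sweeps, n_frames,
              interval, seed, dtrans0):
    np.random.seed(seed)
    pos = pos0.copy()
    n = pos.shape[0]
    rc2 = rc * rc
    dtrans = dtrans0
    frames = np.empty((n_frames, n, 3))
    acc = 0
    tot = 0
    acc_win = 0
    tot_win = 0
    frame_idx = 0
    total_sweeps = equil_sweeps + n_frames * interval
    for sweep in range(total_sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            e_old = _lj_site_energy(pos, i, L, rc2, lj_a, lj_b)
            ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
            pos[i, 0] = (ox + dtrans * (2.0 * np.random.random() - 1.0)) % L
            pos[i, 1] = (oy + dtrans * (2.0 * np.random.random() - 1.0)) % L
            pos[i, 2] = (oz + dtrans * (2.0 * np.random.random() - 1.0)) % L
            e_new = _lj_site_energy(pos, i, L, rc2, lj_a, lj_b)
            de = e_new - e_old
            tot += 1
            tot_win += 1
            if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                acc += 1
                acc_win += 1
            else:
                pos[i, 0], pos[i, 1], pos[i, 2] = ox, oy, oz
        if sweep < equil_sweeps:
            if (sweep + 1) % 50 == 0 and tot_win > 0:
                frac = acc_win / tot_win
                scale = 1.1 if frac > 0.4 else 0.9
                dtrans = min(max(dtrans * scale, 0.01), L / 4.0)
                acc_win = 0
                tot_win = 0
            if sweep == equil_sweeps - 1:
                acc = 0
                tot = 0
        else:
            if (sweep - equil_sweeps + 1) % interval == 0:
                frames[frame_idx] = pos
                frame_idx += 1
    return frames, acc / max(tot, 1)
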