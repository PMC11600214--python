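"""Numerical kernels for the coarse-grained simulator (numba-compiled).

All kernels work on plain float64 arrays in nm / kJ/mol units and return
energies together with analytic forces (negative gradients).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "bonded_forces",
    "pair_forces",
    "restraint_forces",
    "rmsd_and_grad",
]

_NOPYTHON = dict(cache=True, fastmath=False)


@njit(**_NOPYTHON)
def bonded_forces(coords, bonds, bond_r0, k_bond,
                  angles, theta0, angle_k,
                  dihedrals, phi0, dihedral_k, forces):
    """Bond + angle + dihedral energy; forces accumulated in-place."""
    energy = 0.0

    # bonds: V = 0.5 k (r - r0)^2
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx0 = coords[j, 0] - coords[i, 0]
        dx1 = coords[j, 1] - coords[i, 1]
        dx2 = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dr = r - bond_r0[b]
        energy += 0.5 * k_bond * dr * dr
        f = -k_bond * dr / r
        forces[j, 0] += f * dx0
        forces[j, 1] += f * dx1
        forces[j, 2] += f * dx2
        forces[i, 0] -= f * dx0
        forces[i, 1] -= f * dx1
        forces[i, 2] -= f * dx2

    # angles: V = 0.5 k (theta - theta0)^2
    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        v10 = coords[i, 0] - coords[j, 0]
        v11 = coords[i, 1] - coords[j, 1]
        v12 = coords[i, 2] - coords[j, 2]
        v20 = coords[k, 0] - coords[j, 0]
        v21 = coords[k, 1] - coords[j, 1]
        v22 = coords[k, 2] - coords[j, 2]
        n1 = np.sqrt(v10 * v10 + v11 * v11 + v12 * v12)
        n2 = np.sqrt(v20 * v20 + v21 * v21 + v22 * v22)
        cos_t = (v10 * v20 + v11 * v21 + v12 * v22) / (n1 * n2)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
        theta = np.arccos(cos_t)
        dt = theta - theta0[a]
        ka = angle_k[a]
        energy += 0.5 * ka * dt * dt
        sin_t = np.sqrt(1.0 - cos_t * cos_t)
        if sin_t < 1e-8:
            sin_t = 1e-8
        coeff = -ka * dt / sin_t   # dV/dcos
        inv12 = 1.0 / (n1 * n2)
        inv11 = cos_t / (n1 * n1)
        inv22 = cos_t / (n2 * n2)
        fi0 = coeff * (v20 * inv12 - v10 * inv11)
        fi1 = coeff * (v21 * inv12 - v11 * inv11)
        fi2 = coeff * (v22 * inv12 - v12 * inv11)
        fk0 = coeff * (v10 * inv12 - v20 * inv22)
        fk1 = coeff * (v11 * inv12 - v21 * inv22)
        fk2 = coeff * (v12 * inv12 - v22 * inv22)
        forces[i, 0] -= fi0
        forces[i, 1] -= fi1
        forces[i, 2] -= fi2
        forces[k, 0] -= fk0
        forces[k, 1] -= fk1
        forces[k, 2] -= fk2
        forces[j, 0] += fi0 + fk0
        forces[j, 1] += fi1 + fk1
        forces[j, 2] += fi2 + fk2

    # dihedrals: V = k [(1 - cos(dphi)) + 0.5 (1 - cos(3 dphi))]
    for t in range(dihedrals.shape[0]):
        i, j, k, l = (dihedrals[t, 0], dihedrals[t, 1],
                      dihedrals[t, 2], dihedrals[t, 3])
        b10 = coords[j, 0] - coords[i, 0]
        b11 = coords[j, 1] - coords[i, 1]
        b12 = coords[j, 2] - coords[i, 2]
        b20 = coords[k, 0] - coords[j, 0]
        b21 = coords[k, 1] - coords[j, 1]
        b22 = coords[k, 2] - coords[j, 2]
        b30 = coords[l, 0] - coords[k, 0]
        b31 = coords[l, 1] - coords[k, 1]
        b32 = coords[l, 2] - coords[k, 2]
        n10 = b11 * b22 - b12 * b21
        n11 = b12 * b20 - b10 * b22
        n12 = b10 * b21 - b11 * b20
        n20 = b21 * b32 - b22 * b31
        n21 = b22 * b30 - b20 * b32
        n22 = b20 * b31 - b21 * b30
        n1sq = n10 * n10 + n11 * n11 + n12 * n12
        n2sq = n20 * n20 + n21 * n21 + n22 * n22
        b2n = np.sqrt(b20 * b20 + b21 * b21 + b22 * b22)
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        m0 = n11 * b22 - n12 * b21
        m1 = n12 * b20 - n10 * b22
        m2 = n10 * b21 - n11 * b20
        x = n10 * n20 + n11 * n21 + n12 * n22
        y = (m0 * n20 + m1 * n21 + m2 * n22) / b2n
        phi = np.arctan2(y, x)
        dphi = phi - phi0[t]
        kd = dihedral_k[t]
        energy += kd * ((1.0 - np.cos(dphi)) + 0.5 * (1.0 - np.cos(3.0 * dphi)))
        dv = kd * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))  # dV/dphi
        # per-atom gradient of phi (standard torsion derivative)
        b1b2 = b10 * b20 + b11 * b21 + b12 * b22
        b3b2 = b30 * b20 + b31 * b21 + b32 * b22
        c1 = b1b2 / (b2n * b2n)
        c2 = b3b2 / (b2n * b2n)
        q1 = b2n / n1sq
        q4 = -b2n / n2sq
        p10 = q1 * n10
        p11 = q1 * n11
        p12 = q1 * n12
        p40 = q4 * n20
        p41 = q4 * n21
        p42 = q4 * n22
        pj0 = -(1.0 + c1) * p10 + c2 * p40
        pj1 = -(1.0 + c1) * p11 + c2 * p41
        pj2 = -(1.0 + c1) * p12 + c2 * p42
        pk0 = c1 * p10 - (1.0 + c2) * p40
        pk1 = c1 * p11 - (1.0 + c2) * p41
        pk2 = c1 * p12 - (1.0 + c2) * p42
        forces[i, 0] -= dv * p10
        forces[i, 1] -= dv * p11
        forces[i, 2] -= dv * p12
        forces[j, 0] -= dv * pj0
        forces[j, 1] -= dv * pj1
        forces[j, 2] -= dv * pj2
        forces[k, 0] -= dv * pk0
        forces[k, 1] -= dv * pk1
        forces[k, 2] -= dv * pk2
        forces[l, 0] -= dv * p40
        forces[l, 1] -= dv * p41
        forces[l, 2] -= dv * p42

    return energy


@njit(**_NOPYTHON)
def pair_forces(coords, contacts, r0, epsilon,
                rep_pairs, rep_radius, rep_epsilon, forces):
    """12-10 contact wells plus r^-12 excluded-volume repulsion.

    Contact term: V = eps [5 (r0/r)^12 - 6 (r0/r)^10]  (minimum -eps at r0).
    Repulsion:    V = eps_rep (sigma/r)^12.
    Raises on numerical overflow via a large-energy sentinel (checked by the
    caller through non-finite or huge values).
    """
    energy = 0.0
    for c in range(contacts.shape[0]):
        i, j = contacts[c, 0], contacts[c, 1]
        dx0 = coords[j, 0] - coords[i, 0]
        dx1 = coords[j, 1] - coords[i, 1]
        dx2 = coords[j, 2] - coords[i, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        r = np.sqrt(r2)
        s = r0[c] / r
        s2 = s * s
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        energy += epsilon * (5.0 * s12 - 6.0 * s10)
        # dV/dr = eps (-60 s12 + 60 s10) / r
        dv = epsilon * 60.0 * (s10 - s12) / r
        f = -dv / r
        forces[j, 0] += f * dx0
        forces[j, 1] += f * dx1
        forces[j, 2] += f * dx2
        forces[i, 0] -= f * dx0
        forces[i, 1] -= f * dx1
        forces[i, 2] -= f * dx2

    cutoff2 = 6.25 * rep_radius * rep_radius
    for c in range(rep_pairs.shape[0]):
        i, j = rep_pairs[c, 0], rep_pairs[c, 1]
        dx0 = coords[j, 0] - coords[i, 0]
        dx1 = coords[j, 1] - coords[i, 1]
        dx2 = coords[j, 2] - coords[i, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        # cheap cutoff: ignore pairs beyond 2.5 sigma (V < 1.7e-5 eps)
        if r2 > cutoff2:
            continue
        r = np.sqrt(r2)
        s = rep_radius / r
        s2 = s * s
        s12 = s2 * s2 * s2 * s2 * s2 * s2
        energy += rep_epsilon * s12
        dv = -12.0 * rep_epsilon * s12 / r
        f = -dv / r
        forces[j, 0] += f * dx0
        forces[j, 1] += f * dx1
        forces[j, 2] += f * dx2
        forces[i, 0] -= f * dx0
        forces[i, 1] -= f * dx1
        forces[i, 2] -= f * dx2

    return energy


@njit(**_NOPYTHON)
def restraint_forces(coords, pairs, r0, strength, flat_width, forces):
    """Flat-bottom harmonic distance restraints.

    V = 0.5 k (|r - r0| - w)^2 for |r - r0| > w, else 0.
    """
    energy = 0.0
    for c in range(pairs.shape[0]):
        i, j = pairs[c, 0], pairs[c, 1]
        dx0 = coords[j, 0] - coords[i, 0]
        dx1 = coords[j, 1] - coords[i, 1]
        dx2 = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dev = r - r0[c]
        if dev > flat_width:
            excess = dev - flat_width
        elif dev < -flat_width:
            excess = dev + flat_width
        else:
            continue
        energy += 0.5 * strength * excess * excess
        dv = strength * excess
        f = -dv / r
        forces[j, 0] += f * dx0
        forces[j, 1] += f * dx1
        forces[j, 2] += f * dx2
        forces[i, 0] -= f * dx0
        forces[i, 1] -= f * dx1
        forces[i, 2] -= f * dx2
    return energy


@njit(**_NOPYTHON)
def rmsd_and_grad(coords, ref):
    """Best-fit (Kabsch) RMSD to a reference and its coordinate gradient.

    Both inputs are (N, 3); centering and optimal rotation are applied
    internally.  The gradient follows from the envelope theorem: at the
    optimum, derivatives through the rotation and the centroids vanish, so
    d rmsd / d x_i = (x0_i - R q0_i) / (N * rmsd)
    with x0, q0 the centered coordinates and R the optimal rotation of the
    reference onto the instantaneous structure.
    """
    n = coords.shape[0]
    cx = np.zeros(3)
    cq = np.zeros(3)
    for i in range(n):
        for d in range(3):
            cx[d] += coords[i, d]
            cq[d] += ref[i, d]
    cx /= n
    cq /= n
    x0 = coords - cx
    q0 = ref - cq

    # M = q0^T x0
    m = np.zeros((3, 3))
    for i in range(n):
        for a in range(3):
            for b in range(3):
                m[a, b] += q0[i, a] * x0[i, b]
    u, s, vt = np.linalg.svd(m)
    d_sign = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.eye(3)
    diag[2, 2] = d_sign
    rot = vt.T @ diag @ u.T          # maps q0 -> x0 frame

    rq = q0 @ rot.T
    diff = x0 - rq
    msd = 0.0
    for i in range(n):
        msd += diff[i, 0] ** 2 + diff[i, 1] ** 2 + diff[i, 2] ** 2
    msd /= n
    rmsd = np.sqrt(msd)

    grad = np.zeros_like(coords)
    if rmsd > 1e-10:
        denom = n * rmsd
        for i in range(n):
            for d in range(3):
                grad[i, d] = diff[i, d] / denom
    return rmsd, grad


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _bias_interp(grid, lo, inv_h, s1, s2):
    """Bilinear interpolation on a bias grid (clamped at the borders)."""
    n1, n2 = grid.shape
    x = (s1 - lo) * inv_h
    y = (s2 - lo) * inv_h
    if x < 0.0:
        x = 0.0
    elif x > n1 - 1.0001:
        x = n1 - 1.0001
    if y < 0.0:
        y = 0.0
    elif y > n2 - 1.0001:
        y = n2 - 1.0001
    i = int(x)
    j = int(y)
    tx = x - i
    ty = y - j
    return ((1 - tx) * (1 - ty) * grid[i, j] + tx * (1 - ty) * grid[i + 1, j]
            + (1 - tx) * ty * grid[i, j + 1] + tx * ty * grid[i + 1, j + 1])


@njit(cache=True)
def integrate_chunk(coords, vel, n_steps, dt, c1, kT, mass,
                    bonds, bond_r0, k_bond, angles, theta0, angle_k,
                    dihedrals, phi0, dihedral_k,
                    contacts, con_r0, epsilon, reps, rep_radius,
                    res_pairs, res_r0, res_k, res_w,
                    refs, n_refs,
                    bias_on, bias_v, bias_f1, bias_f2, bias_lo, bias_inv_h):
    """BAOAB Langevin chunk with optional CV biasing, fully compiled.

    ``refs`` is a (2, N, 3) array of CV reference structures (n_refs of
    them used).  The metadynamics bias is read from accumulated grids
    (potential plus its negative gradient per CV) by bilinear
    interpolation; the caller adds each deposited Gaussian to the grids.
    Returns (cv1, cv2, potential_energy, bias_at_cv) after the last step.
    c1 = exp(-friction * dt); with c1 == 1 the O-step is skipped (NVE).
    """
    n = coords.shape[0]
    half_dt = 0.5 * dt
    c2 = np.sqrt((1.0 - c1 * c1) * kT / mass)

    # initial forces
    forces = np.zeros_like(coords)
    energy = bonded_forces(coords, bonds, bond_r0, k_bond, angles, theta0,
                           angle_k, dihedrals, phi0, dihedral_k, forces)
    energy += pair_forces(coords, contacts, con_r0, epsilon, reps,
                          rep_radius, epsilon, forces)
    if res_pairs.shape[0] > 0:
        energy += restraint_forces(coords, res_pairs, res_r0, res_k, res_w,
                                   forces)
    s1 = 0.0
    s2 = 0.0
    vbias = 0.0
    if n_refs > 0:
        g1 = np.zeros_like(coords)
        g2 = np.zeros_like(coords)
        s1, g1 = rmsd_and_grad(coords, refs[0])
        if n_refs > 1:
            s2, g2 = rmsd_and_grad(coords, refs[1])
        if bias_on:
            vbias = _bias_interp(bias_v, bias_lo, bias_inv_h, s1, s2)
            fb1 = _bias_interp(bias_f1, bias_lo, bias_inv_h, s1, s2)
            fb2 = 0.0
            if n_refs > 1:
                fb2 = _bias_interp(bias_f2, bias_lo, bias_inv_h, s1, s2)
            for i in range(n):
                for d in range(3):
                    forces[i, d] += fb1 * g1[i, d]
                    if n_refs > 1:
                        forces[i, d] += fb2 * g2[i, d]

    for step in range(n_steps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += half_dt * forces[i, d] / mass
                coords[i, d] += half_dt * vel[i, d]
        if c1 < 1.0:
            for i in range(n):
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + c2 * np.random.standard_normal()
        for i in range(n):
            for d in range(3):
                coords[i, d] += half_dt * vel[i, d]

        forces = np.zeros_like(coords)
        energy = bonded_forces(coords, bonds, bond_r0, k_bond, angles,
                               theta0, angle_k, dihedrals, phi0, dihedral_k,
                               forces)
        energy += pair_forces(coords, contacts, con_r0, epsilon, reps,
                              rep_radius, epsilon, forces)
        if res_pairs.shape[0] > 0:
            energy += restraint_forces(coords, res_pairs, res_r0, res_k,
                                       res_w, forces)
        vbias = 0.0
        if n_refs > 0:
            s1, g1 = rmsd_and_grad(coords, refs[0])
            if n_refs > 1:
                s2, g2 = rmsd_and_grad(coords, refs[1])
            if bias_on:
                vbias = _bias_interp(bias_v, bias_lo, bias_inv_h, s1, s2)
                fb1 = _bias_interp(bias_f1, bias_lo, bias_inv_h, s1, s2)
                fb2 = 0.0
                if n_refs > 1:
                    fb2 = _bias_interp(bias_f2, bias_lo, bias_inv_h, s1, s2)
                for i in range(n):
                    for d in range(3):
                        forces[i, d] += fb1 * g1[i, d]
                        if n_refs > 1:
                            forces[i, d] += fb2 * g2[i, d]
        for i in range(n):
            for d in range(3):
                vel[i, d] += half_dt * forces[i, d] / mass

    return s1, s2, energy, vbias
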