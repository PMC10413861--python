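"""Compiled inner loops for the BD propagator.

These kernels mirror the reference NumPy force field in ``forcefield`` —
the two are cross-checked in the test suite — and advance the positions for
a chunk of steps during which the diffusion tensor, its Cholesky factor and
the divergence drift are held fixed (they are refreshed by the driver at
the configured update interval).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the chunk kernels
OK = 0


@njit(cache=True)
def forces_kernel(
    pos,
    bonds, bond_req, k_b,
    angles, angle_eq, k_a,
    dihedrals, phi1, phi3, k_d1, k_d3,
    nat_pairs, nat_sigma, eps_native,
    nb_i, nb_j, nb_count, sigma_steric, steric_prefactor, cutoff,
    forces,
):
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0

    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        c = 2.0 * k_b * (r - bond_req[b]) / r
        forces[i, 0] += c * dx
        forces[i, 1] += c * dy
        forces[i, 2] += c * dz
        forces[j, 0] -= c * dx
        forces[j, 1] -= c * dy
        forces[j, 2] -= c * dz

    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        rij = pos[i] - pos[j]
        rkj = pos[k] - pos[j]
        nij = np.sqrt(rij[0] ** 2 + rij[1] ** 2 + rij[2] ** 2)
        nkj = np.sqrt(rkj[0] ** 2 + rkj[1] ** 2 + rkj[2] ** 2)
        cos_t = (rij[0] * rkj[0] + rij[1] * rkj[1] + rij[2] * rkj[2]) / (nij * nkj)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 1e-12))
        dE = 2.0 * k_a * (theta - angle_eq[a])
        for c in range(3):
            di = (cos_t * rij[c] / nij - rkj[c] / nkj) / (nij * sin_t)
            dk = (cos_t * rkj[c] / nkj - rij[c] / nij) / (nkj * sin_t)
            forces[i, c] -= dE * di
            forces[k, c] -= dE * dk
            forces[j, c] += dE * (di + dk)

    for d in range(dihedrals.shape[0]):
        i = dihedrals[d, 0]
        j = dihedrals[d, 1]
        k = dihedrals[d, 2]
        l = dihedrals[d, 3]
        b1 = pos[j] - pos[i]
        b2 = pos[k] - pos[j]
        b3 = pos[l] - pos[k]
        n1 = np.empty(3)
        n2 = np.empty(3)
        n1[0] = b1[1] * b2[2] - b1[2] * b2[1]
        n1[1] = b1[2] * b2[0] - b1[0] * b2[2]
        n1[2] = b1[0] * b2[1] - b1[1] * b2[0]
        n2[0] = b2[1] * b3[2] - b2[2] * b3[1]
        n2[1] = b2[2] * b3[0] - b2[0] * b3[2]
        n2[2] = b2[0] * b3[1] - b2[1] * b3[0]
        b2n = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        if n1sq < 1e-18 or n2sq < 1e-18 or b2n < 1e-12:
            continue
        cx = n1[1] * n2[2] - n1[2] * n2[1]
        cy = n1[2] * n2[0] - n1[0] * n2[2]
        cz = n1[0] * n2[1] - n1[1] * n2[0]
        sin_phi = (cx * b2[0] + cy * b2[1] + cz * b2[2]) / b2n
        cos_phi = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        phi = np.arctan2(sin_phi, cos_phi)
        dE = -k_d1 * np.sin(phi - phi1[d]) - 3.0 * k_d3 * np.sin(3.0 * phi - phi3[d])
        s = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (b2n * b2n)
        t = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (b2n * b2n)
        for c in range(3):
            g0 = -b2n / n1sq * n1[c]
            g3 = b2n / n2sq * n2[c]
            g1 = -(1.0 + s) * g0 + t * g3
            g2 = s * g0 - (1.0 + t) * g3
            forces[i, c] -= dE * g0
            forces[j, c] -= dE * g1
            forces[k, c] -= dE * g2
            forces[l, c] -= dE * g3

    cut2 = cutoff * cutoff
    for p in range(nat_pairs.shape[0]):
        i = nat_pairs[p, 0]
        j = nat_pairs[p, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cut2:
            continue
        x2 = nat_sigma[p] * nat_sigma[p] / r2
        x10 = x2 * x2 * x2 * x2 * x2
        x12 = x10 * x2
        c = eps_native * 60.0 * (x10 - x12) / r2  # dE/dr / r, sqrt-free
        forces[i, 0] += c * dx
        forces[i, 1] += c * dy
        forces[i, 2] += c * dz
        forces[j, 0] -= c * dx
        forces[j, 1] -= c * dy
        forces[j, 2] -= c * dz

    for p in range(nb_count):
        i = nb_i[p]
        j = nb_j[p]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cut2:
            continue
        x2 = (sigma_steric * sigma_steric) / r2
        x12 = x2 * x2 * x2 * x2 * x2 * x2
        c = -12.0 * steric_prefactor * x12 / r2  # dE/dr / r
        forces[i, 0] += c * dx
        forces[i, 1] += c * dy
        forces[i, 2] += c * dz
        forces[j, 0] -= c * dx
        forces[j, 1] -= c * dy
        forces[j, 2] -= c * dz


@njit(cache=True)
def fill_full_rpy(pos, a, kBT, eta, out):
    """Dense 3N×3N RPY tensor; mirrors hydro.assemble_tensor('full-rpy')."""
    n = pos.shape[0]
    pi = np.pi
    d_self = kBT / (6.0 * pi * eta * a)
    for i in range(3 * n):
        for j in range(3 * n):
            out[i, j] = 0.0
    for i in range(n):
        out[3 * i, 3 * i] = d_self
        out[3 * i + 1, 3 * i + 1] = d_self
        out[3 * i + 2, 3 * i + 2] = d_self
    d = np.empty(3)
    for i in range(n):
        for j in range(i + 1, n):
            d[0] = pos[j, 0] - pos[i, 0]
            d[1] = pos[j, 1] - pos[i, 1]
            d[2] = pos[j, 2] - pos[i, 2]
            r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
            r = np.sqrt(r2)
            if r >= 2.0 * a:
                pref = kBT / (8.0 * pi * eta * r)
                c1 = pref * (1.0 + 2.0 * a * a / (3.0 * r2))
                c2 = pref * (1.0 - 2.0 * a * a / r2) / r2
            elif r2 > 1e-24:
                c1 = d_self * (1.0 - 9.0 * r / (32.0 * a))
                c2 = d_self * 3.0 / (32.0 * a * r)
            else:
                c1 = d_self
                c2 = 0.0
            for al in range(3):
                for be in range(3):
                    val = c2 * d[al] * d[be]
                    if al == be:
                        val += c1
                    out[3 * i + al, 3 * j + be] = val
                    out[3 * j + be, 3 * i + al] = val


@njit(cache=True)
def fill_oa_rpy(pos, a, kBT, eta, out):
    """N×N OA-RPY coefficient matrix; mirrors assemble_tensor('oa-rpy')."""
    n = pos.shape[0]
    pi = np.pi
    d_self = kBT / (6.0 * pi * eta * a)
    for i in range(n):
        out[i, i] = d_self
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r >= 2.0 * a:
                val = kBT / (6.0 * pi * eta * r)
            else:
                val = d_self * (1.0 - r / (4.0 * a))
            out[i, j] = val
            out[j, i] = val


@njit(cache=True)
def fill_oa_divergence(pos, a, kBT, eta, drift):
    """Analytic OA divergence drift; mirrors hydro.oa_divergence."""
    n = pos.shape[0]
    pi = np.pi
    near_deriv = -kBT / (24.0 * pi * eta * a * a)
    for i in range(n):
        drift[i, 0] = 0.0
        drift[i, 1] = 0.0
        drift[i, 2] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r >= 2.0 * a:
                deriv = -kBT / (6.0 * pi * eta * r2)
            else:
                deriv = near_deriv
            if r > 1e-12:
                c = deriv / r
                drift[i, 0] += c * dx
                drift[i, 1] += c * dy
                drift[i, 2] += c * dz
                drift[j, 0] -= c * dx
                drift[j, 1] -= c * dy
                drift[j, 2] -= c * dz


@njit(cache=True)
def rebuild_neighbor_list(pos, excluded, cutoff, nb_i, nb_j):
    """Brute-force O(N²) pair scan; N is small for CG bead models."""
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if excluded[i, j]:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz <= cut2:
                nb_i[count] = i
                nb_j[count] = j
                count += 1
    return count


@njit(cache=True)
def run_chunk(
    pos,
    n_steps, step0,
    full_kind,            # True: dense 3N tensor, False: OA N×N
    tensor,               # (3N,3N) or (N,N)
    corr_noise,           # (n_steps, 3N) correlated noise incl. sqrt(2Δt)
    drift_dt,             # (N,3) divergence drift × Δt (zeros when off)
    dt_over_kbt,
    bonds, bond_req, k_b,
    angles, angle_eq, k_a,
    dihedrals, phi1, phi3, k_d1, k_d3,
    nat_pairs, nat_sigma, eps_native,
    excluded, nb_i, nb_j, nb_count_io, sigma_steric, steric_prefactor, cutoff,
    list_interval,
    save_stride, frames, frame_count_io,
    blowup_threshold,
):
    """Advance ``n_steps`` BD steps with a frozen tensor/factor/drift.

    Returns OK, or the (negative, 1-based) global step index at which a
    per-step displacement exceeded the blow-up threshold.
    """
    n = pos.shape[0]
    forces = np.empty((n, 3))
    nb_count = nb_count_io[0]
    fcount = frame_count_io[0]
    for k in range(n_steps):
        gstep = step0 + k
        if gstep % list_interval == 0:
            nb_count = rebuild_neighbor_list(pos, excluded, cutoff, nb_i, nb_j)
        forces_kernel(
            pos,
            bonds, bond_req, k_b,
            angles, angle_eq, k_a,
            dihedrals, phi1, phi3, k_d1, k_d3,
            nat_pairs, nat_sigma, eps_native,
            nb_i, nb_j, nb_count, sigma_steric, steric_prefactor, cutoff,
            forces,
        )
        if full_kind:
            disp = dt_over_kbt * np.dot(tensor, forces.reshape(3 * n))
            disp = disp.reshape(n, 3)
        else:
            disp = dt_over_kbt * np.dot(tensor, forces)
        noise = corr_noise[k].reshape(n, 3)
        maxd = 0.0
        for i in range(n):
            for c in range(3):
                d = disp[i, c] + drift_dt[i, c] + noise[i, c]
                disp[i, c] = d
                ad = abs(d)
                if ad > maxd:
                    maxd = ad
        if maxd > blowup_threshold:
            nb_count_io[0] = nb_count
            frame_count_io[0] = fcount
            return -(gstep + 1)
        for i in range(n):
            pos[i, 0] += disp[i, 0]
            pos[i, 1] += disp[i, 1]
            pos[i, 2] += disp[i, 2]
        if (gstep + 1) % save_stride == 0:
            for i in range(n):
                frames[fcount, i, 0] = pos[i, 0]
                frames[fcount, i, 1] = pos[i, 1]
                frames[fcount, i, 2] = pos[i, 2]
            fcount += 1
    nb_count_io[0] = nb_count
    frame_count_io[0] = fcount
    return OK
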