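"""Fused force kernel used by the propagator's inner loop.

Implements exactly the same terms as :mod:`grooveslide.forcefield` (which is
the readable numpy reference); equivalence of the two routes is asserted in
the test suite.  Falls back to the numpy route when numba is unavailable.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap

# beyond 4 sigma the r^-12 repulsion is < 6e-8 kcal/mol and is skipped
_EV_CUT_FACTOR2 = 16.0


@njit(cache=True, fastmath=True)
def forces_kernel(pos, bonds, bond_x0, bond_k,
                  angles, angle_x0, angle_k,
                  dihedrals, dihedral_x0, dihedral_kf,
                  con_pairs, con_a, con_kf,
                  ev_pairs, ev_sigma, k_ev,
                  el_pairs, el_qq, kappa, elec_pref,
                  forces):
    energy = 0.0
    forces[:, :] = 0.0

    for t in range(bonds.shape[0]):
        i, j = bonds[t, 0], bonds[t, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_x0[t]
        energy += bond_k[t] * dr * dr
        g = -2.0 * bond_k[t] * dr / r
        forces[j, 0] += g * dx
        forces[j, 1] += g * dy
        forces[j, 2] += g * dz
        forces[i, 0] -= g * dx
        forces[i, 1] -= g * dy
        forces[i, 2] -= g * dz

    for t in range(angles.shape[0]):
        ia, ib, ic = angles[t, 0], angles[t, 1], angles[t, 2]
        ux = pos[ia, 0] - pos[ib, 0]
        uy = pos[ia, 1] - pos[ib, 1]
        uz = pos[ia, 2] - pos[ib, 2]
        vx = pos[ic, 0] - pos[ib, 0]
        vy = pos[ic, 1] - pos[ib, 1]
        vz = pos[ic, 2] - pos[ib, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - angle_x0[t]
        energy += angle_k[t] * dth * dth
        # sin floor bounds the colinearity singularity of the angle gradient
        s = np.sqrt(max(1.0 - c * c, 4e-4))
        dEdth = 2.0 * angle_k[t] * dth
        gax = (c * ux / nu - vx / nv) / (s * nu)
        gay = (c * uy / nu - vy / nv) / (s * nu)
        gaz = (c * uz / nu - vz / nv) / (s * nu)
        gcx = (c * vx / nv - ux / nu) / (s * nv)
        gcy = (c * vy / nv - uy / nu) / (s * nv)
        gcz = (c * vz / nv - uz / nu) / (s * nv)
        forces[ia, 0] -= dEdth * gax
        forces[ia, 1] -= dEdth * gay
        forces[ia, 2] -= dEdth * gaz
        forces[ic, 0] -= dEdth * gcx
        forces[ic, 1] -= dEdth * gcy
        forces[ic, 2] -= dEdth * gcz
        forces[ib, 0] += dEdth * (gax + gcx)
        forces[ib, 1] += dEdth * (gay + gcy)
        forces[ib, 2] += dEdth * (gaz + gcz)

    for t in range(dihedrals.shape[0]):
        i0, i1, i2, i3 = dihedrals[t, 0], dihedrals[t, 1], dihedrals[t, 2], dihedrals[t, 3]
        b1x = pos[i1, 0] - pos[i0, 0]
        b1y = pos[i1, 1] - pos[i0, 1]
        b1z = pos[i1, 2] - pos[i0, 2]
        b2x = pos[i2, 0] - pos[i1, 0]
        b2y = pos[i2, 1] - pos[i1, 1]
        b2z = pos[i2, 2] - pos[i1, 2]
        b3x = pos[i3, 0] - pos[i2, 0]
        b3y = pos[i3, 1] - pos[i2, 1]
        b3z = pos[i3, 2] - pos[i2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        m1x = n1y * b2z - n1z * b2y
        m1y = n1z * b2x - n1x * b2z
        m1z = n1x * b2y - n1y * b2x
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = (m1x * n2x + m1y * n2y + m1z * n2z) / nb2
        phi = np.arctan2(y, x)
        dphi = phi - dihedral_x0[t]
        energy += dihedral_kf[t] * ((1.0 - np.cos(dphi)) + 0.5 * (1.0 - np.cos(3.0 * dphi)))
        dEdphi = dihedral_kf[t] * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        n1sq = max(n1x * n1x + n1y * n1y + n1z * n1z, 1e-16)
        n2sq = max(n2x * n2x + n2y * n2y + n2z * n2z, 1e-16)
        # dphi/dr1 = (|b2|/|n1|^2) n1, dphi/dr4 = -(|b2|/|n2|^2) n2
        gux, guy, guz = nb2 / n1sq * n1x, nb2 / n1sq * n1y, nb2 / n1sq * n1z
        gwx, gwy, gwz = -nb2 / n2sq * n2x, -nb2 / n2sq * n2y, -nb2 / n2sq * n2z
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        forces[i0, 0] -= dEdphi * gux
        forces[i0, 1] -= dEdphi * guy
        forces[i0, 2] -= dEdphi * guz
        forces[i1, 0] -= dEdphi * (-(1.0 + p) * gux + q * gwx)
        forces[i1, 1] -= dEdphi * (-(1.0 + p) * guy + q * gwy)
        forces[i1, 2] -= dEdphi * (-(1.0 + p) * guz + q * gwz)
        forces[i2, 0] -= dEdphi * (p * gux - (1.0 + q) * gwx)
        forces[i2, 1] -= dEdphi * (p * guy - (1.0 + q) * gwy)
        forces[i2, 2] -= dEdphi * (p * guz - (1.0 + q) * gwz)
        forces[i3, 0] -= dEdphi * gwx
        forces[i3, 1] -= dEdphi * gwy
        forces[i3, 2] -= dEdphi * gwz

    for t in range(con_pairs.shape[0]):
        i, j = con_pairs[t, 0], con_pairs[t, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        qo = con_a[t] / r
        q10 = qo ** 10
        q12 = q10 * qo * qo
        energy += con_kf[t] * (5.0 * q12 - 6.0 * q10)
        dEdr = con_kf[t] * 60.0 * (q10 - q12) / r
        g = -dEdr / r
        forces[j, 0] += g * dx
        forces[j, 1] += g * dy
        forces[j, 2] += g * dz
        forces[i, 0] -= g * dx
        forces[i, 1] -= g * dy
        forces[i, 2] -= g * dz

    for t in range(ev_pairs.shape[0]):
        i, j = ev_pairs[t, 0], ev_pairs[t, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        sig = ev_sigma[t]
        if r2 > _EV_CUT_FACTOR2 * sig * sig:
            continue
        r = np.sqrt(r2)
        q12 = (sig / r) ** 12
        energy += k_ev * q12
        dEdr = -12.0 * k_ev * q12 / r
        g = -dEdr / r
        forces[j, 0] += g * dx
        forces[j, 1] += g * dy
        forces[j, 2] += g * dz
        forces[i, 0] -= g * dx
        forces[i, 1] -= g * dy
        forces[i, 2] -= g * dz

    for t in range(el_pairs.shape[0]):
        i, j = el_pairs[t, 0], el_pairs[t, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        e = elec_pref * el_qq[t] * np.exp(-kappa * r) / r
        energy += e
        dEdr = -e * (kappa + 1.0 / r)
        g = -dEdr / r
        forces[j, 0] += g * dx
        forces[j, 1] += g * dy
        forces[j, 2] += g * dz
        forces[i, 0] -= g * dx
        forces[i, 1] -= g * dy
        forces[i, 2] -= g * dz

    return energy


@njit(cache=True)
def integrate_chunk(pos, vel, forces, mobile_idx, noise,
                    dt, gamma, kBT, box_lo, box_hi, use_box,
                    bonds, bond_x0, bond_k,
                    angles, angle_x0, angle_k,
                    dihedrals, dihedral_x0, dihedral_kf,
                    con_pairs, con_a, con_kf,
                    ev_pairs, ev_sigma, k_ev,
                    el_pairs, el_qq, kappa, elec_pref):
    """Advance ``noise.shape[0]`` BAOAB steps in place; returns the potential
    energy at the final positions.  ``noise`` is (n_steps, n_mobile, 3)."""
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1) * kBT)
    cap = 0.5  # A per half-drift; guards against rare force spikes
    n_steps = noise.shape[0]
    energy = 0.0
    for s in range(n_steps):
        for mi in range(mobile_idx.shape[0]):
            m = mobile_idx[mi]
            for d in range(3):
                vel[m, d] += 0.5 * dt * forces[m, d]
                dx = 0.5 * dt * vel[m, d]
                pos[m, d] += min(max(dx, -cap), cap)
                vel[m, d] = c1 * vel[m, d] + c2 * noise[s, mi, d]
                dx = 0.5 * dt * vel[m, d]
                pos[m, d] += min(max(dx, -cap), cap)
            if use_box:
                for d in range(3):
                    if pos[m, d] < box_lo[d]:
                        pos[m, d] = 2.0 * box_lo[d] - pos[m, d]
                        vel[m, d] = -vel[m, d]
                    elif pos[m, d] > box_hi[d]:
                        pos[m, d] = 2.0 * box_hi[d] - pos[m, d]
                        vel[m, d] = -vel[m, d]
        energy = forces_kernel(pos, bonds, bond_x0, bond_k,
                               angles, angle_x0, angle_k,
                               dihedrals, dihedral_x0, dihedral_kf,
                               con_pairs, con_a, con_kf,
                               ev_pairs, ev_sigma, k_ev,
                               el_pairs, el_qq, kappa, elec_pref,
                               forces)
        for mi in range(mobile_idx.shape[0]):
            m = mobile_idx[mi]
            for d in range(3):
                vel[m, d] += 0.5 * dt * forces[m, d]
    return energy
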