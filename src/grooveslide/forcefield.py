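"""Energy and forces of the structure-based coarse-grained force field.

Terms: harmonic bonds/angles ``k (X - X0)^2``, a cosine dihedral series,
12-10 native contacts, an r^-12 excluded volume between all remaining
long-range pairs, and Debye-Hueckel electrostatics between charged beads.
Every pair interacts through exactly one of {contact, target-site term,
excluded volume}, plus electrostatics whenever both beads are charged;
pairs separated by 1-3 residues within a chain carry bonded terms only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .geometry import wrap_angle
from .topology import CGTopology


class OverlappingBeadsError(ValueError):
    pass


def debye_kappa(c_i: float, eps: float = C.DIELECTRIC, T: float = 298.0) -> float:
    """Inverse Debye screening length in 1/A for a 1:1 salt.

    kappa = sqrt(8 pi l_B N_A c_i 1e-27) with the Bjerrum length
    l_B = e^2 / (4 pi eps0 eps kB T) in A (about 8.01 A at eps=70, 298 K).
    """
    if c_i <= 0:
        raise ValueError("ionic strength c_i must be positive")
    l_b = C.COULOMB_EXACT / (eps * C.KB_KCAL * T)
    n_per_a3 = C.AVOGADRO * c_i * 1e-27
    return float(np.sqrt(8.0 * np.pi * l_b * n_per_a3))


@dataclass
class ForceFieldParams:
    """Force-field constants plus the solvent condition (ionic strength)."""

    k_bond: float = C.K_BOND
    k_angle: float = C.K_ANGLE
    k_dihedral: float = C.K_DIHEDRAL
    k_contact: float = C.K_CONTACT
    k_excluded_volume: float = C.K_EXCLUDED
    k_coulomb: float = C.K_COULOMB
    eps: float = C.DIELECTRIC
    b_kappa: float = C.B_KAPPA
    ionic_strength: float = 0.02   # M; mid-range of the studied 0.01-0.06 M
    temperature: float = 298.0     # K
    kBT: float = C.KBT_ROOM        # kcal/mol
    dihedral_form: str = "cosine"  # or "harmonic"
    elec_cutoff_debye: float | None = None  # e.g. 4.0 -> cutoff at 4/kappa

    @property
    def kappa(self) -> float:
        """1/A; the Coulomb limit c_i -> 0 is represented by ionic_strength=0."""
        if self.ionic_strength == 0:
            return 0.0
        return debye_kappa(self.ionic_strength, self.eps, self.temperature)


# ---------------------------------------------------------------------------
# Pair tables
# ---------------------------------------------------------------------------

@dataclass
class PairTables:
    """Precomputed nonbonded pair lists for one topology.

    ``ev``-pairs are all long-range pairs (sequence separation > 3 or
    inter-chain) that are neither native contacts nor target-site terms;
    ``elec`` pairs are all long-range pairs with q_i * q_j != 0.  When a
    ``mobile`` mask is given, pairs between two immobile beads are dropped
    (their energy is a constant of the motion).
    """

    ev_pairs: np.ndarray
    ev_sigma: np.ndarray
    elec_pairs: np.ndarray
    elec_qq: np.ndarray
    contact_pairs: np.ndarray
    contact_a: np.ndarray
    contact_kf: np.ndarray


def _long_range_mask(top: CGTopology) -> np.ndarray:
    """Boolean (n, n) upper-triangle mask of pairs eligible for nonbonded terms."""
    n = top.n_beads
    res = top.residue_ids.astype(int)
    same_chain = top.chain_ids[:, None] == top.chain_ids[None, :]
    sep = np.abs(res[:, None] - res[None, :])
    eligible = ~(same_chain & (sep <= 3))
    iu = np.triu(np.ones((n, n), dtype=bool), k=1)
    return eligible & iu


def build_pair_tables(top: CGTopology, mobile: np.ndarray | None = None,
                      combination: str = "mean") -> PairTables:
    n = top.n_beads
    eligible = _long_range_mask(top)
    if mobile is not None:
        both_fixed = ~mobile[:, None] & ~mobile[None, :]
        eligible = eligible & ~both_fixed

    special = np.zeros((n, n), dtype=bool)
    for i, j in np.vstack([top.contacts, top.target_pairs]).astype(int):
        special[i, j] = special[j, i] = True

    ev_i, ev_j = np.where(eligible & ~special)
    # per-class repulsion distances combined per pair; the arithmetic mean
    # interpolates between the protein and DNA class values
    if combination == "mean":
        sigma = 0.5 * (top.radii[ev_i] + top.radii[ev_j])
    elif combination == "sum":
        sigma = top.radii[ev_i] + top.radii[ev_j]
    elif combination == "max":
        sigma = np.maximum(top.radii[ev_i], top.radii[ev_j])
    else:
        raise ValueError(f"unknown combination rule {combination!r}")

    charged = top.charges != 0
    el = eligible & charged[:, None] & charged[None, :]
    el_i, el_j = np.where(el)

    # contacts and target-site terms share the 12-10 form; fold them into one
    # table with effective depth k*f
    cp = np.vstack([top.contacts, top.target_pairs]).astype(int)
    ca = np.concatenate([top.contact_a, top.target_a])
    ckf = np.concatenate([top.contact_k * top.contact_f, top.target_k])
    if mobile is not None and len(cp):
        keep = mobile[cp[:, 0]] | mobile[cp[:, 1]]
        cp, ca, ckf = cp[keep], ca[keep], ckf[keep]

    return PairTables(
        ev_pairs=np.stack([ev_i, ev_j], axis=1),
        ev_sigma=sigma,
        elec_pairs=np.stack([el_i, el_j], axis=1),
        elec_qq=top.charges[el_i] * top.charges[el_j],
        contact_pairs=cp,
        contact_a=ca,
        contact_kf=ckf,
    )


# ---------------------------------------------------------------------------
# Energies (numpy reference implementation)
# ---------------------------------------------------------------------------

def _pair_r(positions, pairs):
    d = positions[pairs[:, 1]] - positions[pairs[:, 0]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise OverlappingBeadsError("coincident beads in a nonbonded pair")
    return d, r


def bonded_energy(top: CGTopology, positions: np.ndarray,
                  dihedral_form: str = "cosine"):
    """Total bonded energy and a per-term-type breakdown."""
    positions = np.asarray(positions, dtype=float)
    e_bond = e_angle = e_dih = 0.0
    if len(top.bonds):
        d = positions[top.bonds[:, 1]] - positions[top.bonds[:, 0]]
        r = np.linalg.norm(d, axis=1)
        e_bond = float(np.sum(top.bond_k * (r - top.bond_x0) ** 2))
    if len(top.angles):
        a = positions[top.angles[:, 0]]
        b = positions[top.angles[:, 1]]
        c = positions[top.angles[:, 2]]
        u, v = a - b, c - b
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cosang)
        e_angle = float(np.sum(top.angle_k * (theta - top.angle_x0) ** 2))
    if len(top.dihedrals):
        phi = _dihedral_angles(positions, top.dihedrals)
        dphi = phi - top.dihedral_x0
        if dihedral_form == "cosine":
            e = top.dihedral_k * ((1 - np.cos(dphi)) + 0.5 * (1 - np.cos(3 * dphi)))
        elif dihedral_form == "harmonic":
            e = top.dihedral_k * wrap_angle(dphi) ** 2
        else:
            raise ValueError(f"unknown dihedral form {dihedral_form!r}")
        e_dih = float(np.sum(top.dihedral_f * e))
    breakdown = {"bond": e_bond, "angle": e_angle, "dihedral": e_dih}
    return e_bond + e_angle + e_dih, breakdown


def _dihedral_angles(positions, quads):
    b1 = positions[quads[:, 1]] - positions[quads[:, 0]]
    b2 = positions[quads[:, 2]] - positions[quads[:, 1]]
    b3 = positions[quads[:, 3]] - positions[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    return np.arctan2(y, x)


def contact_energy(top: CGTopology, positions: np.ndarray,
                   tables: PairTables | None = None) -> float:
    """12-10 native-contact (and target-site) energy: f k [5 (A/r)^12 - 6 (A/r)^10]."""
    tables = tables or build_pair_tables(top)
    if len(tables.contact_pairs) == 0:
        return 0.0
    _, r = _pair_r(np.asarray(positions, float), tables.contact_pairs)
    q = tables.contact_a / r
    return float(np.sum(tables.contact_kf * (5.0 * q ** 12 - 6.0 * q ** 10)))


def excluded_volume_energy(top: CGTopology, positions: np.ndarray,
                           tables: PairTables | None = None,
                           k_ev: float = C.K_EXCLUDED) -> float:
    """Repulsive r^-12 energy over long-range non-contact pairs."""
    tables = tables or build_pair_tables(top)
    if len(tables.ev_pairs) == 0:
        return 0.0
    _, r = _pair_r(np.asarray(positions, float), tables.ev_pairs)
    return float(np.sum(k_ev * (tables.ev_sigma / r) ** 12))


def electrostatic_energy(top: CGTopology, positions: np.ndarray,
                         params: ForceFieldParams,
                         tables: PairTables | None = None) -> float:
    """Debye-Hueckel energy K_C B(kappa) q_i q_j exp(-kappa r) / (eps r)."""
    tables = tables or build_pair_tables(top)
    if len(tables.elec_pairs) == 0:
        return 0.0
    _, r = _pair_r(np.asarray(positions, float), tables.elec_pairs)
    kappa = params.kappa
    e = (params.k_coulomb * params.b_kappa * tables.elec_qq
         * np.exp(-kappa * r) / (params.eps * r))
    if params.elec_cutoff_debye is not None and kappa > 0:
        rc = params.elec_cutoff_debye / kappa
        shift = (params.k_coulomb * params.b_kappa * tables.elec_qq
                 * np.exp(-kappa * rc) / (params.eps * rc))
        e = np.where(r < rc, e - shift, 0.0)
    return float(np.sum(e))


def total_energy(top: CGTopology, positions: np.ndarray, params: ForceFieldParams,
                 tables: PairTables | None = None) -> tuple[float, dict]:
    tables = tables or build_pair_tables(top)
    e_bonded, breakdown = bonded_energy(top, positions, params.dihedral_form)
    breakdown = dict(breakdown)
    breakdown["contact"] = contact_energy(top, positions, tables)
    breakdown["excluded_volume"] = excluded_volume_energy(
        top, positions, tables, params.k_excluded_volume
    )
    breakdown["electrostatic"] = electrostatic_energy(top, positions, params, tables)
    return float(sum(breakdown.values())), breakdown


def total_energy_and_forces(top: CGTopology, positions: np.ndarray,
                            params: ForceFieldParams,
                            tables: PairTables | None = None):
    """Energy and analytic forces (-gradient) for all terms."""
    positions = np.asarray(positions, dtype=float)
    tables = tables or build_pair_tables(top)
    forces = np.zeros_like(positions)
    energy = 0.0

    # bonds
    if len(top.bonds):
        i, j = top.bonds[:, 0], top.bonds[:, 1]
        d = positions[j] - positions[i]
        r = np.linalg.norm(d, axis=1)
        energy += float(np.sum(top.bond_k * (r - top.bond_x0) ** 2))
        # dE/dr = 2 k (r - r0); force on j is -dE/dr * d/r
        fscal = (-2.0 * top.bond_k * (r - top.bond_x0) / r)[:, None] * d
        np.add.at(forces, j, fscal)
        np.add.at(forces, i, -fscal)

    # angles
    if len(top.angles):
        ia, ib, ic = top.angles[:, 0], top.angles[:, 1], top.angles[:, 2]
        u = positions[ia] - positions[ib]
        v = positions[ic] - positions[ib]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cosang)
        energy += float(np.sum(top.angle_k * (theta - top.angle_x0) ** 2))
        dEdtheta = 2.0 * top.angle_k * (theta - top.angle_x0)
        # the angle gradient is singular at colinearity; flooring sin(theta)
        # bounds the force there instead of failing
        sin = np.sqrt(np.maximum(1.0 - cosang ** 2, 4e-4))
        ga = (u * cosang[:, None] / nu[:, None] - v / nv[:, None]) / (sin * nu)[:, None]
        gc = (v * cosang[:, None] / nv[:, None] - u / nu[:, None]) / (sin * nv)[:, None]
        fa = -dEdtheta[:, None] * ga
        fc = -dEdtheta[:, None] * gc
        np.add.at(forces, ia, fa)
        np.add.at(forces, ic, fc)
        np.add.at(forces, ib, -(fa + fc))

    # dihedrals
    if len(top.dihedrals):
        q = top.dihedrals
        phi = _dihedral_angles(positions, q)
        dphi = phi - top.dihedral_x0
        if params.dihedral_form == "cosine":
            energy += float(np.sum(top.dihedral_f * top.dihedral_k
                                   * ((1 - np.cos(dphi)) + 0.5 * (1 - np.cos(3 * dphi)))))
            dEdphi = top.dihedral_f * top.dihedral_k * (np.sin(dphi) + 1.5 * np.sin(3 * dphi))
        else:
            w = wrap_angle(dphi)
            energy += float(np.sum(top.dihedral_f * top.dihedral_k * w ** 2))
            dEdphi = 2.0 * top.dihedral_f * top.dihedral_k * w
        b1 = positions[q[:, 1]] - positions[q[:, 0]]
        b2 = positions[q[:, 2]] - positions[q[:, 1]]
        b3 = positions[q[:, 3]] - positions[q[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        # dphi/dr1 = (|b2|/|n1|^2) n1, dphi/dr4 = -(|b2|/|n2|^2) n2;
        # middle atoms follow from p = b1.b2/|b2|^2, q = b3.b2/|b2|^2
        gu = (nb2 / np.maximum(np.sum(n1 * n1, axis=1), 1e-16))[:, None] * n1
        gw = (-nb2 / np.maximum(np.sum(n2 * n2, axis=1), 1e-16))[:, None] * n2
        p = (np.sum(b1 * b2, axis=1) / nb2 ** 2)[:, None]
        qq_ = (np.sum(b3 * b2, axis=1) / nb2 ** 2)[:, None]
        de = dEdphi[:, None]
        np.add.at(forces, q[:, 0], -de * gu)
        np.add.at(forces, q[:, 1], -de * (-(1.0 + p) * gu + qq_ * gw))
        np.add.at(forces, q[:, 2], -de * (p * gu - (1.0 + qq_) * gw))
        np.add.at(forces, q[:, 3], -de * gw)

    # 12-10 contacts / target-site terms
    if len(tables.contact_pairs):
        i, j = tables.contact_pairs[:, 0], tables.contact_pairs[:, 1]
        d, r = _pair_r(positions, tables.contact_pairs)
        qo = tables.contact_a / r
        energy += float(np.sum(tables.contact_kf * (5 * qo ** 12 - 6 * qo ** 10)))
        dEdr = tables.contact_kf * 60.0 * (qo ** 10 - qo ** 12) / r
        fvec = (-dEdr / r)[:, None] * d
        np.add.at(forces, j, fvec)
        np.add.at(forces, i, -fvec)

    # excluded volume
    if len(tables.ev_pairs):
        i, j = tables.ev_pairs[:, 0], tables.ev_pairs[:, 1]
        d, r = _pair_r(positions, tables.ev_pairs)
        q12 = (tables.ev_sigma / r) ** 12
        energy += float(np.sum(params.k_excluded_volume * q12))
        dEdr = -12.0 * params.k_excluded_volume * q12 / r
        fvec = (-dEdr / r)[:, None] * d
        np.add.at(forces, j, fvec)
        np.add.at(forces, i, -fvec)

    # electrostatics
    if len(tables.elec_pairs):
        i, j = tables.elec_pairs[:, 0], tables.elec_pairs[:, 1]
        d, r = _pair_r(positions, tables.elec_pairs)
        kappa = params.kappa
        pref = params.k_coulomb * params.b_kappa / params.eps
        e = pref * tables.elec_qq * np.exp(-kappa * r) / r
        if params.elec_cutoff_debye is not None and kappa > 0:
            rc = params.elec_cutoff_debye / kappa
            shift = pref * tables.elec_qq * np.exp(-kappa * rc) / rc
            live = r < rc
            energy += float(np.sum(np.where(live, e - shift, 0.0)))
            dEdr = np.where(live, -e * (kappa + 1.0 / r), 0.0)
        else:
            energy += float(np.sum(e))
            dEdr = -e * (kappa + 1.0 / r)
        fvec = (-dEdr / r)[:, None] * d
        np.add.at(forces, j, fvec)
        np.add.at(forces, i, -fvec)

    return energy, forces
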