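"""Synthetic inputs: ideal straight B-DNA, a bent-DNA mimic, a toy dimeric
groove binder with a positively charged recognition face, and hand-constructed
(Z, d, phi) traces with known event labels for classifier oracle tests.

All generators are pure functions of their parameters and seed.  Geometry is
schematic: beads sit on idealized cylindrical helices (phosphate radius
~9.4 A, sugar ~7.4 A, base ~2.0 A) rather than on a physical fold; the point
is correct charge placement, groove periodicity and connectivity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .analysis import GrooveMap, LABEL_3D, LABEL_GROOVE, LABEL_HOP
from .geometry import rotation_matrix, wrap_angle
from .io import make_atom_array
from .topology import (
    CGTopology,
    apply_flexibility,
    coarse_grain_dna,
    coarse_grain_protein,
    compute_native_contacts,
)

STRAND_HALF_ANGLE = np.deg2rad(110.0)  # phosphate azimuth offset from the
                                       # major-groove center line
SUGAR_HALF_ANGLE = np.deg2rad(75.0)
BASE_HALF_ANGLE = np.deg2rad(35.0)


@dataclass
class DNAGeometry:
    """Idealized B-DNA helix parameters."""

    n_bp: int
    rise: float = C.BP_RISE          # A per bp
    twist: float = C.TWIST_DEG       # degrees per bp
    groove_phase: float = 0.0        # azimuth of the major-groove center at Z=0
    r_phosphate: float = 9.4
    r_sugar: float = 7.4
    r_base: float = 4.5   # base-ring centers sit ~4-5 A off-axis in B-DNA

    def __post_init__(self):
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")
        if self.rise <= 0:
            raise ValueError("rise must be positive")

    @property
    def repeat_bp(self) -> float:
        return 360.0 / self.twist

    @property
    def slope(self) -> float:
        """Groove-line angular advance in rad per A of Z."""
        return np.deg2rad(self.twist) / self.rise

    def z_of_bp(self, k) -> np.ndarray:
        """Z of base pair k (1-based), duplex centered at the origin."""
        k = np.asarray(k, dtype=float)
        return (k - 1 - (self.n_bp - 1) / 2.0) * self.rise

    def groove_map(self) -> GrooveMap:
        return GrooveMap(slope=self.slope, phi0=self.groove_phase,
                         repeat_bp=self.repeat_bp, rise=self.rise)


def _cyl(r, phi, z):
    """Cylindrical to Cartesian in the phi = atan2(x, y) convention."""
    return np.array([r * np.sin(phi), r * np.cos(phi), z])


def generate_ideal_bdna(geom: DNAGeometry):
    """Straight duplex on the lab z-axis, centered at the origin.

    Each nucleotide contributes three pseudo-atoms (P, C1', N1) that map onto
    the phosphate/sugar/base beads; both strands' phosphates run at azimuth
    +-110 deg around the major-groove center line, so the groove geometry is
    periodic with the helical repeat.  Returns ``(atoms, topology)``.
    """
    coords, names, res_names, res_ids, chains, elements = [], [], [], [], [], []
    for k in range(geom.n_bp):
        z = geom.z_of_bp(k + 1)
        m = geom.groove_phase + geom.slope * z  # major-groove center azimuth
        for strand, sign in (("D", +1.0), ("E", -1.0)):
            res = k + 1 if strand == "D" else geom.n_bp - k
            base = "DA" if (k + strand.startswith("D")) % 2 else "DT"
            # the P -> sugar -> base atoms spiral inward toward the groove
            # center, filling the duplex core like stacked base pairs do
            for nm, el, r, off in (("P", "P", geom.r_phosphate, STRAND_HALF_ANGLE),
                                   ("C1'", "C", geom.r_sugar, SUGAR_HALF_ANGLE),
                                   ("N1", "N", geom.r_base, BASE_HALF_ANGLE)):
                coords.append(_cyl(r, m + sign * off, z))
                names.append(nm)
                res_names.append(base)
                res_ids.append(res)
                chains.append(strand)
                elements.append(el)
    # order atoms by (chain, res_id) so residues are contiguous and 5'->3'
    order = np.lexsort((np.asarray(res_ids), np.asarray(chains)))
    atoms = make_atom_array(
        np.asarray(coords)[order],
        np.asarray(names)[order], np.asarray(res_names)[order],
        np.asarray(res_ids)[order], np.asarray(chains)[order],
        np.asarray(elements)[order],
    )
    return atoms, coarse_grain_dna(atoms)


def generate_bent_dna(geom: DNAGeometry, bend_angle: float, bend_center: int):
    """Two ideal helical arms joined at ``bend_center`` with the given
    inter-axis angle (degrees); the bend opens in the y-z plane.

    ``bend_angle = 0`` reproduces :func:`generate_ideal_bdna` exactly.
    Returns ``(atoms, topology)``.
    """
    if not 0.0 <= bend_angle <= 90.0:
        raise ValueError("bend_angle must be in [0, 90] degrees")
    if not 1 <= bend_center <= geom.n_bp:
        raise ValueError("bend_center outside the duplex")
    atoms, _ = generate_ideal_bdna(geom)
    if bend_angle > 0.0:
        zc = geom.z_of_bp(bend_center)
        pivot = np.array([0.0, 0.0, zc])
        # the arm above the bend tilts toward +y, i.e. away from the groove
        # face at the duplex center where a binder would be posed
        rot = rotation_matrix([1.0, 0.0, 0.0], -np.deg2rad(bend_angle))
        # bp index of each atom irrespective of strand numbering direction
        bp = np.where(atoms.chain_id == "D", atoms.res_id,
                      geom.n_bp + 1 - atoms.res_id)
        move = bp > bend_center
        atoms.coord[move] = (atoms.coord[move] - pivot) @ rot.T + pivot
        # widen the minor groove on the outside (convex, -y) side of the bend:
        # push the convex-side junction phosphates slightly outward
        near = ((np.abs(bp - bend_center) <= 1) & (atoms.atom_name == "P")
                & (atoms.coord[:, 1] < 0))
        atoms.coord[near] += np.array([0.0, -1.5, 0.0])
    return atoms, coarse_grain_dna(atoms)


# ---------------------------------------------------------------------------
# Toy binder
# ---------------------------------------------------------------------------

REC_LEN = 8      # recognition ladder residues per monomer
HINGE_LEN = 4


@dataclass
class ToyBinder:
    atoms: object
    topology: CGTopology
    recognition_residues: dict   # chain -> list of res_ids
    hinge_residues: dict
    core_residues: dict

    def recognition_beads(self) -> dict:
        out = {}
        top = self.topology
        for i, (chain, res) in enumerate(self.recognition_residues.items()):
            sel = np.where(np.isin(top.residue_ids, res)
                           & (top.chain_ids == chain))[0]
            out[str(i + 1)] = sel
        return out


def _monomer_coords(geom: DNAGeometry, n_res: int, z_center: float,
                    rec_radius: float, rec_zig: float, n_lys: int,
                    rng) -> tuple[np.ndarray, list]:
    """CA coordinates and residue names for one monomer whose recognition
    ladder hugs the major-groove line around ``z_center``."""
    gm = geom.groove_map()
    coords = []
    res_names = []
    # recognition ladder: 8 CAs following the groove line, alternating between
    # an inward (charged, Lys) and an outward rail
    # ~2.33 A of groove arc per residue -> ~1 A of Z per residue
    arc_per_z = np.sqrt((rec_radius * gm.slope) ** 2 + 1.0)
    dz = np.sqrt(max(3.8 ** 2 - (2.0 * rec_zig) ** 2, 4.0)) / arc_per_z
    lys_at = set([1, 3, 5, 7, 0, 4, 2, 6][:n_lys])  # inward rail first
    for i in range(REC_LEN):
        z = z_center + (i - (REC_LEN - 1) / 2.0) * dz
        phi = gm.groove_phi(z)
        r = rec_radius - rec_zig if i % 2 else rec_radius + rec_zig
        coords.append(_cyl(r, phi, z))
        res_names.append("LYS" if i in lys_at else "ALA")
    # hinge: 4 CAs walking radially outward and toward the dimer interface
    p_last = coords[-1]
    phi_last = np.arctan2(p_last[0], p_last[1])
    radial = np.array([np.sin(phi_last), np.cos(phi_last), 0.0])
    step = radial + np.array([0.0, 0.0, 0.55 * np.sign(-z_center)])
    step = 3.8 * step / np.linalg.norm(step)
    for h in range(1, HINGE_LEN + 1):
        coords.append(p_last + h * step)
        res_names.append("GLY")
    # core: alpha-helix-like (radius 2.3 A, rise 1.5 A, 100 deg/res) along x
    n_core = n_res - REC_LEN - HINGE_LEN
    start = coords[-1] + step
    axis = np.array([1.0, 0.0, 0.0]) * (np.sign(-start[0]) or 1.0)
    for i in range(n_core):
        ph = np.deg2rad(100.0 * i)
        center = start + axis * 1.5 * i
        coords.append(center + np.array([0.0, 2.3 * np.cos(ph), 2.3 * np.sin(ph)]))
        res_names.append("GLU" if i in (6, 12) else "ALA")
    coords = np.asarray(coords)
    coords = coords + rng.normal(0.0, 0.02, size=coords.shape)
    return coords, res_names


def generate_toy_binder(n_residues_per_monomer: int = 30, dimeric: bool = True,
                        hinge_flexible: bool = True, hinge_f: float = 0.0,
                        seed: int = 0, geom: DNAGeometry | None = None,
                        contact_cutoff: float = 7.0, rec_radius: float = 11.0,
                        rec_zig: float = 1.5, n_lys: int = 6) -> ToyBinder:
    """Schematic helix-turn-helix-like binder posed on the DNA groove.

    Each monomer carries an 8-residue recognition ladder with four +1 (Lys)
    beads facing the DNA, a 4-residue hinge and a compact core; the dimer is
    generated by a 2-fold rotation about the lab y-axis so both recognition
    ladders sit one helical turn apart on the same groove line.  With
    ``hinge_flexible`` the hinge dihedrals and any contact involving hinge
    residues are scaled by ``hinge_f`` (0 = fully free).
    """
    if n_residues_per_monomer < 20:
        raise ValueError("n_residues_per_monomer must be >= 20")
    geom = geom or DNAGeometry(n_bp=30)
    rng = np.random.default_rng(seed)
    half_turn_z = geom.repeat_bp * geom.rise / 2.0
    coords_a, res_names = _monomer_coords(
        geom, n_residues_per_monomer, z_center=-half_turn_z,
        rec_radius=rec_radius, rec_zig=rec_zig, n_lys=n_lys, rng=rng,
    )
    chains = ["A"] * len(coords_a)
    coords = coords_a
    names = list(res_names)
    if dimeric:
        c2 = np.diag([-1.0, 1.0, -1.0])  # 2-fold about the y-axis
        coords = np.vstack([coords_a, coords_a @ c2.T])
        chains += ["B"] * len(coords_a)
        names += list(res_names)
    res_ids = list(range(1, n_residues_per_monomer + 1)) * (2 if dimeric else 1)
    atoms = make_atom_array(coords, ["CA"] * len(coords), names, res_ids,
                            chains, ["C"] * len(coords))
    top = coarse_grain_protein(atoms)
    pairs, aij = compute_native_contacts(atoms, top, heavy_atom_cutoff=contact_cutoff)
    if len(pairs):
        top.add_contacts(pairs, aij)
    # the recognition ladder mimics a rigid folded element: triangulate it
    # with stiff 1-2 and 1-3 brace bonds so it cannot crumple and thread
    # into the DNA grooves (a folded domain does not unfold on binding)
    rec_ids = set(range(1, REC_LEN + 1))
    for i in range(top.n_beads):
        ri = int(top.residue_ids[i])
        if ri not in rec_ids:
            continue
        for j in range(i + 1, top.n_beads):
            if top.chain_ids[j] != top.chain_ids[i]:
                continue
            rj = int(top.residue_ids[j])
            if rj not in rec_ids or rj - ri not in (2, 3):
                continue
            x0 = float(np.linalg.norm(top.positions[j] - top.positions[i]))
            top.bonds = np.vstack([top.bonds, [[i, j]]])
            top.bond_x0 = np.append(top.bond_x0, x0)
            top.bond_k = np.append(top.bond_k, 100.0)
    rec = list(range(1, REC_LEN + 1))
    hinge = list(range(REC_LEN + 1, REC_LEN + HINGE_LEN + 1))
    core = list(range(REC_LEN + HINGE_LEN + 1, n_residues_per_monomer + 1))
    chains_used = ["A", "B"] if dimeric else ["A"]
    if hinge_flexible:
        hinge_set = {(c, r) for c in chains_used for r in hinge}
        top = apply_flexibility(top, hinge_set, hinge_f)
    return ToyBinder(
        atoms=atoms,
        topology=top,
        recognition_residues={c: rec for c in chains_used},
        hinge_residues={c: hinge for c in chains_used},
        core_residues={c: core for c in chains_used},
    )


# ---------------------------------------------------------------------------
# Oracle traces
# ---------------------------------------------------------------------------

@dataclass
class OracleTrace:
    """Hand-constructed (Z, d, phi) trace with known ground-truth labels."""

    times_ns: np.ndarray
    regions: dict
    true_labels: np.ndarray
    flip_times_us: list
    groove_map: GrooveMap
    plan: list = field(default_factory=list)

    def helix_trace(self):
        from .analysis import HelixTrace

        return HelixTrace(times_ns=self.times_ns, regions=self.regions,
                          groove_map=self.groove_map)


def generate_oracle_trace(plan, geom: DNAGeometry | None = None,
                          frame_dt_ns: float = 0.1, noise_bp: float = 0.3,
                          d_groove: float = 18.0, d_hop: float = 26.0,
                          d_3d: float = 40.0, seed: int = 0,
                          n_regions: int = 1, region_offset_bp: float = 10.0,
                          start_z: float = 0.0) -> OracleTrace:
    """Build a trace from a segment plan.

    ``plan`` is a list of dicts with keys ``type`` (groove/hop/threeD/flip),
    ``duration_ns`` and optional ``span_bp``.  Groove segments follow the
    linear groove relation phi(Z) with uniform sub-tolerance noise of
    amplitude ``noise_bp``; hop segments move Z by ``span_bp`` with the
    azimuth decoupled (offset half a turn from the groove center); 3D
    segments sit at d > R_c.  True labels incorporate the short-event rules
    (a planned hop under 1 bp is groove-tracking ground truth; planned groove
    tracking under 0.5 ns is hopping ground truth).
    """
    geom = geom or DNAGeometry(n_bp=100)
    gm = geom.groove_map()
    rng = np.random.default_rng(seed)
    half_len = (geom.n_bp - 1) * geom.rise / 2.0
    bp_angle = 2.0 * np.pi / gm.repeat_bp

    times, zs, ds, phis, labels = [], [], [], [], []
    flip_signs = []
    t = 0.0
    z = float(start_z)
    order = 1.0
    flip_times = []
    for seg in plan:
        kind = seg["type"]
        if kind == "flip":
            order = -order
            flip_times.append(t * 1e-3)
            continue
        dur = float(seg["duration_ns"])
        span = float(seg.get("span_bp", 0.0)) * geom.rise
        nf = max(1, int(round(dur / frame_dt_ns)))
        if abs(z + span) > half_len:
            raise ValueError("plan span exceeds the DNA length")
        frac = (np.arange(nf) + 0.5) / nf
        seg_z = z + span * frac
        if kind == "groove":
            noise = rng.uniform(-noise_bp, noise_bp, nf) * bp_angle
            seg_phi = gm.groove_phi(seg_z) + noise
            seg_d = d_groove + rng.uniform(-1.0, 1.0, nf)
            lab = LABEL_GROOVE
            if dur < C.MIN_GROOVE_NS:
                lab = LABEL_HOP
        elif kind == "hop":
            seg_phi = gm.groove_phi(seg_z) + np.pi + rng.uniform(-0.3, 0.3, nf)
            seg_d = d_hop + rng.uniform(-1.0, 1.0, nf)
            lab = LABEL_HOP
            if abs(span) / geom.rise < C.MIN_HOP_BP:
                lab = LABEL_GROOVE
        elif kind == "threeD":
            seg_phi = rng.uniform(-np.pi, np.pi, nf)
            seg_d = d_3d + rng.uniform(0.0, 5.0, nf)
            lab = LABEL_3D
        else:
            raise ValueError(f"unknown segment type {kind!r}")
        times.append(t + (np.arange(nf) + 1.0) * frame_dt_ns)
        zs.append(seg_z)
        ds.append(seg_d)
        phis.append(wrap_angle(seg_phi))
        labels.extend([lab] * nf)
        flip_signs.extend([order] * nf)
        t += nf * frame_dt_ns
        z += span

    times = np.concatenate(times)
    zs = np.concatenate(zs)
    ds = np.concatenate(ds)
    phis = np.concatenate(phis)
    flip_signs = np.asarray(flip_signs)

    regions = {"1": {"Z": zs, "d": ds, "phi": phis}}
    if n_regions == 2:
        off = region_offset_bp * geom.rise * flip_signs
        z2 = zs - off
        regions["2"] = {
            "Z": z2,
            "d": ds.copy(),
            "phi": wrap_angle(gm.groove_phi(z2)),
        }
    return OracleTrace(
        times_ns=times,
        regions=regions,
        true_labels=np.asarray(labels, dtype="<U6"),
        flip_times_us=flip_times,
        groove_map=gm,
        plan=list(plan),
    )
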