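"""Coarse-grained topologies: one bead per amino acid at the Calpha position,
three beads per nucleotide at the geometric centers of the sugar, base and
phosphate groups, with Go-type bonded terms, native contacts, charges,
flexibility scaling and optional protein-DNA target-site potentials.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import constants as C
from .geometry import angle, dihedral

POSITIVE_RESIDUES = {"LYS", "ARG"}
NEGATIVE_RESIDUES = {"GLU", "ASP"}
HISTIDINE = {"HIS", "HSP", "HIP"}
DNA_RESNAMES = {"DA", "DT", "DG", "DC", "DU", "DI", "A", "T", "G", "C", "U", "I"}
PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "O1P", "O2P", "OP3", "O3P"}
CHAIN_BREAK_CUTOFF = 4.5  # A between consecutive Calpha beads

ROLE_CA = "CA"
ROLE_SUGAR = "sugar"
ROLE_BASE = "base"
ROLE_PHOSPHATE = "phosphate"


class StructureInputError(ValueError):
    """Raised for malformed structural input (e.g. a residue without Calpha)."""


@dataclass
class CGBead:
    """A single coarse-grained bead."""

    index: int
    role: str
    position: np.ndarray
    charge: float
    residue_id: int
    chain_id: str
    repulsion_radius: float


def _empty(shape, dtype=float):
    return np.zeros(shape, dtype=dtype)


@dataclass
class CGTopology:
    """Array-backed coarse-grained topology.

    Bonded terms are harmonic with energy ``k (X - X0)^2``; native contacts and
    target-site terms use the 12-10 well ``f k [5 (A/r)^12 - 6 (A/r)^10]``.
    ``contact_f`` / ``dihedral_f`` are flexibility scales in [0, 1].
    """

    positions: np.ndarray
    roles: np.ndarray
    charges: np.ndarray
    residue_ids: np.ndarray
    chain_ids: np.ndarray
    radii: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: _empty((0, 2), int))
    bond_x0: np.ndarray = field(default_factory=lambda: _empty(0))
    bond_k: np.ndarray = field(default_factory=lambda: _empty(0))
    angles: np.ndarray = field(default_factory=lambda: _empty((0, 3), int))
    angle_x0: np.ndarray = field(default_factory=lambda: _empty(0))
    angle_k: np.ndarray = field(default_factory=lambda: _empty(0))
    dihedrals: np.ndarray = field(default_factory=lambda: _empty((0, 4), int))
    dihedral_x0: np.ndarray = field(default_factory=lambda: _empty(0))
    dihedral_k: np.ndarray = field(default_factory=lambda: _empty(0))
    dihedral_f: np.ndarray = field(default_factory=lambda: _empty(0))
    contacts: np.ndarray = field(default_factory=lambda: _empty((0, 2), int))
    contact_a: np.ndarray = field(default_factory=lambda: _empty(0))
    contact_k: np.ndarray = field(default_factory=lambda: _empty(0))
    contact_f: np.ndarray = field(default_factory=lambda: _empty(0))
    target_pairs: np.ndarray = field(default_factory=lambda: _empty((0, 2), int))
    target_a: np.ndarray = field(default_factory=lambda: _empty(0))
    target_k: np.ndarray = field(default_factory=lambda: _empty(0))

    # ------------------------------------------------------------------ basic
    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[0])

    @property
    def is_protein(self) -> np.ndarray:
        return self.roles == ROLE_CA

    @property
    def is_dna(self) -> np.ndarray:
        return self.roles != ROLE_CA

    @property
    def beads(self) -> list[CGBead]:
        return [
            CGBead(
                index=i,
                role=str(self.roles[i]),
                position=self.positions[i].copy(),
                charge=float(self.charges[i]),
                residue_id=int(self.residue_ids[i]),
                chain_id=str(self.chain_ids[i]),
                repulsion_radius=float(self.radii[i]),
            )
            for i in range(self.n_beads)
        ]

    def copy(self) -> "CGTopology":
        kw = {}
        for name in self.__dataclass_fields__:
            kw[name] = getattr(self, name).copy()
        return CGTopology(**kw)

    def sequence_separation(self, i: int, j: int) -> float:
        """|res_i - res_j| within a chain, inf across chains."""
        if self.chain_ids[i] != self.chain_ids[j]:
            return np.inf
        return abs(int(self.residue_ids[i]) - int(self.residue_ids[j]))

    # -------------------------------------------------------------- mutation
    def add_contacts(self, pairs, a, k=None, f=None) -> None:
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        a = np.asarray(a, dtype=float)
        if np.any(a <= 0):
            raise ValueError("contact reference distances A_ij must be positive")
        for i, j in pairs:
            if self.sequence_separation(i, j) <= 3:
                raise ValueError(
                    f"contact ({i},{j}) violates the >3 sequence-separation rule"
                )
        k = np.full(len(pairs), C.K_CONTACT) if k is None else np.asarray(k, float)
        f = np.ones(len(pairs)) if f is None else np.asarray(f, float)
        self.contacts = np.vstack([self.contacts, pairs])
        self.contact_a = np.concatenate([self.contact_a, a])
        self.contact_k = np.concatenate([self.contact_k, k])
        self.contact_f = np.concatenate([self.contact_f, f])

    def set_target_terms(self, pairs, a, k=None) -> None:
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        self.target_pairs = pairs
        self.target_a = np.asarray(a, dtype=float)
        self.target_k = (
            np.full(len(pairs), C.K_CONTACT) if k is None else np.asarray(k, float)
        )
        # DNA beads held by a target-site potential become more penetrable so
        # the protein can actually reach the reference separations.
        for _, j in pairs:
            if self.roles[j] != ROLE_CA:
                self.radii[j] = C.R_DNA_TARGET
        for i, _ in pairs:
            if self.roles[i] != ROLE_CA:
                self.radii[i] = C.R_DNA_TARGET

    # --------------------------------------------------------------- combine
    def merge(self, other: "CGTopology") -> "CGTopology":
        """Concatenate two topologies (indices of *other* are shifted)."""
        off = self.n_beads
        out = self.copy()
        out.positions = np.vstack([self.positions, other.positions])
        out.roles = np.concatenate([self.roles, other.roles])
        out.charges = np.concatenate([self.charges, other.charges])
        out.residue_ids = np.concatenate([self.residue_ids, other.residue_ids])
        out.chain_ids = np.concatenate([self.chain_ids, other.chain_ids])
        out.radii = np.concatenate([self.radii, other.radii])
        for name, width in [
            ("bonds", 2), ("angles", 3), ("dihedrals", 4),
            ("contacts", 2), ("target_pairs", 2),
        ]:
            mine = getattr(self, name)
            theirs = getattr(other, name)
            setattr(out, name, np.vstack([mine, theirs + off]).astype(int))
        for name in [
            "bond_x0", "bond_k", "angle_x0", "angle_k",
            "dihedral_x0", "dihedral_k", "dihedral_f",
            "contact_a", "contact_k", "contact_f", "target_a", "target_k",
        ]:
            setattr(out, name, np.concatenate([getattr(self, name), getattr(other, name)]))
        return out

    # ------------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        d = {}
        for name in self.__dataclass_fields__:
            arr = getattr(self, name)
            d[name] = arr.tolist()
        d["format"] = "grooveslide-topology-1"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CGTopology":
        kw = {}
        int_fields = {"bonds", "angles", "dihedrals", "contacts", "target_pairs"}
        widths = {"bonds": 2, "angles": 3, "dihedrals": 4, "contacts": 2,
                  "target_pairs": 2}
        for name in cls.__dataclass_fields__:
            val = d[name]
            if name in ("roles", "chain_ids"):
                kw[name] = np.asarray(val, dtype="<U12")
            elif name == "residue_ids":
                kw[name] = np.asarray(val, dtype=int)
            elif name in int_fields:
                arr = np.asarray(val, dtype=int)
                kw[name] = arr.reshape(-1, widths[name])
            else:
                arr = np.asarray(val, dtype=float)
                if name == "positions":
                    arr = arr.reshape(-1, 3)
                kw[name] = arr
        return cls(**kw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "CGTopology":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Structure -> topology builders.  Structures are biotite AtomArrays.
# ---------------------------------------------------------------------------

def _residue_groups(atoms):
    """Ordered list of (chain_id, res_id, atom-index array)."""
    keys = list(zip(atoms.chain_id.tolist(), atoms.res_id.tolist()))
    seen = {}
    order = []
    for idx, key in enumerate(keys):
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(idx)
    return [(c, r, np.asarray(seen[(c, r)], dtype=int)) for c, r in order]


def residue_charge(res_name: str, his_protonated: bool = False) -> float:
    res_name = res_name.upper()
    if res_name in POSITIVE_RESIDUES:
        return 1.0
    if res_name in NEGATIVE_RESIDUES:
        return -1.0
    if res_name in HISTIDINE:
        return 1.0 if his_protonated else 0.0
    return 0.0


def _chain_bonded_terms(top: CGTopology, chain_indices: list[np.ndarray],
                        flexibility=None) -> None:
    """Sequential bonds/angles/dihedrals along each run of connected beads."""
    pos = top.positions
    for run in chain_indices:
        run = np.asarray(run, dtype=int)
        for a, b in zip(run[:-1], run[1:]):
            top.bonds = np.vstack([top.bonds, [[a, b]]])
            top.bond_x0 = np.append(top.bond_x0, np.linalg.norm(pos[b] - pos[a]))
            top.bond_k = np.append(top.bond_k, C.K_BOND)
        for a, b, c in zip(run[:-2], run[1:-1], run[2:]):
            top.angles = np.vstack([top.angles, [[a, b, c]]])
            top.angle_x0 = np.append(top.angle_x0, angle(pos[a], pos[b], pos[c]))
            top.angle_k = np.append(top.angle_k, C.K_ANGLE)
        for a, b, c, d in zip(run[:-3], run[1:-2], run[2:-1], run[3:]):
            top.dihedrals = np.vstack([top.dihedrals, [[a, b, c, d]]])
            top.dihedral_x0 = np.append(
                top.dihedral_x0, dihedral(pos[a], pos[b], pos[c], pos[d])
            )
            top.dihedral_k = np.append(top.dihedral_k, C.K_DIHEDRAL)
            top.dihedral_f = np.append(top.dihedral_f, 1.0)


def coarse_grain_protein(atoms, his_protonated: bool = False) -> CGTopology:
    """One bead per residue at the Calpha position.

    Lys/Arg (and His when protonated) carry +1; Glu/Asp carry -1.  Consecutive
    residues are joined by bonds/angles/dihedrals whose reference values come
    from the input geometry; a Calpha-Calpha gap above 4.5 A is treated as a
    chain break (warning, no bonded term across it).
    """
    groups = _residue_groups(atoms)
    positions, roles, charges, res_ids, chain_ids, radii = [], [], [], [], [], []
    for chain, res, idx in groups:
        names = atoms.atom_name[idx]
        ca = idx[names == "CA"]
        if len(ca) == 0:
            raise StructureInputError(
                f"residue {atoms.res_name[idx[0]]} {res} (chain {chain}) has no CA atom"
            )
        positions.append(atoms.coord[ca[0]])
        res_name = str(atoms.res_name[idx[0]])
        roles.append(ROLE_CA)
        charges.append(residue_charge(res_name, his_protonated))
        res_ids.append(int(res))
        chain_ids.append(str(chain))
        radii.append(C.R_PROTEIN)

    top = CGTopology(
        positions=np.asarray(positions, dtype=float).reshape(-1, 3),
        roles=np.asarray(roles, dtype="<U12"),
        charges=np.asarray(charges, dtype=float),
        residue_ids=np.asarray(res_ids, dtype=int),
        chain_ids=np.asarray(chain_ids, dtype="<U12"),
        radii=np.asarray(radii, dtype=float),
    )

    # split each chain into runs at breaks
    runs = []
    for chain in dict.fromkeys(chain_ids):
        sel = np.where(top.chain_ids == chain)[0]
        run = [sel[0]]
        for a, b in zip(sel[:-1], sel[1:]):
            gap = np.linalg.norm(top.positions[b] - top.positions[a])
            if gap > CHAIN_BREAK_CUTOFF:
                warnings.warn(
                    f"chain break in chain {chain} between residues "
                    f"{top.residue_ids[a]} and {top.residue_ids[b]} "
                    f"(Calpha gap {gap:.2f} A)"
                )
                runs.append(run)
                run = [b]
            else:
                run.append(b)
        runs.append(run)
    _chain_bonded_terms(top, runs)
    return top


_SUGAR_MARKS = ("'", "*")


def _dna_atom_role(name: str) -> str:
    if name in PHOSPHATE_ATOMS:
        return ROLE_PHOSPHATE
    if any(m in name for m in _SUGAR_MARKS):
        return ROLE_SUGAR
    return ROLE_BASE


def coarse_grain_dna(atoms) -> CGTopology:
    """Three beads per nucleotide at the geometric centers of the sugar, base
    and phosphate atom groups; phosphates carry -1.

    A 5' nucleotide without phosphate atoms simply omits that bead (warning).
    """
    groups = _residue_groups(atoms)
    positions, roles, charges, res_ids, chain_ids, radii = [], [], [], [], [], []
    strand_runs: dict[str, list[list[int]]] = {}
    for chain, res, idx in groups:
        res_name = str(atoms.res_name[idx[0]]).strip()
        if res_name.upper() not in DNA_RESNAMES:
            raise StructureInputError(f"unknown nucleotide residue name {res_name!r}")
        by_role = {ROLE_PHOSPHATE: [], ROLE_SUGAR: [], ROLE_BASE: []}
        for i in idx:
            nm = str(atoms.atom_name[i]).strip()
            if str(atoms.element[i]).upper() == "H" or nm.startswith("H"):
                continue
            by_role[_dna_atom_role(nm)].append(i)
        nt_beads = {}
        for role in (ROLE_PHOSPHATE, ROLE_SUGAR, ROLE_BASE):
            members = by_role[role]
            if not members:
                if role == ROLE_PHOSPHATE:
                    warnings.warn(
                        f"nucleotide {res_name} {res} (chain {chain}) lacks a "
                        "phosphate group; bead omitted (5' terminus?)"
                    )
                    continue
                raise StructureInputError(
                    f"nucleotide {res_name} {res} (chain {chain}) lacks {role} atoms"
                )
            center = atoms.coord[members].mean(axis=0)
            nt_beads[role] = len(positions)
            positions.append(center)
            roles.append(role)
            charges.append(-1.0 if role == ROLE_PHOSPHATE else 0.0)
            res_ids.append(int(res))
            chain_ids.append(str(chain))
            radii.append(C.R_DNA)
        strand_runs.setdefault(str(chain), []).append(
            [nt_beads.get(ROLE_PHOSPHATE), nt_beads[ROLE_SUGAR], nt_beads[ROLE_BASE]]
        )

    top = CGTopology(
        positions=np.asarray(positions, dtype=float).reshape(-1, 3),
        roles=np.asarray(roles, dtype="<U12"),
        charges=np.asarray(charges, dtype=float),
        residue_ids=np.asarray(res_ids, dtype=int),
        chain_ids=np.asarray(chain_ids, dtype="<U12"),
        radii=np.asarray(radii, dtype=float),
    )

    # intra-strand connectivity: the backbone alternates P(i)-S(i)-P(i+1)-...
    # with the base hanging off each sugar.
    backbone_runs = []
    extra_bonds = []
    for chain, nts in strand_runs.items():
        backbone = []
        for k, (p, s, b) in enumerate(nts):
            if p is not None:
                backbone.append(p)
            backbone.append(s)
            extra_bonds.append((s, b))
        backbone_runs.append(backbone)
    _chain_bonded_terms(top, backbone_runs)
    for s, b in extra_bonds:
        top.bonds = np.vstack([top.bonds, [[s, b]]])
        top.bond_x0 = np.append(
            top.bond_x0, np.linalg.norm(top.positions[b] - top.positions[s])
        )
        top.bond_k = np.append(top.bond_k, C.K_BOND)
    return top


def compute_native_contacts(atoms, cg: CGTopology, heavy_atom_cutoff: float = 4.5):
    """Residue pairs with any heavy-atom pair within the cutoff and sequence
    separation > 3 (or inter-chain).  A_ij is the Calpha-Calpha (bead-bead)
    distance in the reference.

    Returns ``(pairs, a_ij)`` as arrays of bead-index pairs and reference
    distances; attach with :meth:`CGTopology.add_contacts`.
    """
    if heavy_atom_cutoff <= 0:
        raise ValueError("heavy_atom_cutoff must be positive")
    groups = _residue_groups(atoms)
    heavy = [
        g[2][np.asarray([
            not (str(atoms.element[i]).upper() == "H" or str(atoms.atom_name[i]).startswith("H"))
            for i in g[2]
        ])]
        for g in groups
    ]
    # map (chain, res) -> CA bead index
    bead_of = {}
    for b in range(cg.n_beads):
        if cg.roles[b] == ROLE_CA:
            bead_of[(str(cg.chain_ids[b]), int(cg.residue_ids[b]))] = b
    pairs, aij = [], []
    n = len(groups)
    for x in range(n):
        cx, rx, _ = groups[x]
        bx = bead_of.get((str(cx), int(rx)))
        if bx is None:
            continue
        for y in range(x + 1, n):
            cy, ry, _ = groups[y]
            by = bead_of.get((str(cy), int(ry)))
            if by is None:
                continue
            if cx == cy and abs(int(rx) - int(ry)) <= 3:
                continue
            if len(heavy[x]) == 0 or len(heavy[y]) == 0:
                continue
            dmin = cdist(atoms.coord[heavy[x]], atoms.coord[heavy[y]]).min()
            if dmin <= heavy_atom_cutoff:
                pairs.append((bx, by))
                aij.append(np.linalg.norm(cg.positions[by] - cg.positions[bx]))
    return np.asarray(pairs, dtype=int).reshape(-1, 2), np.asarray(aij, dtype=float)


def apply_flexibility(cg: CGTopology, residue_set, f: float) -> CGTopology:
    """Scale dihedral and native-contact force constants for a residue set.

    Dihedrals with all four residues in the set and contacts with either
    residue in the set receive flexibility scale ``f``; bonds and angles are
    untouched.  Residues are given as ``(chain_id, res_id)`` pairs, or as bare
    residue ids (matched in every chain).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("flexibility scale f must lie in [0, 1]")
    keyed = set()
    anychain = set()
    for r in residue_set:
        if isinstance(r, tuple):
            keyed.add((str(r[0]), int(r[1])))
        else:
            anychain.add(int(r))

    def in_set(b):
        rid = int(cg.residue_ids[b])
        return rid in anychain or (str(cg.chain_ids[b]), rid) in keyed

    out = cg.copy()
    for t, quad in enumerate(out.dihedrals):
        if all(in_set(b) for b in quad):
            out.dihedral_f[t] = f
    for t, (i, j) in enumerate(out.contacts):
        if in_set(i) or in_set(j):
            out.contact_f[t] = f
    return out


def build_target_site_potential(atoms, cg: CGTopology, dna_span,
                                heavy_atom_cutoff: float = 4.5):
    """12-10 protein-bead/DNA-bead terms from a bound complex.

    ``dna_span`` is an inclusive (first_bp, last_bp) residue-id range on the
    DNA; protein-residue/nucleotide pairs with any heavy-atom pair within the
    cutoff contribute one term per (CA bead, nearest DNA bead), with A_ij taken
    from the bead-bead distance in the complex.  Returns ``(pairs, a_ij)``;
    attach with :meth:`CGTopology.set_target_terms`.
    """
    span = range(int(dna_span[0]), int(dna_span[1]) + 1) if len(tuple(dna_span)) == 2 else dna_span
    span = set(int(x) for x in span)
    is_prot = cg.is_protein
    pairs, aij = [], []
    if span and heavy_atom_cutoff <= 0:
        raise ValueError("heavy_atom_cutoff must be positive")
    if span:
        prot_idx = np.where(is_prot)[0]
        dna_idx = np.where(~is_prot & np.isin(cg.residue_ids, list(span)))[0]
        if len(prot_idx) and len(dna_idx):
            d = cdist(cg.positions[prot_idx], cg.positions[dna_idx])
            # heavy atoms of the specific group each bead represents
            groups = {(str(c), int(r)): idx for c, r, idx in _residue_groups(atoms)}

            def bead_atoms(b):
                g = groups.get((str(cg.chain_ids[b]), int(cg.residue_ids[b])))
                if g is None:
                    return None
                keep = []
                for i in g:
                    nm = str(atoms.atom_name[i]).strip()
                    if str(atoms.element[i]).upper() == "H" or nm.startswith("H"):
                        continue
                    role = cg.roles[b]
                    if role == ROLE_CA or _dna_atom_role(nm) == role:
                        keep.append(i)
                return np.asarray(keep, dtype=int) if keep else None

            for a_i, bi in enumerate(prot_idx):
                gi = bead_atoms(bi)
                if gi is None:
                    continue
                for a_j, bj in enumerate(dna_idx):
                    if d[a_i, a_j] > 4.0 * heavy_atom_cutoff:
                        continue
                    gj = bead_atoms(bj)
                    if gj is None:
                        continue
                    if cdist(atoms.coord[gi], atoms.coord[gj]).min() <= heavy_atom_cutoff:
                        pairs.append((bi, bj))
                        aij.append(d[a_i, a_j])
    if not pairs:
        warnings.warn("no protein-DNA atom pairs within cutoff; empty target-site potential")
    return np.asarray(pairs, dtype=int).reshape(-1, 2), np.asarray(aij, dtype=float)
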