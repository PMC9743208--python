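"""Coarse-graining: bead placement, charges, bonded terms, native contacts,
flexibility scaling and topology round-trips."""
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from grooveslide.io import make_atom_array
from grooveslide.forcefield import build_pair_tables, contact_energy
from grooveslide.topology import (
    CGTopology, StructureInputError, apply_flexibility,
    build_target_site_potential, coarse_grain_dna, coarse_grain_protein,
    compute_native_contacts,
)
from grooveslide.synthetic import DNAGeometry, generate_ideal_bdna

from conftest import ca_protein


class TestProteinCoarseGraining:
    def test_tripeptide_charges_and_bonded_terms(self, tripeptide):
        top = coarse_grain_protein(tripeptide)
        assert top.n_beads == 3
        assert top.charges.tolist() == [1.0, 0.0, -1.0]
        assert len(top.bonds) == 2 and len(top.angles) == 1
        assert len(top.dihedrals) == 0
        assert np.allclose(top.bond_x0, 3.8)
        assert np.allclose(top.bond_k, 100.0)
        assert np.allclose(top.radii, 2.0)

    def test_single_residue_has_no_bonded_terms(self):
        top = coarse_grain_protein(ca_protein(["ALA"]))
        assert top.n_beads == 1
        assert len(top.bonds) == len(top.angles) == len(top.dihedrals) == 0

    def test_straight_chain_reference_geometry(self):
        top = coarse_grain_protein(ca_protein(["ALA"] * 3))
        assert np.allclose(top.bond_x0, 3.8)
        assert np.allclose(top.angle_x0, np.pi)

    def test_histidine_protonation_switch(self):
        atoms = ca_protein(["HIS"])
        assert coarse_grain_protein(atoms).charges[0] == 0.0
        assert coarse_grain_protein(atoms, his_protonated=True).charges[0] == 1.0

    def test_missing_ca_raises_naming_residue(self):
        atoms = make_atom_array([[0, 0, 0]], ["CB"], ["ALA"], [7], ["A"], ["C"])
        with pytest.raises(StructureInputError, match="ALA 7"):
            coarse_grain_protein(atoms)

    def test_chain_break_warns_and_skips_bond(self):
        coords = [[0, 0, 0], [3.8, 0, 0], [13.8, 0, 0], [17.6, 0, 0]]
        atoms = make_atom_array(coords, ["CA"] * 4, ["ALA"] * 4,
                                [1, 2, 3, 4], ["A"] * 4, ["C"] * 4)
        with pytest.warns(UserWarning, match="chain break"):
            top = coarse_grain_protein(atoms)
        assert len(top.bonds) == 2  # no bond across the 10 A gap
        assert len(top.angles) == 0

    @given(st.lists(st.sampled_from(
        ["LYS", "ARG", "HIS", "GLU", "ASP", "ALA", "GLY", "SER"]),
        min_size=1, max_size=25))
    @settings(max_examples=25, deadline=None)
    def test_net_charge_matches_sequence(self, seq):
        top = coarse_grain_protein(ca_protein(seq))
        expected = sum(seq.count(r) for r in ("LYS", "ARG")) \
            - sum(seq.count(r) for r in ("GLU", "ASP"))
        assert top.charges.sum() == expected
        assert top.n_beads == len(seq)


class TestDNACoarseGraining:
    def test_bead_and_charge_counts_100bp(self):
        _, top = generate_ideal_bdna(DNAGeometry(n_bp=100))
        assert top.n_beads == 600
        assert (top.charges == -1).sum() == 200
        assert np.allclose(top.radii, 3.7)

    def test_one_bp_duplex(self):
        _, top = generate_ideal_bdna(DNAGeometry(n_bp=1))
        assert top.n_beads == 6

    def test_sugar_bead_at_geometric_center(self):
        atoms = make_atom_array(
            [[0, 0, 0], [2, 0, 0], [5, 0, 0], [5, 3, 0]],
            ["C1'", "C2'", "N1", "P"], ["DA"] * 4, [1] * 4, ["D"] * 4,
            ["C", "C", "N", "P"],
        )
        top = coarse_grain_dna(atoms)
        sugar = top.positions[top.roles == "sugar"][0]
        assert np.allclose(sugar, [1, 0, 0])

    def test_missing_5prime_phosphate_warns_and_omits(self):
        atoms = make_atom_array(
            [[0, 0, 0], [3, 0, 0]], ["C1'", "N1"], ["DT"] * 2, [1] * 2,
            ["D"] * 2, ["C", "N"],
        )
        with pytest.warns(UserWarning, match="phosphate"):
            top = coarse_grain_dna(atoms)
        assert top.n_beads == 2
        assert "phosphate" not in top.roles

    def test_unknown_residue_name_raises(self):
        atoms = make_atom_array([[0, 0, 0]], ["C1'"], ["XXX"], [1], ["D"], ["C"])
        with pytest.raises(StructureInputError, match="XXX"):
            coarse_grain_dna(atoms)

    def test_phosphate_charge_minus_one(self):
        _, top = generate_ideal_bdna(DNAGeometry(n_bp=5))
        assert np.all(top.charges[top.roles == "phosphate"] == -1)
        assert np.all(top.charges[top.roles != "phosphate"] == 0)


class TestNativeContacts:
    def _two_residue_structure(self, ca_gap=6.2, heavy_gap=4.0, sep=7):
        # residues 1 and 1+sep, each CA + one side-chain atom; side chains
        # approach to heavy_gap while the CAs stay at ca_gap
        coords = [[0, 0, 0], [(ca_gap - heavy_gap) / 2, 1.0, 0],
                  [ca_gap, 0, 0], [ca_gap - (ca_gap - heavy_gap) / 2, 1.0, 0]]
        return make_atom_array(
            coords, ["CA", "CB", "CA", "CB"], ["ALA"] * 4,
            [1, 1, 1 + sep, 1 + sep], ["A"] * 4, ["C"] * 4,
        )

    def test_constructed_pair_becomes_contact(self):
        atoms = self._two_residue_structure()
        cg = coarse_grain_protein(atoms)
        pairs, aij = compute_native_contacts(atoms, cg, 4.5)
        assert len(pairs) == 1
        assert aij[0] == pytest.approx(6.2)

    def test_sequence_separation_three_never_contacts(self):
        atoms = self._two_residue_structure(sep=3, ca_gap=4.0, heavy_gap=3.0)
        cg = coarse_grain_protein(atoms)
        pairs, _ = compute_native_contacts(atoms, cg, 4.5)
        assert len(pairs) == 0

    def test_invalid_cutoff_raises(self, tripeptide):
        cg = coarse_grain_protein(tripeptide)
        with pytest.raises(ValueError):
            compute_native_contacts(tripeptide, cg, -1.0)

    def test_matches_exhaustive_pair_scan(self, rng):
        # oracle: plain double loop over residue pairs on a random CA blob
        n = 15
        coords = rng.normal(0, 6, (n, 3))
        atoms = make_atom_array(coords, ["CA"] * n, ["ALA"] * n,
                                list(range(1, n + 1)), ["A"] * n, ["C"] * n)
        cg = coarse_grain_protein(atoms)
        pairs, aij = compute_native_contacts(atoms, cg, 7.5)
        expected = set()
        for i in range(n):
            for j in range(i + 1, n):
                if j - i > 3 and np.linalg.norm(coords[j] - coords[i]) <= 7.5:
                    expected.add((i, j))
        assert {tuple(p) for p in pairs} == expected
        for (i, j), a in zip(pairs, aij):
            assert a == pytest.approx(np.linalg.norm(coords[j] - coords[i]))

    def test_contact_excluded_volume_exclusive(self, rng):
        n = 12
        coords = rng.normal(0, 5, (n, 3))
        atoms = make_atom_array(coords, ["CA"] * n, ["ALA"] * n,
                                list(range(1, n + 1)), ["A"] * n, ["C"] * n)
        cg = coarse_grain_protein(atoms)
        pairs, aij = compute_native_contacts(atoms, cg, 7.0)
        if len(pairs):
            cg.add_contacts(pairs, aij)
        tables = build_pair_tables(cg)
        ev = {tuple(sorted(p)) for p in tables.ev_pairs}
        con = {tuple(sorted(p)) for p in cg.contacts}
        assert not ev & con


class TestFlexibility:
    @pytest.fixture
    def contact_topology(self):
        atoms = ca_protein(["ALA"] * 8, jitter=1.0, seed=3)
        cg = coarse_grain_protein(atoms)
        pairs, aij = compute_native_contacts(atoms, cg, 8.0)
        cg.add_contacts(pairs, aij)
        return cg

    def test_f_one_is_identity_and_idempotent(self, contact_topology):
        once = apply_flexibility(contact_topology, {("A", 4), ("A", 5)}, 1.0)
        twice = apply_flexibility(once, {("A", 4), ("A", 5)}, 1.0)
        assert np.array_equal(once.contact_f, contact_topology.contact_f)
        assert np.array_equal(twice.dihedral_f, once.dihedral_f)

    def test_f_zero_silences_hinge_terms(self, contact_topology):
        residues = {("A", r) for r in range(1, 9)}
        flex = apply_flexibility(contact_topology, residues, 0.0)
        pos = flex.positions + 0.5
        assert contact_energy(flex, pos) == 0.0
        assert np.all(flex.dihedral_f == 0.0)

    def test_half_scale_halves_contact_depth(self, contact_topology):
        residues = {("A", r) for r in range(1, 9)}
        flex = apply_flexibility(contact_topology, residues, 0.5)
        # at the native geometry every 12-10 well sits at its minimum -k f
        e = contact_energy(flex, flex.positions)
        assert e == pytest.approx(-0.5 * len(flex.contacts))

    def test_invalid_scale_raises(self, contact_topology):
        with pytest.raises(ValueError):
            apply_flexibility(contact_topology, {("A", 1)}, 1.5)

    def test_bonds_and_angles_untouched(self, contact_topology):
        flex = apply_flexibility(contact_topology, {("A", r) for r in range(1, 9)}, 0.0)
        assert np.array_equal(flex.bond_k, contact_topology.bond_k)
        assert np.array_equal(flex.angle_k, contact_topology.angle_k)


class TestTargetSite:
    def _complex(self, gap=5.5):
        # one CA residue near one nucleotide
        prot = make_atom_array([[0, 0, gap]], ["CA"], ["ARG"], [1], ["P"], ["C"])
        dna = make_atom_array(
            [[0, 0, 0], [3, 0, 0], [6, 0, 0]], ["P", "C1'", "N1"],
            ["DA"] * 3, [1] * 3, ["D"] * 3, ["P", "C", "N"],
        )
        import biotite.structure as struc
        atoms = struc.concatenate([dna, prot])
        cg = coarse_grain_dna(dna).merge(coarse_grain_protein(prot))
        return atoms, cg

    def test_single_qualifying_pair(self):
        atoms, cg = self._complex(gap=4.4)
        pairs, aij = build_target_site_potential(atoms, cg, (1, 1), 4.5)
        assert len(pairs) == 1
        assert aij[0] == pytest.approx(4.4)
        cg.set_target_terms(pairs, aij)
        # 12-10 minimum of depth -k at the reference separation
        e = contact_energy(cg, cg.positions)
        assert e == pytest.approx(-1.0)
        # engaged DNA bead becomes more penetrable
        assert cg.radii[pairs[0][1]] == pytest.approx(3.0)

    def test_empty_span_gives_empty_terms(self):
        atoms, cg = self._complex()
        with pytest.warns(UserWarning, match="target-site"):
            pairs, _ = build_target_site_potential(atoms, cg, (5, 4), 4.5)
        assert len(pairs) == 0

    def test_matches_bruteforce_scan(self, rng):
        geom = DNAGeometry(n_bp=4)
        dna_atoms, dna = generate_ideal_bdna(geom)
        n = 6
        coords = rng.normal(0, 4, (n, 3)) + [0, 11, 0]
        prot_atoms = make_atom_array(coords, ["CA"] * n, ["ALA"] * n,
                                     list(range(1, n + 1)), ["P"] * n, ["C"] * n)
        import biotite.structure as struc
        atoms = struc.concatenate([dna_atoms, prot_atoms])
        cg = dna.merge(coarse_grain_protein(prot_atoms))
        pairs, aij = build_target_site_potential(atoms, cg, (1, 4), 6.0)
        # oracle: exhaustive scan over (protein bead, DNA bead) distances --
        # every pseudo-atom coincides with its bead here
        expected = set()
        prot_idx = np.where(cg.is_protein)[0]
        dna_idx = np.where(cg.is_dna)[0]
        d = cdist(cg.positions[prot_idx], cg.positions[dna_idx])
        for a, i in enumerate(prot_idx):
            for b, j in enumerate(dna_idx):
                if d[a, b] <= 6.0:
                    expected.add((int(i), int(j)))
        assert {tuple(p) for p in pairs} == expected


class TestRoundTrip:
    def test_json_round_trip_is_lossless(self, tmp_path):
        atoms = ca_protein(["ALA"] * 8, jitter=0.8, seed=1)
        cg = coarse_grain_protein(atoms)
        p, a = compute_native_contacts(atoms, cg, 8.0)
        if len(p):
            cg.add_contacts(p, a)
        path = tmp_path / "top.json"
        cg.to_json(path)
        back = CGTopology.from_json(path)
        for name in cg.__dataclass_fields__:
            assert np.array_equal(getattr(cg, name), getattr(back, name)), name

    def test_merge_preserves_counts_and_offsets(self, tripeptide):
        a = coarse_grain_protein(tripeptide)
        _, b = generate_ideal_bdna(DNAGeometry(n_bp=2))
        m = b.merge(a)
        assert m.n_beads == a.n_beads + b.n_beads
        assert m.bonds.shape[0] == a.bonds.shape[0] + b.bonds.shape[0]
        assert m.charges.sum() == a.charges.sum() + b.charges.sum()
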