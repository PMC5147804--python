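"""Structural annotation: secondary structure, ASA/RSA, contacts."""

import math

import numpy as np
import pytest

from ssrobust._geometry import PHI_PSI, build_backbone
from ssrobust.structcalc import (ContactMap, ResidueAnnotation, assign_ss,
                                 compute_asa, compute_contacts, compute_rsa,
                                 contact_stats, max_asa_table, ss8_to_ss3,
                                 _ks_hbond_matrix)
from ssrobust.structio import Atom, DomainStructure, Residue
from ssrobust.synthetic_data import make_ideal_structure


def _point_structure(points, radius_element="C", split_residues=True):
    """One atom per residue at the given coordinates (non-adjacent contacts)."""
    residues = []
    for i, p in enumerate(points):
        atoms = (Atom("X" + str(i), radius_element, tuple(map(float, p))),)
        residues.append(Residue(2 * i + 1 if split_residues else i + 1, "", "A",
                                atoms))
    return DomainStructure(sid="pts", residues=residues)


class TestAssignSS:
    def test_ideal_helix_interior_is_h(self):
        helix = make_ideal_structure("helix", 15)
        ss = assign_ss(helix)
        assert all(s == "H" for s in ss[1:-1])

    def test_helix_hbond_ladder_matches_direct_energy(self):
        """Oracle: the i -> i+4 donor pattern evaluated bond by bond."""
        helix = make_ideal_structure("helix", 15)
        hb = _ks_hbond_matrix(helix)
        for i in range(11):
            assert hb[i, i + 4], f"missing CO({i})..NH({i + 4})"
        # no spurious i -> i+3 or i -> i+5 bonds in the ideal alpha geometry
        assert not any(hb[i, i + 3] for i in range(12))

    def test_dipeptide_is_all_coil(self):
        di = build_backbone("AA", [PHI_PSI["helix"]] * 2)
        assert assign_ss(di) == ["C", "C"]

    def test_antiparallel_pair_interior_is_strand(self):
        hp = make_ideal_structure("hairpin", 10)
        ss = assign_ss(hp)
        # strands occupy residues 0-9 and 12-21 around the 2-residue turn
        assert all(s == "E" for s in ss[1:9])
        assert all(s == "E" for s in ss[13:21])
        assert ss[10] == "C" and ss[11] == "C"

    def test_lone_strand_has_no_partner_hence_coil(self):
        strand = make_ideal_structure("strand", 15)
        assert set(assign_ss(strand)) == {"C"}

    def test_two_residue_strand_pair_cannot_form_ladder(self):
        strand = make_ideal_structure("strand", 2)
        assert assign_ss(strand) == ["C", "C"]

    def test_missing_backbone_warns_and_coils(self):
        res = [Residue(1, "", "A", (Atom("CA", "C", (0.0, 0.0, 0.0)),)),
               Residue(2, "", "A", (Atom("CA", "C", (3.8, 0.0, 0.0)),)),
               Residue(3, "", "A", (Atom("CA", "C", (7.6, 0.0, 0.0)),))]
        dom = DomainStructure(sid="bad", residues=res)
        with pytest.warns(UserWarning, match="missing"):
            assert assign_ss(dom) == ["C", "C", "C"]

    def test_idempotent_on_ideal_geometry(self):
        """Rebuilding from the assigned state's canonical dihedrals is stable."""
        helix = make_ideal_structure("helix", 12)
        ss1 = assign_ss(helix)
        rebuilt = make_ideal_structure("helix", 12)
        assert assign_ss(rebuilt) == ss1


class TestSS8Reduction:
    @pytest.mark.parametrize("ss8,expected", [
        ("H", "H"), ("G", "H"), ("I", "H"),
        ("E", "E"), ("B", "E"),
        ("T", "C"), ("S", "C"), (" ", "C"),
    ])
    def test_default_mapping(self, ss8, expected):
        assert ss8_to_ss3(ss8) == expected

    def test_unknown_letter_warns_to_coil(self):
        with pytest.warns(UserWarning):
            assert ss8_to_ss3("Z") == "C"

    def test_configurable_mapping(self):
        assert ss8_to_ss3("G", mapping={"G": "C"}) == "C"


class TestASA:
    def test_single_atom_closed_form(self):
        dom = _point_structure([(0, 0, 0)])
        asa = compute_asa(dom, n_points=960)
        expected = 4 * math.pi * (1.7 + 1.4) ** 2
        assert abs(asa[0] - expected) / expected < 0.01

    def test_fully_enclosed_atom_has_zero_asa(self):
        # shell of 26 neighbors on a tight cube grid occludes the center
        shell = [(dx, dy, dz) for dx in (-2, 0, 2) for dy in (-2, 0, 2)
                 for dz in (-2, 0, 2) if (dx, dy, dz) != (0, 0, 0)]
        dom = _point_structure([(0, 0, 0)] + shell)
        asa = compute_asa(dom, n_points=960)
        assert asa[0] == 0.0

    def test_two_overlapping_atoms_symmetric_and_reduced(self):
        dom = _point_structure([(0, 0, 0), (1.0, 0, 0)])
        asa = compute_asa(dom, n_points=960)
        isolated = 4 * math.pi * (1.7 + 1.4) ** 2
        assert asa[0] == pytest.approx(asa[1], rel=0.02)
        assert asa[0] < isolated

    def test_monotone_under_added_neighbor(self):
        """Adding an atom never increases any existing residue's ASA."""
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 8, size=(12, 3))
        base = compute_asa(_point_structure(pts), n_points=240)
        for extra in rng.uniform(0, 8, size=(5, 3)):
            more = compute_asa(_point_structure(np.vstack([pts, extra])),
                               n_points=240)
            assert np.all(more[:12] <= base + 1e-9)

    def test_agrees_with_independent_shrake_rupley(self):
        """Cross-check against Biopython's implementation on a real backbone."""
        from Bio.PDB.SASA import ShrakeRupley
        from Bio.PDB.StructureBuilder import StructureBuilder

        dom = make_ideal_structure("helix", 10)
        builder = StructureBuilder()
        builder.init_structure("x")
        builder.init_model(0)
        builder.init_chain("A")
        builder.init_seg(" ")
        for res in dom.residues:
            builder.init_residue("ALA", " ", res.number, " ")
            for a in res.atoms:
                builder.set_line_counter(0)
                builder.init_atom(a.name, np.array(a.coords), 0.0, 1.0, " ",
                                  a.name, element=a.element)
        structure = builder.get_structure()
        sr = ShrakeRupley(probe_radius=1.4, n_points=960)
        sr.compute(structure, level="R")
        theirs = np.array([r.sasa for r in structure.get_residues()])
        ours = compute_asa(dom, n_points=960)
        # different point sets and radii tables; agreement within 10%
        assert np.all(np.abs(ours - theirs) / np.maximum(theirs, 1.0) < 0.10)


class TestRSA:
    def test_zero_asa_gives_zero(self):
        assert compute_rsa(0.0, "A") == 0.0

    def test_table_maximum_gives_one(self):
        table = max_asa_table()
        assert compute_rsa(table["W"], "W") == pytest.approx(1.0)

    def test_gly_x_gly_central_residue_near_one(self):
        """The normalization tripeptide itself must score rsa ~ 1."""
        from ssrobust._geometry import build_backbone
        from ssrobust.synthetic_data import STRAND_PHI_PSI

        for aa in "AVLW":
            tri = build_backbone(f"G{aa}G", [STRAND_PHI_PSI] * 3)
            asa = compute_asa(tri, n_points=960)
            rsa = compute_rsa(asa[1], aa)
            assert abs(rsa - 1.0) < 0.10

    def test_unknown_amino_acid_is_undefined(self):
        assert compute_rsa(50.0, "X") is None

    def test_values_above_one_retained(self):
        table = max_asa_table()
        assert compute_rsa(table["A"] * 1.2, "A") == pytest.approx(1.2)


class TestContacts:
    def test_surface_gap_rule(self):
        # two carbons (r=1.7) at 3.6 A: gap 0.2 < 0.25 -> contact
        dom = _point_structure([(0, 0, 0), (3.6, 0, 0)])
        cmap = compute_contacts(dom)
        assert (0, 1) in cmap and len(cmap) == 1

    def test_gap_at_threshold_is_not_contact(self):
        dom = _point_structure([(0, 0, 0), (3.7, 0, 0)])
        assert len(compute_contacts(dom)) == 0

    def test_peptide_bond_excluded_but_other_adjacent_atoms_count(self):
        helix = make_ideal_structure("helix", 6)
        cmap = compute_contacts(helix)
        for i, j in cmap.pairs():
            assert i != j

    def test_intra_residue_pairs_excluded(self):
        res = Residue(1, "", "A", (Atom("CA", "C", (0.0, 0.0, 0.0)),
                                   Atom("CB", "C", (1.5, 0.0, 0.0))))
        res2 = Residue(5, "", "A", (Atom("CA", "C", (20.0, 0.0, 0.0)),))
        dom = DomainStructure(sid="two", residues=[res, res2])
        assert len(compute_contacts(dom)) == 0

    def test_grid_equals_brute_force_on_random_structure(self):
        """Spatial-index result identical to the all-pairs double loop."""
        rng = np.random.default_rng(7)
        coil = make_ideal_structure("coil", 50, seed=3)
        fast = compute_contacts(coil)
        slow = compute_contacts(coil, _brute_force=True)
        assert fast.pairs() == slow.pairs()
        for i, j in fast.pairs():
            assert fast.gap(i, j) == pytest.approx(slow.gap(i, j))

    def test_symmetry(self):
        helix = make_ideal_structure("helix", 12)
        cmap = compute_contacts(helix)
        for i, j in cmap.pairs():
            assert (j, i) in cmap

    def test_helix_has_more_short_range_contacts_than_strand(self):
        """Interior helix residues out-contact the lone extended strand."""
        helix = make_ideal_structure("helix", 15)
        strand = make_ideal_structure("strand", 15)
        ch = compute_contacts(helix)
        cs = compute_contacts(strand)

        def short_range(cmap, i):
            return sum(1 for j in cmap.partners(i) if abs(i - j) <= 4)

        for i in range(4, 11):
            assert short_range(ch, i) > short_range(cs, i)


class TestContactStats:
    def test_two_partners(self):
        cmap = ContactMap(12)
        cmap.add(2, 5, 0.1)
        cmap.add(2, 7, 0.2)
        assert contact_stats(cmap, 2) == (2, 4.0)

    def test_no_partners_undefined(self):
        cmap = ContactMap(5)
        assert contact_stats(cmap, 1) == (0, None)

    def test_matches_enumeration_oracle_on_fixture(self):
        """Direct enumeration over the map reproduces every residue's stats."""
        dom = make_ideal_structure("helix", 20)
        cmap = compute_contacts(dom)
        pairs = cmap.pairs()
        for i in range(20):
            partners = sorted({b for a, b in pairs if a == i}
                              | {a for a, b in pairs if b == i})
            n, mcd = contact_stats(cmap, i)
            assert n == len(partners)
            if partners:
                assert mcd == pytest.approx(
                    sum(abs(i - j) for j in partners) / len(partners))
            else:
                assert mcd is None
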