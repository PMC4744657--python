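"""van der Waals clash detection and the clashes-per-1000-atoms score."""

import numpy as np
import pytest

import hofaudit as ha
from hofaudit.clash import find_clashes, min_interresidue_h_distance
from hofaudit.elements import vdw_radius
from hofaudit.structure import AtomRecord, MolecularStructure, infer_bonds


def brute_force_clashes(s, cutoff=0.4, exclude_within_bonds=3,
                        polar_h_radius=1.0):
    """All-pairs reference implementation (no spatial index)."""
    from hofaudit.clash import _topo_excluded_pairs, _is_hbond, _DONOR_ELEMENTS

    coords = s.coords
    idx = s.serial_to_index
    adj = s.adjacency()
    elements = [a.element for a in s.atoms]
    radii = []
    for a in s.atoms:
        r = vdw_radius(a.element)
        if (
            polar_h_radius is not None
            and a.element == "H"
            and any(elements[idx[p]] in _DONOR_ELEMENTS for p in adj[a.serial])
        ):
            r = polar_h_radius
        radii.append(r)
    excluded = _topo_excluded_pairs(s, exclude_within_bonds)
    found = set()
    n = len(s.atoms)
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = s.atoms[i].serial, s.atoms[j].serial
            pair = (min(sa, sb), max(sa, sb))
            if pair in excluded:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if radii[i] + radii[j] - d < cutoff:
                continue
            exempt = False
            for h, o in ((sa, sb), (sb, sa)):
                if elements[idx[h]] == "H" and _is_hbond(
                    idx, coords, elements, adj, h, o, 2.5, 120.0
                ):
                    exempt = True
            if not exempt:
                found.add(pair)
    return found


class TestFindClashes:
    def test_engineered_hh_contact(self, clash_fixture):
        report = find_clashes(clash_fixture)
        assert len(report.records) == 1
        r = report.records[0]
        assert r.distance == pytest.approx(1.78, abs=1e-9)
        # Bondi H radius 1.20 on both sides (C-bonded hydrogens)
        assert r.overlap == pytest.approx(1.20 + 1.20 - 1.78, abs=1e-9)
        assert r.residue_a[2] != r.residue_b[2]  # spans the two residues

    def test_no_clash_at_vdw_contact(self):
        s = ha.make_clash_fixture(h_h_distance=2.40)
        assert find_clashes(s).records == []

    def test_covalent_pair_never_reported(self):
        # water O-H at 0.9572 Å would be a gross overlap if eligible
        atoms = [AtomRecord(1, "O", "O", "HOH", 1, "A", (0, 0, 0), True)]
        s = ha.add_hydrogens(infer_bonds(MolecularStructure(atoms=atoms)))
        assert find_clashes(s).records == []

    def test_rejects_heavy_atom_only(self):
        s = ha.make_polyalanine(2, hydrogens=False)
        with pytest.raises(ValueError, match="no hydrogens"):
            find_clashes(s)

    def test_clashscore_definition(self, clash_fixture):
        report = find_clashes(clash_fixture)
        assert report.clashscore == pytest.approx(
            1000.0 * len(report.records) / len(clash_fixture.atoms)
        )

    def test_ideal_chains_are_clash_free(self, helix10, extended10):
        assert find_clashes(helix10).clashscore == 0.0
        assert find_clashes(extended10).clashscore == 0.0

    def test_rigid_motion_invariance(self, clash_fixture, rng):
        ref = {(r.serial_a, r.serial_b) for r in find_clashes(clash_fixture).records}
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = clash_fixture.with_coords(
            clash_fixture.coords @ q.T + rng.normal(size=3) * 5
        )
        got = {(r.serial_a, r.serial_b) for r in find_clashes(moved).records}
        assert got == ref

    def test_cutoff_monotonicity(self, clash_fixture):
        counts = [
            len(find_clashes(clash_fixture, overlap_cutoff=c).records)
            for c in (0.0, 0.2, 0.4, 0.6, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_on_random_structure(self, rng):
        """KD-tree candidate search equals exhaustive enumeration."""
        n = 400
        elements = rng.choice(["H", "C", "N", "O"], size=n, p=[0.5, 0.3, 0.1, 0.1])
        coords = rng.uniform(0, 18.0, size=(n, 3))
        atoms = [
            AtomRecord(i + 1, str(e), str(e), "UNK", i // 10 + 1, "A",
                       tuple(coords[i]), False)
            for i, e in enumerate(elements)
        ]
        with pytest.warns(UserWarning):  # random H's rarely bond cleanly
            s = infer_bonds(MolecularStructure(atoms=atoms))
        got = {(r.serial_a, r.serial_b) for r in find_clashes(s).records}
        assert got == brute_force_clashes(s)

    def test_sorted_by_decreasing_overlap(self, rng):
        n = 200
        coords = rng.uniform(0, 12.0, size=(n, 3))
        atoms = [
            AtomRecord(i + 1, "C", "C", "UNK", i + 1, "A", tuple(coords[i]), False)
        for i in range(n)]
        atoms.append(AtomRecord(n + 1, "H", "H", "UNK", 1, "A",
                                tuple(coords[0] + [1.0, 0, 0]), False))
        s = infer_bonds(MolecularStructure(atoms=atoms))
        overlaps = [r.overlap for r in find_clashes(s).records]
        assert overlaps == sorted(overlaps, reverse=True)


class TestHBondExemption:
    def test_helix_backbone_hbonds_not_counted(self, helix10):
        """i -> i+4 amide H sit inside O vdW contact but are hydrogen
        bonds, so they must be exempt rather than clashing."""
        idx = helix10.serial_to_index
        coords = helix10.coords
        ri = helix10.residue_index

        def atom(res, name):
            for ser in ri[("A", res, "ALA")]:
                if helix10.atoms[idx[ser]].name == name:
                    return coords[idx[ser]]

        d = np.linalg.norm(atom(2, "O") - atom(6, "H"))
        assert d < 1.0 + 1.52  # inside polar-H + O vdW sum: would clash
        assert find_clashes(helix10).records == []


class TestMinInterresidueH:
    def test_engineered_distance(self, clash_fixture):
        d = min_interresidue_h_distance(
            clash_fixture, ("A", 104, "LEU"), ("A", 110, "VAL")
        )
        assert d == pytest.approx(1.78, abs=1e-12)

    def test_matches_exhaustive_enumeration(self, helix10):
        keys = [("A", 2, "ALA"), ("A", 9, "ALA")]
        got = min_interresidue_h_distance(helix10, *keys)
        idx = helix10.serial_to_index
        coords = helix10.coords
        ri = helix10.residue_index
        best = np.inf
        for sa in ri[keys[0]]:
            for sb in ri[keys[1]]:
                if (helix10.atoms[idx[sa]].element == "H"
                        and helix10.atoms[idx[sb]].element == "H"):
                    best = min(best, np.linalg.norm(coords[idx[sa]] - coords[idx[sb]]))
        assert got == pytest.approx(best, abs=1e-12)
        assert got > 2.0  # well separated residues

    def test_same_residue_rejected(self, clash_fixture):
        with pytest.raises(ValueError, match="distinct"):
            min_interresidue_h_distance(
                clash_fixture, ("A", 104, "LEU"), ("A", 104, "LEU")
            )

    def test_residue_without_h_rejected(self):
        s = ha.make_polyalanine(2, hydrogens=False)
        k1, k2 = list(s.residue_index)[:2]
        with pytest.raises(ValueError, match="no hydrogens"):
            min_interresidue_h_distance(s, k1, k2)
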