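"""Hydrogen stripping, template addition, and frozen-heavy-atom relaxation."""

import math

import numpy as np
import pytest

import hofaudit as ha
from hofaudit.structure import AtomRecord, MolecularStructure, infer_bonds


def water_structure(offsets):
    atoms = [
        AtomRecord(i + 1, "O", "O", "HOH", i + 1, "A", tuple(o), True)
        for i, o in enumerate(offsets)
    ]
    return infer_bonds(MolecularStructure(atoms=atoms))


def test_strip_removes_all_hydrogens(helix10):
    stripped = ha.strip_hydrogens(helix10)
    assert all(a.element != "H" for a in stripped.atoms)
    heavy = [a for a in helix10.atoms if a.element != "H"]
    assert [a.serial for a in stripped.atoms] == [a.serial for a in heavy]
    assert np.allclose(
        stripped.coords, np.array([a.coords for a in heavy])
    )


def test_strip_is_identity_without_hydrogens():
    s = ha.make_polyalanine(2, hydrogens=False)
    out = ha.strip_hydrogens(s)
    assert [a.serial for a in out.atoms] == [a.serial for a in s.atoms]


def test_strip_add_strip_idempotent(helix10):
    stripped = ha.strip_hydrogens(helix10)
    again = ha.strip_hydrogens(ha.add_hydrogens(stripped))
    assert [a.serial for a in again.atoms] == [a.serial for a in stripped.atoms]


def test_isolated_water_geometry():
    s = ha.add_hydrogens(water_structure([(0, 0, 0)]))
    hs = [np.array(a.coords) for a in s.atoms if a.element == "H"]
    assert len(hs) == 2
    d = [np.linalg.norm(h) for h in hs]
    assert d[0] == pytest.approx(0.9572, abs=1e-6)
    assert d[1] == pytest.approx(0.9572, abs=1e-6)
    angle = math.degrees(
        math.acos(np.dot(hs[0], hs[1]) / (d[0] * d[1]))
    )
    assert angle == pytest.approx(104.52, abs=1e-4)


def test_all_waters_identically_oriented():
    s = ha.add_hydrogens(water_structure([(0, 0, 0), (3.1, 0.5, -1.0)]))
    by_res = {}
    for a in s.atoms:
        by_res.setdefault(a.residue_seq, {})[a.name] = np.array(a.coords)
    off1 = [by_res[1][f"H{i}"] - by_res[1]["O"] for i in (1, 2)]
    off2 = [by_res[2][f"H{i}"] - by_res[2]["O"] for i in (1, 2)]
    assert np.allclose(off1, off2, atol=1e-12)


def test_alanine_hydrogen_counts():
    """Mid-chain alanine: N gets 1 H, CA 1, CB 3; C and O none."""
    s = ha.make_polyalanine(3)
    counts = {}
    adj = s.adjacency()
    idx = s.serial_to_index
    for a in s.atoms:
        if a.residue_seq != 2 or a.element == "H":
            continue
        n_h = sum(1 for p in adj[a.serial] if s.atoms[idx[p]].element == "H")
        counts[a.name] = n_h
    assert counts == {"N": 1, "CA": 1, "CB": 3, "C": 0, "O": 0}


def test_terminal_states():
    s = ha.make_polyalanine(3)
    adj = s.adjacency()
    idx = s.serial_to_index

    def h_on(res, name):
        (ser,) = [
            a.serial for a in s.atoms if a.residue_seq == res and a.name == name
        ]
        return sum(1 for p in adj[ser] if s.atoms[idx[p]].element == "H")

    assert h_on(1, "N") == 3  # ammonium
    assert h_on(3, "OXT") == 0  # carboxylate


def test_add_rejects_prehydrogenated(helix10):
    with pytest.raises(ValueError, match="already contains hydrogens"):
        ha.add_hydrogens(helix10)


def test_add_rejects_unknown_residue():
    atoms = [AtomRecord(1, "C1", "C", "XYZ", 1, "A", (0, 0, 0), True)]
    with pytest.raises(ha.hydrogenation.TemplateError, match="XYZ"):
        ha.add_hydrogens(MolecularStructure(atoms=atoms))


def test_h_count_reproducible(helix10):
    stripped = ha.strip_hydrogens(helix10)
    c1 = sum(a.element == "H" for a in ha.add_hydrogens(stripped).atoms)
    c2 = sum(a.element == "H" for a in ha.add_hydrogens(stripped).atoms)
    assert c1 == c2 == sum(a.element == "H" for a in helix10.atoms)


class TestHydrogenOptimization:
    def test_heavy_atoms_bit_identical(self, surrogate):
        s = ha.add_hydrogens(water_structure([(0, 0, 0), (2.8, 0, 0)]))
        opt, _ = ha.optimize_hydrogen_positions(s, surrogate)
        for a, b in zip(s.atoms, opt.atoms):
            if a.element != "H":
                assert a.coords == b.coords  # bit-identical, not approx

    def test_energy_trace_non_increasing(self, surrogate):
        s = ha.add_hydrogens(water_structure([(0, 0, 0), (2.8, 0, 0)]))
        _, trace = ha.optimize_hydrogen_positions(s, surrogate)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_adjacent_identical_waters_relax(self, surrogate):
        """Identically oriented neighboring waters are not a minimum:
        a brute-force rotation grid finds a lower-energy arrangement,
        and the optimizer must find one too."""
        s = ha.add_hydrogens(water_structure([(0, 0, 0), (2.8, 0, 0)]))
        e0 = surrogate.evaluate(s)

        # oracle: rigidly rotate water 2's hydrogens about its O
        coords = s.coords
        idx = s.serial_to_index
        o2 = next(a for a in s.atoms if a.residue_seq == 2 and a.element == "O")
        h2 = [a for a in s.atoms if a.residue_seq == 2 and a.element == "H"]
        best = e0
        for ax in (0, 1, 2):
            for ang in np.linspace(0, 2 * np.pi, 24, endpoint=False):
                c = coords.copy()
                rot = np.eye(3)
                i1, i2 = (ax + 1) % 3, (ax + 2) % 3
                rot[i1, i1] = rot[i2, i2] = np.cos(ang)
                rot[i1, i2], rot[i2, i1] = -np.sin(ang), np.sin(ang)
                for h in h2:
                    r = c[idx[h.serial]] - c[idx[o2.serial]]
                    c[idx[h.serial]] = c[idx[o2.serial]] + rot @ r
                best = min(best, surrogate.evaluate(s.with_coords(c)))
        assert best < e0  # a strictly better arrangement exists

        opt, trace = ha.optimize_hydrogen_positions(s, surrogate)
        assert trace[-1] < e0

    def test_fixed_point_stays(self, surrogate):
        s = ha.add_hydrogens(water_structure([(0, 0, 0), (2.8, 0, 0)]))
        opt, _ = ha.optimize_hydrogen_positions(s, surrogate, gtol=1e-6,
                                                maxiter=5000)
        again, _ = ha.optimize_hydrogen_positions(opt, surrogate, gtol=1e-6)
        disp = np.abs(again.coords - opt.coords).max()
        assert disp < 0.05

    def test_requires_hydrogens(self, surrogate):
        s = ha.make_polyalanine(1, hydrogens=False)
        with pytest.raises(ValueError, match="no hydrogens"):
            ha.optimize_hydrogen_positions(s, surrogate)
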