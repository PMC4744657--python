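"""Synthetic generators: peptides, perturbations, trajectories, records."""

import math

import numpy as np
import pytest

import hofaudit as ha
from hofaudit.partition import PartitionConstants, partition, total_epsilon


class TestPolyalanine:
    def test_single_residue_hydrogen_count(self):
        s = ha.make_polyalanine(1)
        # ammonium N: 3, CA: 1, CB: 3 -> 7 (carboxylate O/OXT bare)
        assert sum(a.element == "H" for a in s.atoms) == 7

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ha.make_polyalanine(0)
        with pytest.raises(ValueError):
            ha.make_polyalanine(3, "sheet")

    def test_helix_backbone_hbond_geometry(self, helix10):
        """i -> i+4 carbonyl O to amide H under 2.3 Å, every turn."""
        idx = helix10.serial_to_index
        coords = helix10.coords
        ri = helix10.residue_index

        def atom(res, name):
            for ser in ri[("A", res, "ALA")]:
                if helix10.atoms[idx[ser]].name == name:
                    return coords[idx[ser]]

        for i in range(1, 6):
            d = np.linalg.norm(atom(i, "O") - atom(i + 4, "H"))
            assert d < 2.3

    def test_ideal_geometry_is_clash_free(self, helix10, extended10):
        assert ha.find_clashes(helix10).records == []
        assert ha.find_clashes(extended10).records == []

    def test_two_chain_complex_contact(self):
        c = ha.make_two_chain_complex(3, contact=2.6)
        half = len(c.atoms) // 2
        d = np.linalg.norm(
            c.coords[:half, None, :] - c.coords[None, half:, :], axis=2
        )
        assert d.min() == pytest.approx(2.6, abs=1e-6)
        # no covalent link across chains
        serials_a = {a.serial for a in c.atoms[:half]}
        assert not any(
            (x in serials_a) != (y in serials_a) for x, y in c.bonds
        )


class TestPerturb:
    def test_identity(self, helix10):
        out = ha.perturb(helix10, ha.PerturbationSpec(seed=5))
        assert np.array_equal(out.coords, helix10.coords)

    def test_seeded_jitter_statistics(self):
        """Signed along-bond displacements over ~1000 bonds: mean near 0,
        spread near sigma; different seeds give different coordinates."""
        s = ha.make_polyalanine(100, "extended")
        sigma = 0.01
        outs = [
            ha.perturb(s, ha.PerturbationSpec(bond_jitter_sigma=sigma, seed=k))
            for k in (1, 2)
        ]
        assert not np.array_equal(outs[0].coords, outs[1].coords)
        adj = s.adjacency()
        idx = s.serial_to_index
        disp = []
        for a in s.atoms:
            partners = sorted(adj[a.serial])
            if not partners:
                continue
            u = s.coords[idx[partners[0]]] - s.coords[idx[a.serial]]
            u /= np.linalg.norm(u)
            disp.append(
                float(np.dot(outs[0].coords[idx[a.serial]] - s.coords[idx[a.serial]], u))
            )
        disp = np.asarray(disp)
        assert len(disp) > 1000
        assert abs(disp.mean()) < 3 * sigma / math.sqrt(len(disp))
        assert disp.std() == pytest.approx(sigma, rel=0.15)

    def test_half_shift_rmsd_closed_form(self):
        """Rigidly shifting exactly half the atoms by d gives RMSD d/sqrt(2)."""
        c = ha.make_two_chain_complex(3)
        chain_b = {k for k in c.residue_index if k[0] == "B"}
        out = ha.perturb(
            c,
            ha.PerturbationSpec(shift_vector=(0.0, 0.0, 0.5),
                                shift_residues=chain_b),
        )
        assert ha.rmsd(out, c) == pytest.approx(0.5 / math.sqrt(2), abs=1e-12)


@pytest.fixture(scope="module")
def relaxed_complex(surrogate):
    base, _ = surrogate.optimize(
        ha.make_two_chain_complex(3), gtol=1e-3, maxiter=5000
    )
    return base


class TestRelaxationTrajectory:
    def test_single_unrestrained_weight_recovers_everything(
        self, surrogate, relaxed_complex
    ):
        pert = ha.perturb(
            relaxed_complex,
            ha.PerturbationSpec(bond_jitter_sigma=0.02, seed=0),
        )
        traj = ha.relaxation_trajectory(pert, relaxed_complex, surrogate, [0.0])
        assert len(traj) == 1
        assert traj[0][1] == pytest.approx(1.0, abs=1e-9)

    def test_unperturbed_input_guarded(self, surrogate, relaxed_complex):
        traj = ha.relaxation_trajectory(
            relaxed_complex, relaxed_complex, surrogate, [10.0, 0.0]
        )
        for r, frac in traj:
            assert r < 0.05
        # near-zero total drop must not blow up the fraction
        assert all(np.isfinite(f) for _, f in traj)

    def test_fractions_non_decreasing(self, surrogate, relaxed_complex):
        pert = ha.perturb(
            relaxed_complex,
            ha.PerturbationSpec(bond_jitter_sigma=0.03, seed=1),
        )
        traj = ha.relaxation_trajectory(
            pert, relaxed_complex, surrogate, [100.0, 10.0, 1.0, 0.0]
        )
        fracs = [f for _, f in traj]
        assert fracs == sorted(fracs)
        assert fracs[-1] == pytest.approx(1.0, abs=1e-9)

    def test_weight_validation(self, surrogate, relaxed_complex):
        with pytest.raises(ValueError, match="decreasing"):
            ha.relaxation_trajectory(
                relaxed_complex, relaxed_complex, surrogate, [1.0, 5.0, 0.0]
            )
        with pytest.raises(ValueError, match="last restraint weight"):
            ha.relaxation_trajectory(
                relaxed_complex, relaxed_complex, surrogate, [5.0, 1.0]
            )

    def test_jitter_recovers_more_than_shift_at_small_rmsd(
        self, surrogate, relaxed_complex
    ):
        """Covalent jitter energy is recovered within ~0.02 Å motions;
        rigid-chain displacement energy is not (two seeds here; the full
        10-seed sweep runs in the acceptance suite)."""
        chain_b = {k for k in relaxed_complex.residue_index if k[0] == "B"}
        n_shift = sum(
            1 for a in relaxed_complex.atoms if a.residue_key in chain_b
        )
        frac_atoms = n_shift / len(relaxed_complex.atoms)
        weights = [100.0, 10.0, 1.0, 0.1, 0.0]
        for seed in (0, 1):
            jit = ha.perturb(
                relaxed_complex,
                ha.PerturbationSpec(bond_jitter_sigma=0.02,
                                    shift_vector=(0.0, 0.0, 1.0),
                                    shift_residues=chain_b, seed=seed),
            )
            mag = ha.rmsd(jit, relaxed_complex) / math.sqrt(frac_atoms)
            shift = ha.perturb(
                relaxed_complex,
                ha.PerturbationSpec(shift_vector=(0.0, 0.0, mag),
                                    shift_residues=chain_b, seed=seed),
            )
            t_jit = ha.relaxation_trajectory(
                jit, relaxed_complex, surrogate, weights
            )
            t_shift = ha.relaxation_trajectory(
                shift, relaxed_complex, surrogate, weights
            )

            def frac_at(traj, r_cut=0.1):
                return max([f for r, f in traj if r <= r_cut], default=0.0)

            assert frac_at(t_jit) > frac_at(t_shift)


class TestEnergyFixture:
    def test_total_epsilon_forced_by_construction(self):
        records, truth = ha.make_energy_fixture(8, 0.97, 0.12, seed=3)
        expected = math.hypot(0.97, 0.12)
        assert truth["eps_tot_true"] == expected
        for rec in records:
            assert total_epsilon(rec, "gas") == pytest.approx(expected, abs=1e-12)
            assert total_epsilon(rec, "aqueous") == pytest.approx(
                expected, abs=1e-12
            )

    def test_exact_parameter_recovery(self):
        records, truth = ha.make_energy_fixture(8, 0.97, 0.12, seed=3)
        c = PartitionConstants(0.12, 0.12)
        for rec in records:
            ep, deg = partition(total_epsilon(rec, "gas"), c, "gas")
            assert not deg
            assert ep == pytest.approx(0.97, abs=1e-12)

    def test_wrong_constant_gives_closed_form_bias(self):
        records, truth = ha.make_energy_fixture(4, 0.97, 0.12, seed=3)
        wrong = PartitionConstants(0.24, 0.24)
        expected = math.sqrt(truth["eps_tot_true"] ** 2 - 0.24**2)
        for rec in records:
            ep, _ = partition(total_epsilon(rec, "gas"), wrong, "gas")
            assert ep == pytest.approx(expected, abs=1e-12)

    def test_deterministic_for_seed(self):
        r1, _ = ha.make_energy_fixture(5, seed=9)
        r2, _ = ha.make_energy_fixture(5, seed=9)
        assert r1 == r2
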