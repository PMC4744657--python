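"""Synthetic structure and energy-record generators.

Everything the pipeline consumes can be generated here at desk scale:

* ideal-geometry polyalanine chains (helical or extended) built from
  standard internal coordinates,
* controlled perturbations that separate covalent bond-length jitter
  from rigid tertiary displacement,
* an engineered nonbonded H-H close-contact fixture (two hydrophobic
  methyl groups facing each other, with a nearby attractive pair
  pulling the fragments together — the constellation under which
  anomalously short contacts appear),
* Lennard-Jones probe dimers for calibration and scan oracles,
* heat-of-formation record tables with known error partitions for
  parameter-recovery tests.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import (
    GAS,
    EnergyBackend,
    Phase,
    PhaseEnergyRecord,
)
from .hydrogenation import add_hydrogens, load_default_templates
from .structure import AtomRecord, MolecularStructure, infer_bonds

__all__ = [
    "PerturbationSpec",
    "make_polyalanine",
    "make_two_chain_complex",
    "make_probe_pair",
    "make_clash_fixture",
    "perturb",
    "rmsd",
    "relaxation_trajectory",
    "make_energy_fixture",
]

# ideal backbone internal coordinates (Engh-Huber-style values)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.521
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_A_C_CA_CB = 110.1
_OMEGA = 180.0

CONFORMATIONS = {
    "helix": (-57.0, -47.0),
    "extended": (-139.0, 135.0),
}


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d given a-b-c, d-c bond, d-c-b angle and
    a-b-c-d torsion."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_polyalanine(
    n_res: int, conformation: str = "helix", hydrogens: bool = True
) -> MolecularStructure:
    """Ideal-geometry polyalanine chain.

    ``conformation`` is ``helix`` (phi=-57, psi=-47) or ``extended``
    (beta-strand phi=-139, psi=135).  The chain carries charged termini
    (ammonium N, carboxylate with OXT) and, by default, the full
    template hydrogen complement.
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    if conformation not in CONFORMATIONS:
        raise ValueError(f"conformation must be one of {sorted(CONFORMATIONS)}")
    phi, psi = CONFORMATIONS[conformation]

    backbone: list[dict] = []  # per residue: {'N':..., 'CA':..., 'C':...}
    # seed residue in the xy-plane
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    backbone.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = backbone[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca = _place(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
        c = _place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        backbone.append({"N": n, "CA": ca, "C": c})

    atoms: list[AtomRecord] = []
    serial = 1

    def emit(name: str, element: str, xyz: np.ndarray, res_seq: int):
        nonlocal serial
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                residue_name="ALA",
                residue_seq=res_seq,
                chain_id="A",
                coords=tuple(float(v) for v in xyz),
                is_hetero=False,
            )
        )
        serial += 1

    for i, bb in enumerate(backbone):
        res_seq = i + 1
        emit("N", "N", bb["N"], res_seq)
        emit("CA", "C", bb["CA"], res_seq)
        emit("C", "C", bb["C"], res_seq)
        # carbonyl O: anti to the next amide nitrogen (torsion psi+180)
        o = _place(bb["N"], bb["CA"], bb["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        emit("O", "O", o, res_seq)
        # CB off the L-alpha carbon
        # L-configuration: improper C-N-CA-CB dihedral of -122.6 deg
        cb = _place(bb["C"], bb["N"], bb["CA"], _B_CA_CB, _A_C_CA_CB, -122.6)
        emit("CB", "C", cb, res_seq)
        if i == n_res - 1:
            oxt = _place(bb["N"], bb["CA"], bb["C"], _B_C_O, _A_CA_C_O, psi)
            emit("OXT", "O", oxt, res_seq)

    s = infer_bonds(MolecularStructure(atoms=atoms))
    if hydrogens:
        s = add_hydrogens(s, load_default_templates())
    return s


def make_two_chain_complex(
    n_res: int = 3,
    conformation: str = "extended",
    contact: float = 2.6,
) -> MolecularStructure:
    """Two identical peptide chains in nonbonded contact.

    Chain B is a rigid copy of chain A offset along +z (perpendicular
    to the plane the chain is built in) by whatever distance puts the
    closest interchain atom pair at ``contact`` Å — near vdW contact,
    close enough for dispersion-like coupling but with no covalent
    link.  This is the minimal system in which rigid tertiary
    displacement (moving chain B) is energetically cheap while covalent
    jitter is expensive.
    """
    a = make_polyalanine(n_res, conformation)
    coords = a.coords

    def min_interchain(z: float) -> float:
        d = coords[:, None, :] - (coords[None, :, :] + np.array([0.0, 0.0, z]))
        return float(np.sqrt((d**2).sum(axis=2)).min())

    lo, hi = 0.0, 50.0
    for _ in range(60):  # min_interchain is monotone for z past the extent
        mid = 0.5 * (lo + hi)
        if min_interchain(mid) < contact:
            lo = mid
        else:
            hi = mid
    offset = np.array([0.0, 0.0, hi])
    serial0 = max(at.serial for at in a.atoms)
    b_atoms = [
        AtomRecord(
            serial=at.serial + serial0,
            name=at.name,
            element=at.element,
            residue_name=at.residue_name,
            residue_seq=at.residue_seq,
            chain_id="B",
            coords=tuple(np.array(at.coords) + offset),
            is_hetero=at.is_hetero,
        )
        for at in a.atoms
    ]
    bonds = set(a.bonds) | {(i + serial0, j + serial0) for i, j in a.bonds}
    return MolecularStructure(atoms=list(a.atoms) + b_atoms, bonds=bonds)


def make_probe_pair(
    separation: float, element: str = "C", residue_name: str = "PRB"
) -> MolecularStructure:
    """Two unbonded probe atoms on the x-axis (12-6 oracle fixture)."""
    atoms = [
        AtomRecord(1, element, element, residue_name, 1, "A", (0.0, 0.0, 0.0), True),
        AtomRecord(
            2, element, element, residue_name, 2, "A", (separation, 0.0, 0.0), True
        ),
    ]
    return MolecularStructure(atoms=atoms, bonds=set())


def _methyl(
    center: np.ndarray, toward: np.ndarray, residue: tuple[str, int], start_serial: int
) -> list[AtomRecord]:
    """A methane-like CH4 probe with one C-H bond pointing along
    ``toward``."""
    res_name, res_seq = residue
    u = toward / np.linalg.norm(toward)
    # build three remaining H tetrahedral to the first
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    w = np.cross(u, ref)
    w /= np.linalg.norm(w)
    tet = math.radians(109.47)
    dirs = [u]
    base = u * math.cos(tet) + w * math.sin(tet)
    for k in range(3):
        ang = 2 * math.pi * k / 3
        rot = (
            base * math.cos(ang)
            + np.cross(u, base) * math.sin(ang)
            + u * np.dot(u, base) * (1 - math.cos(ang))
        )
        dirs.append(rot / np.linalg.norm(rot))
    atoms = [
        AtomRecord(
            start_serial, "CD1" if res_name == "LEU" else "CG1", "C",
            res_name, res_seq, "A", tuple(center), False,
        )
    ]
    stem = "HD1" if res_name == "LEU" else "HG1"
    for k, d in enumerate(dirs):
        atoms.append(
            AtomRecord(
                start_serial + 1 + k, f"{stem}{k + 1}", "H",
                res_name, res_seq, "A", tuple(center + 1.09 * d), False,
            )
        )
    return atoms


def make_clash_fixture(h_h_distance: float = 1.78) -> MolecularStructure:
    """Engineered nonbonded H-H close contact between hydrophobic groups.

    Synthetic stand-in for a leucine/valine side-chain pair: two
    methane-like hydrophobic probes face each other with their closest
    hydrogens at
    ``h_h_distance`` (default 1.78 Å, well inside twice the hydrogen vdW
    radius), plus a pair of bare oxygens at attractive range that mimics
    the nearby pulling interaction required for such contacts to form.
    """
    x_gap = h_h_distance + 2 * 1.09  # C...C distance along the contact axis
    atoms: list[AtomRecord] = []
    atoms += _methyl(np.zeros(3), np.array([1.0, 0.0, 0.0]), ("LEU", 104), 1)
    atoms += _methyl(
        np.array([x_gap, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0]), ("VAL", 110), 6
    )
    # attractive pair: two oxygens near vdW contact, one per residue
    atoms.append(
        AtomRecord(11, "O1", "O", "LEU", 104, "A", (0.0, 4.0, 0.0), False)
    )
    atoms.append(
        AtomRecord(12, "O2", "O", "VAL", 110, "A", (3.1, 4.0, 0.0), False)
    )
    return infer_bonds(MolecularStructure(atoms=atoms))


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


@dataclass
class PerturbationSpec:
    """Covalent jitter plus rigid tertiary displacement.

    ``bond_jitter_sigma``: every bonded atom is displaced along the
    direction of one of its bonds by a N(0, sigma^2) draw.
    ``shift_vector``: rigid translation (its norm is the shift
    magnitude) applied to atoms of ``shift_residues`` (residue keys;
    empty set means no rigid part).
    """

    bond_jitter_sigma: float = 0.0
    shift_vector: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shift_residues: set = field(default_factory=set)
    seed: int = 0

    def __post_init__(self):
        if self.bond_jitter_sigma < 0:
            raise ValueError("bond_jitter_sigma must be >= 0")


def perturb(s: MolecularStructure, spec: PerturbationSpec) -> MolecularStructure:
    """Apply a :class:`PerturbationSpec`; deterministic for fixed seed."""
    rng = np.random.default_rng(spec.seed)
    coords = s.coords
    adj = s.adjacency()
    idx = s.serial_to_index
    if spec.bond_jitter_sigma > 0:
        for a in s.atoms:
            partners = sorted(adj[a.serial])
            if not partners:
                continue
            i = idx[a.serial]
            j = idx[partners[0]]
            u = coords[j] - coords[i]
            nrm = np.linalg.norm(u)
            if nrm < 1e-9:
                continue
            coords[i] += (rng.normal(0.0, spec.bond_jitter_sigma) / nrm) * u
    shift = np.asarray(spec.shift_vector, dtype=float)
    if np.linalg.norm(shift) > 0 and spec.shift_residues:
        rows = [idx[a.serial] for a in s.atoms if a.residue_key in spec.shift_residues]
        coords[rows] += shift
    return s.with_coords(coords)


def rmsd(a: MolecularStructure | np.ndarray, b: MolecularStructure | np.ndarray,
         heavy_only: bool = False, elements: list[str] | None = None) -> float:
    """Plain coordinate RMSD (no superposition — displacement is the
    quantity of interest here)."""
    ca = a.coords if isinstance(a, MolecularStructure) else np.asarray(a)
    cb = b.coords if isinstance(b, MolecularStructure) else np.asarray(b)
    if ca.shape != cb.shape:
        raise ValueError("structures are not atom-matched")
    if heavy_only:
        if elements is None:
            if not isinstance(a, MolecularStructure):
                raise ValueError("heavy_only needs element information")
            elements = a.elements
        mask = np.array([e != "H" for e in elements])
        ca, cb = ca[mask], cb[mask]
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# restrained relaxation trajectory
# ---------------------------------------------------------------------------


def relaxation_trajectory(
    s_perturbed: MolecularStructure,
    s_reference: MolecularStructure,
    backend: EnergyBackend,
    restraint_weights: list[float],
    phase: Phase = GAS,
    maxiter: int = 2000,
) -> list[tuple[float, float]]:
    """Energy recovery as a function of allowed displacement.

    At each restraint weight ``w`` (kcal/mol/Å², strictly decreasing,
    last entry 0) the objective ``E_backend + w * sum |x - x_start|^2``
    is minimized, warm-starting from the previous solution.  Returns a
    list of ``(rmsd_from_start, fraction_of_total_energy_drop)`` where
    the total drop is the backend-energy decrease of the final,
    unrestrained optimization.  Fractions are non-decreasing.
    """
    from scipy.optimize import minimize

    if len(s_perturbed.atoms) != len(s_reference.atoms):
        raise ValueError("structures are not atom-matched")
    weights = list(restraint_weights)
    if weights != sorted(weights, reverse=True):
        raise ValueError("restraint weights must be strictly decreasing")
    if weights[-1] != 0:
        raise ValueError("last restraint weight must be 0 (unrestrained)")

    x_start = s_perturbed.coords
    energy_grad = backend.coordinate_function(s_perturbed, phase)
    e_start = energy_grad(x_start)[0]

    raw: list[tuple[float, float]] = []  # (rmsd, backend energy)
    x_cur = x_start.copy()
    for w in weights:
        def objective(xflat: np.ndarray):
            coords = xflat.reshape(-1, 3)
            e, g = energy_grad(coords)
            dr = coords - x_start
            return (
                e + w * float(np.sum(dr**2)),
                (g + 2.0 * w * dr).ravel(),
            )

        res = minimize(
            objective,
            x_cur.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": 1e-4, "ftol": 1e-12},
        )
        x_cur = res.x.reshape(-1, 3)
        e_backend = energy_grad(x_cur)[0]
        raw.append((rmsd(x_cur, x_start), e_backend))

    total_drop = e_start - raw[-1][1]
    out: list[tuple[float, float]] = []
    best = 0.0
    for r, e in raw:
        frac = 0.0 if total_drop <= 1e-12 else (e_start - e) / total_drop
        best = max(best, frac)  # fractions are cumulative recoveries
        out.append((r, best))
    return out


# ---------------------------------------------------------------------------
# energy-record fixtures with known partitions
# ---------------------------------------------------------------------------


def make_energy_fixture(
    n_structures: int,
    eps_pdb_true: float = 0.97,
    eps_method_true: float = 0.12,
    seed: int = 0,
) -> tuple[list[PhaseEnergyRecord], dict]:
    """Heat-of-formation records with an exactly known error partition.

    Every record is constructed so that its total per-atom drop equals
    ``sqrt(eps_pdb_true^2 + eps_method_true^2)`` in both phases; atom
    counts and baseline energies are randomized.  The returned truth
    dict allows exact recovery testing.
    """
    if eps_pdb_true < 0 or eps_method_true < 0:
        raise ValueError("true epsilon components must be >= 0")
    rng = np.random.default_rng(seed)
    eps_tot = math.hypot(eps_pdb_true, eps_method_true)
    records = []
    for k in range(n_structures):
        n = int(rng.integers(200, 6000))
        base_gas = float(rng.uniform(-60000.0, -1000.0))
        base_aq = base_gas - float(rng.uniform(100.0, 3000.0))
        records.append(
            PhaseEnergyRecord(
                structure_id=f"SYN{k:03d}",
                n=n,
                hof_pdb_gas=base_gas,
                hof_pdb_aq=base_aq,
                hof_opt_gas=base_gas - eps_tot * n,
                hof_opt_aq=base_aq - eps_tot * n,
            )
        )
    truth = {
        "eps_pdb_true": eps_pdb_true,
        "eps_method_true": eps_method_true,
        "eps_tot_true": eps_tot,
        "seed": seed,
    }
    return records, truth
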