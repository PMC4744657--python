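"""Hydrogen stripping, template-based re-addition, and H-only optimization.

Deposited high-resolution structures rarely resolve hydrogens, so the
audit protocol strips whatever hydrogens are present, re-adds a full
pH-7 complement from residue templates, and then relaxes only the added
hydrogens with every heavy atom frozen.

Placement follows the parent atom's hybridization and its existing
bonded neighbors.  Entrained waters, deposited as lone oxygen atoms,
deliberately all receive their two protons in one identical absolute
orientation — an artifact of utility-style hydrogenation that the
subsequent frozen-heavy-atom optimization must then resolve.

The geometric rules here are a documented reimplementation of
utility-style hydrogen addition, not a bit-match of any particular
program.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .energy import GAS, EnergyBackend, Phase
from .structure import (
    DEFAULT_BOND_TOLERANCE,
    AtomRecord,
    MolecularStructure,
    WATER_RESIDUE_NAMES,
    infer_bonds,
)

__all__ = [
    "ProtonationTemplates",
    "TemplateError",
    "load_default_templates",
    "strip_hydrogens",
    "add_hydrogens",
    "optimize_hydrogen_positions",
]

TET = math.radians(109.47)  # ideal tetrahedral angle
WATER_OH = 0.9572  # Å
WATER_HOH = math.radians(104.52)

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class TemplateError(ValueError):
    """A residue or atom has no protonation template."""


@dataclass
class ProtonationTemplates:
    """Per-residue hydrogen counts and placement tags.

    ``residues[res][atom] = (h_count, hybridization)``;
    ``bond_lengths[element]`` is the ideal X-H distance in Å.
    """

    residues: dict[str, dict[str, tuple[int, str]]] = field(default_factory=dict)
    bond_lengths: dict[str, float] = field(default_factory=dict)

    def lookup(self, residue_name: str, atom_name: str) -> tuple[int, str]:
        res = self.residues.get(residue_name)
        if res is None:
            raise TemplateError(f"no protonation template for residue {residue_name!r}")
        if atom_name in res:
            return res[atom_name]
        raise TemplateError(
            f"no template entry for atom {atom_name!r} of residue {residue_name!r}"
        )

    def bond_length(self, element: str) -> float:
        try:
            return self.bond_lengths[element]
        except KeyError:
            raise TemplateError(f"no X-H bond length for element {element!r}") from None

    @classmethod
    def from_file(cls, path: str | Path) -> "ProtonationTemplates":
        t = cls()
        backbone: dict[str, tuple[int, str]] = {}
        body: dict[str, dict[str, tuple[int, str]]] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if tok[0] == "bondlength":
                t.bond_lengths[tok[1].upper()] = float(tok[2])
                continue
            res, atom, count, hyb = tok[0], tok[1], int(tok[2]), tok[3]
            if res == "BACKBONE":
                backbone[atom] = (count, hyb)
            else:
                body.setdefault(res, {})[atom] = (count, hyb)
        for res, entries in body.items():
            if res in WATER_RESIDUE_NAMES:
                t.residues[res] = dict(entries)
            else:
                merged = dict(backbone)
                merged.update(entries)
                t.residues[res] = merged
        return t


def load_default_templates() -> ProtonationTemplates:
    with resources.as_file(
        resources.files("hofaudit.data") / "residue_templates.txt"
    ) as p:
        return ProtonationTemplates.from_file(p)


# ---------------------------------------------------------------------------
# strip / add
# ---------------------------------------------------------------------------


def strip_hydrogens(
    s: MolecularStructure, tolerance: float = DEFAULT_BOND_TOLERANCE
) -> MolecularStructure:
    """Remove all hydrogen atoms; heavy atoms untouched, bonds re-inferred."""
    heavy = [a for a in s.atoms if a.element != "H"]
    if len(heavy) == len(s.atoms):
        return MolecularStructure(atoms=list(s.atoms), bonds=set(s.bonds))
    return infer_bonds(MolecularStructure(atoms=heavy), tolerance)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("zero-length vector")
    return v / n


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, trial))


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * np.dot(axis, v) * (1.0 - math.cos(angle))
    )


_WATER_DIRS = (
    np.array([math.sin(WATER_HOH / 2), 0.0, math.cos(WATER_HOH / 2)]),
    np.array([-math.sin(WATER_HOH / 2), 0.0, math.cos(WATER_HOH / 2)]),
)


def _h_directions(
    hyb: str,
    n_h: int,
    nb_units: list[np.ndarray],
    ref_unit: np.ndarray | None,
    parent_serial: int,
) -> list[np.ndarray]:
    """Unit vectors (from the parent atom) for the new hydrogens."""
    if hyb == "water":
        return [d.copy() for d in _WATER_DIRS[:n_h]]
    k = len(nb_units)
    if k == 0:
        # isolated heavy atom: deterministic tetrahedral fan
        dirs = [np.array([0.0, 0.0, 1.0])]
        base = _rotate(dirs[0], np.array([1.0, 0.0, 0.0]), TET)
        for i in range(3):
            dirs.append(_rotate(base, dirs[0], i * 2 * math.pi / 3))
        return dirs[:n_h]

    vsum = np.sum(nb_units, axis=0)
    if k >= 2 and np.linalg.norm(vsum) < 1e-6:
        warnings.warn(
            f"degenerate (collinear) neighbor geometry at atom serial "
            f"{parent_serial}; using fallback direction"
        )
        w = _any_perpendicular(nb_units[0])
        return [w] if n_h == 1 else [w, -w][:n_h]

    if k == 3:
        return [-_unit(vsum)]  # single H completes the tetrahedron
    if k == 2:
        b = -_unit(vsum)
        if n_h == 1:
            return [b]
        w = _unit(np.cross(nb_units[0], nb_units[1]))
        half = TET / 2 if hyb == "sp3" else math.radians(60.0)
        return [
            _unit(b * math.cos(half) + w * math.sin(half)),
            _unit(b * math.cos(half) - w * math.sin(half)),
        ][:n_h]
    # k == 1: build around the single bond, torsion fixed by ref_unit
    u = nb_units[0]
    w = None
    if ref_unit is not None:
        perp = ref_unit - np.dot(ref_unit, u) * u
        if np.linalg.norm(perp) > 1e-6:
            w = _unit(perp)
    if w is None:
        w = _any_perpendicular(u)
    angle = TET if hyb == "sp3" else math.radians(120.0)
    # first H anti-periplanar to the reference atom
    first = _unit(u * math.cos(angle) - w * math.sin(angle))
    dirs = [first]
    for i in range(1, n_h):
        dirs.append(_unit(_rotate(first, u, i * 2 * math.pi / max(n_h, 2))))
    if hyb == "sp2" and n_h == 2:
        # amide-style NH2: both H in the reference plane
        second = _unit(u * math.cos(angle) + w * math.sin(angle))
        dirs = [first, second]
    return dirs[:n_h]


def _h_names(parent: AtomRecord, n_h: int, terminal: bool) -> list[str]:
    if parent.residue_name in WATER_RESIDUE_NAMES:
        return [f"H{i + 1}" for i in range(n_h)]
    if terminal or len(parent.name) <= 1:
        base = "H"
        return [base] if n_h == 1 else [f"{base}{i + 1}" for i in range(n_h)]
    stem = "H" + parent.name[1:]
    return [stem] if n_h == 1 else [f"{stem}{i + 1}" for i in range(n_h)]


def add_hydrogens(
    s: MolecularStructure,
    templates: ProtonationTemplates | None = None,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
) -> MolecularStructure:
    """Add a full pH-7 hydrogen complement to a heavy-atom structure.

    Preconditions: the input carries no hydrogens (run
    :func:`strip_hydrogens` first) and has bonds inferred.  Chain
    termini are detected from connectivity: an amine nitrogen bonded
    only to CA becomes an ammonium (3 H, 2 for proline).  All waters
    receive their two protons in the same absolute orientation.
    """
    if any(a.element == "H" for a in s.atoms):
        raise ValueError("input already contains hydrogens; strip them first")
    templates = templates or load_default_templates()
    if not s.bonds and len(s.atoms) > 1:
        s = infer_bonds(s, tolerance)

    adj = s.adjacency()
    by_serial = {a.serial: a for a in s.atoms}
    pos = {a.serial: np.array(a.coords) for a in s.atoms}
    next_serial = max((a.serial for a in s.atoms), default=0) + 1

    new_atoms: list[AtomRecord] = []
    new_bonds = set(s.bonds)
    missing: set[str] = set()

    for parent in s.atoms:
        is_water = parent.residue_name in WATER_RESIDUE_NAMES
        try:
            if is_water:
                n_h, hyb = templates.lookup(parent.residue_name, "O")
            else:
                n_h, hyb = templates.lookup(parent.residue_name, parent.name)
        except TemplateError:
            missing.add(parent.residue_name)
            new_atoms.append(parent)
            continue

        terminal = False
        if not is_water:
            heavy_nb = [by_serial[x] for x in sorted(adj[parent.serial])]
            # terminal ammonium: backbone N bonded only to its own CA
            if parent.name == "N" and parent.element == "N":
                if all(nb.name == "CA" for nb in heavy_nb):
                    terminal = True
                    n_h = 2 if parent.residue_name == "PRO" else 3
                    hyb = "sp3"
        else:
            heavy_nb = []

        new_atoms.append(parent)
        if n_h == 0:
            continue

        nb_units = []
        p0 = pos[parent.serial]
        for nb in heavy_nb:
            try:
                nb_units.append(_unit(pos[nb.serial] - p0))
            except ValueError:
                continue
        ref_unit = None
        if len(heavy_nb) == 1:
            # reference for the torsion: a second-shell heavy atom
            second = [
                x for x in sorted(adj[heavy_nb[0].serial]) if x != parent.serial
            ]
            if second:
                ref_unit = _unit(pos[second[0]] - pos[heavy_nb[0].serial])

        try:
            dirs = _h_directions(hyb, n_h, nb_units, ref_unit, parent.serial)
        except ValueError:
            warnings.warn(
                f"could not place hydrogens on atom serial {parent.serial}; skipped"
            )
            continue
        blen = WATER_OH if hyb == "water" else templates.bond_length(parent.element)
        for name, d in zip(_h_names(parent, n_h, terminal), dirs):
            h = AtomRecord(
                serial=next_serial,
                name=name,
                element="H",
                residue_name=parent.residue_name,
                residue_seq=parent.residue_seq,
                chain_id=parent.chain_id,
                coords=tuple(p0 + blen * d),
                is_hetero=parent.is_hetero,
            )
            new_atoms.append(h)
            new_bonds.add((min(parent.serial, next_serial), max(parent.serial, next_serial)))
            next_serial += 1

    if missing:
        raise TemplateError(
            "no protonation template for residue(s): " + ", ".join(sorted(missing))
        )
    return MolecularStructure(atoms=new_atoms, bonds=new_bonds)


# ---------------------------------------------------------------------------
# H-only optimization
# ---------------------------------------------------------------------------


def optimize_hydrogen_positions(
    s: MolecularStructure,
    backend: EnergyBackend,
    phase: Phase = GAS,
    gtol: float = 0.1,
    maxiter: int = 2000,
) -> tuple[MolecularStructure, list[float]]:
    """Relax hydrogen positions with all heavy atoms frozen.

    Returns the relaxed structure and an energy trace
    ``[E_initial, E_final]`` (non-increasing).  Heavy-atom coordinates
    are bit-identical to the input.
    """
    is_h = np.array([a.element == "H" for a in s.atoms])
    if not is_h.any():
        raise ValueError("structure has no hydrogens to optimize")
    e0 = backend.evaluate(s, phase)
    opt, e1 = backend.optimize(s, phase, frozen=~is_h, gtol=gtol, maxiter=maxiter)
    return opt, [e0, min(e1, e0)]
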