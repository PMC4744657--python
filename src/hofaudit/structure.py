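"""Protein structure container and PDB input/output.

The in-memory model is deliberately small: an ordered list of
:class:`AtomRecord` plus a covalent bond set inferred from interatomic
distances.  Entrained waters are single ``HOH`` oxygen atoms until
hydrogenation adds their protons.  Biotite performs the actual PDB text
parsing and writing; alternate locations are collapsed to the
highest-occupancy conformer on read.

Coordinates are Cartesian Å throughout.  Atom serials are the stable
identity; indexing is 0-based internally and 1-based only at the PDB
text boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .elements import (
    COVALENT_RADII,
    UnknownElementError,
    covalent_radius,
    normalize_element,
)

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "infer_bonds",
    "count_atoms",
    "infer_element_from_name",
]

WATER_RESIDUE_NAMES = {"HOH", "WAT", "DOD"}

#: default bond-inference distance slack added to the covalent-radius sum, Å
DEFAULT_BOND_TOLERANCE = 0.4


class PDBParseError(ValueError):
    """A PDB record could not be interpreted (bad element, empty file...)."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure.

    ``coords`` is a length-3 tuple in Å; it is kept immutable so records
    can be shared between derived structures.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: tuple[float, float, float]
    is_hetero: bool = False

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} has non-finite coordinates")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.residue_name)


@dataclass
class MolecularStructure:
    """Ordered atom list with an (optional) inferred covalent bond graph."""

    atoms: list[AtomRecord] = field(default_factory=list)
    bonds: set[tuple[int, int]] = field(default_factory=set)

    # -- derived views ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in atom order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def serial_to_index(self) -> dict[int, int]:
        return {a.serial: i for i, a in enumerate(self.atoms)}

    @property
    def residue_index(self) -> dict[tuple[str, int, str], list[int]]:
        """Map residue key ``(chain, seq, name)`` → atom serials, in order."""
        index: dict[tuple[str, int, str], list[int]] = {}
        for a in self.atoms:
            index.setdefault(a.residue_key, []).append(a.serial)
        return index

    @property
    def water_serials(self) -> set[int]:
        return {
            a.serial
            for a in self.atoms
            if a.is_hetero and a.residue_name in WATER_RESIDUE_NAMES
        }

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        """Copy of this structure with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, coords=tuple(xyz)) for a, xyz in zip(self.atoms, coords)
        ]
        return MolecularStructure(atoms=atoms, bonds=set(self.bonds))

    def bond_partners(self, serial: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == serial:
                out.append(b)
            elif b == serial:
                out.append(a)
        return sorted(out)

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {a.serial: set() for a in self.atoms}
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        return adj


def infer_element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name when columns 77-78 are blank.

    Follows the usual convention: leading digits are part of the name,
    not the element (``1HB`` → H); a leading letter in {H,C,N,O,S,P} is
    the element for protein atoms (``CA`` → C); otherwise a two-letter
    symbol is attempted (ions such as ``ZN``).
    """
    s = name.strip().lstrip("0123456789 ")
    if not s:
        raise PDBParseError(f"cannot infer element from atom name {name!r}")
    first = s[0].upper()
    if first in {"H", "C", "N", "O", "S", "P"}:
        return first
    two = s[:2].upper()
    if two in COVALENT_RADII:
        return two
    raise PDBParseError(f"cannot infer element from atom name {name!r}")


def read_pdb(path: str | Path) -> MolecularStructure:
    """Read a PDB file into a :class:`MolecularStructure`.

    Every ATOM/HETATM record of the first model becomes one
    :class:`AtomRecord`, in file order.  Alternate locations are reduced
    to the highest-occupancy conformer.  Elements come from the element
    column when present, otherwise from the atom name.  Bonds are *not*
    inferred here; call :func:`infer_bonds`.
    """
    path = Path(path)
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        arr = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["atom_id"]
        )
    except Exception as exc:  # biotite raises various error types
        raise PDBParseError(f"could not parse {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBParseError(f"{path} contains no ATOM or HETATM records")

    atoms: list[AtomRecord] = []
    for i in range(arr.array_length()):
        raw_element = str(arr.element[i]).strip()
        name = str(arr.atom_name[i])
        if raw_element:
            try:
                element = normalize_element(raw_element)
            except UnknownElementError:
                # Some depositions abuse the element column; fall back.
                element = infer_element_from_name(name)
        else:
            element = infer_element_from_name(name)
        atoms.append(
            AtomRecord(
                serial=int(arr.atom_id[i]),
                name=name,
                element=element,
                residue_name=str(arr.res_name[i]),
                residue_seq=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]) or "A",
                coords=tuple(float(x) for x in arr.coord[i]),
                is_hetero=bool(arr.hetero[i]),
            )
        )
    return MolecularStructure(atoms=atoms)


def _to_atom_array(s: MolecularStructure) -> struc.AtomArray:
    n = len(s.atoms)
    arr = struc.AtomArray(n)
    arr.add_annotation("atom_id", int)
    for i, a in enumerate(s.atoms):
        arr.coord[i] = a.coords
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.res_name[i] = a.residue_name
        arr.res_id[i] = a.residue_seq
        arr.chain_id[i] = a.chain_id
        arr.hetero[i] = a.is_hetero
        arr.atom_id[i] = a.serial
    return arr


def write_pdb(s: MolecularStructure, path: str | Path, conect: bool = False) -> None:
    """Write the structure as PDB text (ATOM/HETATM records, END).

    With ``conect=True`` the inferred bond set is emitted as CONECT
    records; bonds are never read back from CONECT.
    """
    arr = _to_atom_array(s)
    if conect and s.bonds:
        idx = s.serial_to_index
        bond_list = struc.BondList(
            len(s.atoms),
            np.array([[idx[a], idx[b]] for a, b in sorted(s.bonds)], dtype=np.uint32),
        )
        arr.bonds = bond_list
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def infer_bonds(
    s: MolecularStructure,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
    radii: dict[str, float] | None = None,
) -> MolecularStructure:
    """Infer covalent bonds from interatomic distances.

    A pair is bonded when its distance is at most the sum of the two
    covalent radii plus ``tolerance``.  A hydrogen must end with exactly
    one bond: hydrogens with zero or multiple candidate partners are
    (with a warning) assigned to their single nearest neighbor.
    """
    from scipy.spatial import cKDTree

    n = len(s.atoms)
    if n == 0:
        return MolecularStructure(atoms=[], bonds=set())
    coords = s.coords
    rcov = np.array([covalent_radius(a.element, radii) for a in s.atoms])
    serials = [a.serial for a in s.atoms]
    is_h = np.array([a.element == "H" for a in s.atoms])

    tree = cKDTree(coords)
    cutoff = 2.0 * rcov.max() + tolerance
    bonds: set[tuple[int, int]] = set()
    h_bond_count = dict.fromkeys(np.nonzero(is_h)[0], 0)
    for i, j in tree.query_pairs(cutoff):
        d = np.linalg.norm(coords[i] - coords[j])
        if d <= rcov[i] + rcov[j] + tolerance and d > 1e-6:
            if is_h[i] and is_h[j]:
                continue  # H-H covalent bonds do not occur in proteins
            bonds.add((min(serials[i], serials[j]), max(serials[i], serials[j])))
            for k in (i, j):
                if is_h[k]:
                    h_bond_count[k] += 1

    # enforce exactly one bond per hydrogen
    heavy_idx = np.nonzero(~is_h)[0]
    for hi, count in h_bond_count.items():
        if count == 1:
            continue
        warnings.warn(
            f"hydrogen serial {serials[hi]} has {count} bond candidates; "
            "assigning nearest heavy neighbor"
        )
        # drop existing H bonds, then attach to the nearest heavy atom
        bonds = {
            (a, b) for a, b in bonds if serials[hi] not in (a, b)
        }
        if heavy_idx.size:
            d = np.linalg.norm(coords[heavy_idx] - coords[hi], axis=1)
            j = int(heavy_idx[np.argmin(d)])
            bonds.add((min(serials[hi], serials[j]), max(serials[hi], serials[j])))
    return MolecularStructure(atoms=list(s.atoms), bonds=bonds)


def count_atoms(s: MolecularStructure) -> int:
    """Total atom count, hydrogens and entrained waters included."""
    return len(s.atoms)
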