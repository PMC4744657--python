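"""Steric-clash detection by van der Waals overlap.

A clash is a nonbonded atom pair whose vdW spheres interpenetrate by at
least ``overlap_cutoff`` (default 0.4 Å).  Pairs separated by up to
three covalent bonds are never eligible; pairs that satisfy a simple geometric
hydrogen-bond rule (H on an N/O/S donor, H···acceptor within 2.5 Å,
donor-H···acceptor angle ≥ 120°) are marked exempt and not counted.  The
headline statistic is the clashscore, clashes per 1000 atoms — higher
means a worse model.

This is an overlap-based reimplementation of validation-tool practice,
not a reproduction of any probe/contact-dot algorithm; hydrogen
positions are nuclear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .elements import vdw_radius
from .structure import MolecularStructure

__all__ = [
    "DEFAULT_OVERLAP_CUTOFF",
    "ClashRecord",
    "ClashReport",
    "find_clashes",
    "min_interresidue_h_distance",
]

DEFAULT_OVERLAP_CUTOFF = 0.4  # Å
HBOND_MAX_DIST = 2.5  # Å, H···acceptor
HBOND_MIN_ANGLE = 120.0  # degrees, donor-H···acceptor
#: vdW radius for hydrogens bonded to N/O/S; polar hydrogens sit deep in
#: their heavy atom's electron cloud, and validation tools shrink them
POLAR_H_RADIUS = 1.0
_DONOR_ELEMENTS = {"N", "O", "S"}
_ACCEPTOR_ELEMENTS = {"N", "O", "S"}


@dataclass(frozen=True)
class ClashRecord:
    """One overlapping nonbonded contact."""

    serial_a: int
    serial_b: int
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    distance: float
    overlap: float
    hbond_exempt: bool = False


@dataclass(frozen=True)
class ClashReport:
    records: list[ClashRecord]
    n_atoms: int

    @property
    def clashscore(self) -> float:
        """Clashes per 1000 atoms."""
        if self.n_atoms == 0:
            return 0.0
        return 1000.0 * len(self.records) / self.n_atoms

    def to_rows(self) -> list[dict]:
        return [
            {
                "serial_a": r.serial_a,
                "serial_b": r.serial_b,
                "residue_a": f"{r.residue_a[0]}/{r.residue_a[2]}{r.residue_a[1]}",
                "residue_b": f"{r.residue_b[0]}/{r.residue_b[2]}{r.residue_b[1]}",
                "distance": round(r.distance, 3),
                "overlap": round(r.overlap, 3),
            }
            for r in self.records
        ]


def _topo_excluded_pairs(
    s: MolecularStructure, max_separation: int
) -> set[tuple[int, int]]:
    """Serial pairs within ``max_separation`` bonds (excluded from
    clashing), found by depth-limited BFS from every atom."""
    adj = s.adjacency()
    excluded: set[tuple[int, int]] = set()
    for start in adj:
        frontier = {start}
        seen = {start}
        for _ in range(max_separation):
            frontier = {
                nb for cur in frontier for nb in adj[cur] if nb not in seen
            }
            seen |= frontier
            for other in frontier:
                if other > start:
                    excluded.add((start, other))
    return excluded


def _is_hbond(
    s_idx: dict[int, int],
    coords: np.ndarray,
    elements: list[str],
    adj: dict[int, set[int]],
    serial_h: int,
    serial_acc: int,
    max_dist: float,
    min_angle_deg: float,
) -> bool:
    """Hydrogen-bond test for an H / acceptor serial pair."""
    i_h = s_idx[serial_h]
    i_a = s_idx[serial_acc]
    if elements[i_a] not in _ACCEPTOR_ELEMENTS:
        return False
    donors = [d for d in adj[serial_h]]
    if len(donors) != 1:
        return False
    i_d = s_idx[donors[0]]
    if elements[i_d] not in _DONOR_ELEMENTS:
        return False
    ha = coords[i_a] - coords[i_h]
    d_ha = np.linalg.norm(ha)
    if d_ha > max_dist or d_ha < 1e-6:
        return False
    hd = coords[i_d] - coords[i_h]
    cos = np.dot(hd, ha) / (np.linalg.norm(hd) * d_ha)
    angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return angle >= min_angle_deg


def find_clashes(
    s: MolecularStructure,
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
    vdw_radii: dict[str, float] | None = None,
    hbond_max_dist: float = HBOND_MAX_DIST,
    hbond_min_angle: float = HBOND_MIN_ANGLE,
    exclude_within_bonds: int = 3,
    polar_h_radius: float | None = POLAR_H_RADIUS,
) -> ClashReport:
    """All-atom clash detection.

    Requires hydrogens (all-atom convention) and an inferred bond graph.
    Candidate pairs come from a KD-tree search; each surviving pair with
    ``r_vdw(a) + r_vdw(b) - d >= overlap_cutoff`` is reported once,
    sorted by decreasing overlap.  Hydrogen-bonded H···acceptor pairs
    are exempt.  Pairs within ``exclude_within_bonds`` covalent bonds
    are ineligible (default 3: 1-2, 1-3 and 1-4 excluded, matching
    validation-tool practice where even ideal covalent geometry puts
    1-4 partners inside vdW contact).  Hydrogens bonded to N/O/S use the
    reduced ``polar_h_radius`` (pass ``None`` to keep the element table).
    """
    n = len(s.atoms)
    if n == 0:
        return ClashReport(records=[], n_atoms=0)
    if not any(a.element == "H" for a in s.atoms):
        raise ValueError(
            "clash analysis is all-atom: structure has no hydrogens; "
            "run hydrogenation first"
        )
    coords = s.coords
    elements = [a.element for a in s.atoms]
    serials = [a.serial for a in s.atoms]
    radii = np.array([vdw_radius(e, vdw_radii) for e in elements])
    s_idx = s.serial_to_index
    adj = s.adjacency()
    if polar_h_radius is not None:
        for i, a in enumerate(s.atoms):
            if a.element != "H":
                continue
            partners = adj[a.serial]
            if any(elements[s_idx[p]] in _DONOR_ELEMENTS for p in partners):
                radii[i] = polar_h_radius
    excluded = _topo_excluded_pairs(s, exclude_within_bonds)

    tree = cKDTree(coords)
    cutoff = 2.0 * radii.max() - overlap_cutoff
    records: list[ClashRecord] = []
    for i, j in tree.query_pairs(max(cutoff, 0.1)):
        sa, sb = serials[i], serials[j]
        pair = (min(sa, sb), max(sa, sb))
        if pair in excluded:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        overlap = float(radii[i] + radii[j] - d)
        if overlap < overlap_cutoff:
            continue
        exempt = False
        for h, other in ((sa, sb), (sb, sa)):
            if elements[s_idx[h]] == "H" and _is_hbond(
                s_idx, coords, elements, adj, h, other,
                hbond_max_dist, hbond_min_angle,
            ):
                exempt = True
                break
        if exempt:
            continue
        a, b = s.atoms[i], s.atoms[j]
        records.append(
            ClashRecord(
                serial_a=pair[0],
                serial_b=pair[1],
                residue_a=(a if a.serial == pair[0] else b).residue_key,
                residue_b=(b if a.serial == pair[0] else a).residue_key,
                distance=d,
                overlap=overlap,
            )
        )
    records.sort(key=lambda r: (-r.overlap, r.serial_a, r.serial_b))
    return ClashReport(records=records, n_atoms=n)


def min_interresidue_h_distance(
    s: MolecularStructure,
    res_a: tuple[str, int, str],
    res_b: tuple[str, int, str],
) -> float:
    """Exact minimum H-H distance between two distinct residues.

    Residue keys are ``(chain_id, residue_seq, residue_name)``.  Both
    residues must carry hydrogens; no cutoff is applied.
    """
    if res_a == res_b:
        raise ValueError("residues must be distinct")
    index = s.residue_index
    for key in (res_a, res_b):
        if key not in index:
            raise ValueError(f"residue {key} not found in structure")
    s_idx = s.serial_to_index
    coords = s.coords

    def h_coords(key):
        out = [
            coords[s_idx[ser]]
            for ser in index[key]
            if s.atoms[s_idx[ser]].element == "H"
        ]
        if not out:
            raise ValueError(f"residue {key} carries no hydrogens")
        return np.array(out)

    ha, hb = h_coords(res_a), h_coords(res_b)
    diff = ha[:, None, :] - hb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())
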