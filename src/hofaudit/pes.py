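"""Rigid-fragment potential-energy-surface scans along a distance grid.

Two internally rigid fragments are translated relative to each other so
that a monitored atom pair (by default the closest hydrogen-hydrogen
pair across the fragments) sits at each requested separation; the
backend energy is evaluated at every point.  Energies are reported
relative to the largest separation, and the minimum is refined by local
polynomial interpolation around the grid minimum.

Rigid scans are deterministic: no relaxation is performed at any grid
point, so the profile characterizes the fixed-fragment interaction
shape — the balance of short-range repulsion against the attractive
dispersion-like well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .energy import GAS, EnergyBackend, Phase, _check_phase
from .structure import MolecularStructure

__all__ = [
    "ScanSpec",
    "PESProfile",
    "default_grid",
    "rigid_scan",
    "locate_minimum",
]


def default_grid(start: float = 1.4, stop: float = 5.0, step: float = 0.1) -> np.ndarray:
    """Default scan grid 1.4-5.0 Å in 0.1 Å steps."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass
class ScanSpec:
    """Definition of a rigid two-fragment distance scan.

    ``fragment_a`` and ``fragment_b`` are disjoint, non-empty atom
    serial sets.  ``monitored_pair`` (serial in a, serial in b) is the
    distance that is driven over ``distances``; when omitted the closest
    H-H pair across the fragments is used, falling back to the closest
    pair of any elements.  ``axis`` overrides the translation direction
    (default: along the monitored pair).
    """

    fragment_a: set[int]
    fragment_b: set[int]
    distances: np.ndarray = field(default_factory=default_grid)
    monitored_pair: tuple[int, int] | None = None
    axis: np.ndarray | None = None
    phase: Phase = GAS

    def __post_init__(self):
        self.fragment_a = set(self.fragment_a)
        self.fragment_b = set(self.fragment_b)
        if not self.fragment_a or not self.fragment_b:
            raise ValueError("both fragments must be non-empty")
        if self.fragment_a & self.fragment_b:
            raise ValueError("fragments must be disjoint")
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.size < 3:
            raise ValueError("scan grid needs at least 3 points")
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("scan grid must be strictly increasing")
        _check_phase(self.phase)


@dataclass
class PESProfile:
    """Scan result: grid, relative energies, interpolated minimum."""

    distances: np.ndarray
    rel_energies: np.ndarray
    r_min: float
    depth: float
    unbound: bool = False
    overlap_flagged: bool = False


def _closest_pair(
    s: MolecularStructure, frag_a: set[int], frag_b: set[int], element: str | None
) -> tuple[int, int] | None:
    idx = s.serial_to_index
    coords = s.coords

    def sel(frag):
        return [
            ser for ser in sorted(frag)
            if element is None or s.atoms[idx[ser]].element == element
        ]

    aa, bb = sel(frag_a), sel(frag_b)
    if not aa or not bb:
        return None
    ca = coords[[idx[x] for x in aa]]
    cb = coords[[idx[x] for x in bb]]
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return aa[i], bb[j]


def rigid_scan(
    s: MolecularStructure, spec: ScanSpec, backend: EnergyBackend
) -> PESProfile:
    """Translate fragment_b rigidly so the monitored pair distance equals
    each grid value; evaluate the backend at every point."""
    idx = s.serial_to_index
    missing = (spec.fragment_a | spec.fragment_b) - set(idx)
    if missing:
        raise ValueError(f"fragment serials not in structure: {sorted(missing)}")

    pair = spec.monitored_pair
    if pair is None:
        pair = _closest_pair(s, spec.fragment_a, spec.fragment_b, "H")
        if pair is None:
            pair = _closest_pair(s, spec.fragment_a, spec.fragment_b, None)
    pa, pb = pair
    if pa not in spec.fragment_a or pb not in spec.fragment_b:
        raise ValueError("monitored pair must span (fragment_a, fragment_b)")

    coords0 = s.coords
    b_rows = [idx[x] for x in sorted(spec.fragment_b)]
    ref_a = coords0[idx[pa]]
    ref_b = coords0[idx[pb]]
    if spec.axis is not None:
        axis = np.asarray(spec.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
    else:
        axis = ref_b - ref_a
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            raise ValueError("monitored pair is coincident; supply an axis")
        axis = axis / nrm

    energies = np.empty_like(spec.distances)
    overlap_flagged = False
    for k, r in enumerate(spec.distances):
        coords = coords0.copy()
        # place pb at ref_a + r*axis, shifting the whole of fragment_b
        shift = (ref_a + r * axis) - ref_b
        coords[b_rows] += shift
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            energies[k] = backend.evaluate(s.with_coords(coords), spec.phase)
        if any("overlap" in str(w.message) for w in caught):
            overlap_flagged = True

    rel = energies - energies[-1]
    r_min, depth, unbound = locate_minimum_arrays(spec.distances, rel)
    return PESProfile(
        distances=spec.distances.copy(),
        rel_energies=rel,
        r_min=r_min,
        depth=depth,
        unbound=unbound,
        overlap_flagged=overlap_flagged,
    )


def _quadratic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    x0, x1, x2 = x
    y0, y1, y2 = y
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    if a <= 0:  # degenerate curvature
        return None
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    xv = float(np.clip(-b / (2 * a), x0, x2))
    c = y1 - a * x1**2 - b * x1
    return xv, float(a * xv**2 + b * xv + c)


def _cubic_minimum(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    coeffs = np.polyfit(x, y, 3)
    deriv = np.polyder(coeffs)
    for root in np.roots(deriv):
        if abs(root.imag) > 1e-9:
            continue
        r = float(root.real)
        if x[0] <= r <= x[-1] and np.polyval(np.polyder(deriv), r) > 0:
            return r, float(np.polyval(coeffs, r))
    return None


def locate_minimum_arrays(
    distances: np.ndarray, energies: np.ndarray
) -> tuple[float, float, bool]:
    """Local polynomial refinement of the grid minimum.

    A cubic is fitted through the four points bracketing the grid
    minimum (three-point quadratic when only three are available or the
    cubic has no interior minimum).  Returns ``(r_min, depth,
    unbound)``; a minimum at either endpoint is returned as-is with
    ``unbound=True``.
    """
    distances = np.asarray(distances, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if distances.size < 3:
        raise ValueError("need at least 3 grid points")
    k = int(np.argmin(energies))
    if k == 0 or k == distances.size - 1:
        return float(distances[k]), float(energies[k]), True
    if distances.size >= 4:
        lo = int(np.clip(k - 1, 0, distances.size - 4))
        fit = _cubic_minimum(distances[lo: lo + 4], energies[lo: lo + 4])
        if fit is not None:
            return fit[0], fit[1], False
    fit = _quadratic_vertex(distances[k - 1: k + 2], energies[k - 1: k + 2])
    if fit is None:  # flat or concave neighborhood; keep the grid point
        return float(distances[k]), float(energies[k]), False
    return fit[0], fit[1], False


def locate_minimum(profile: PESProfile) -> tuple[float, float]:
    """Interpolated ``(r_min, depth)`` of an existing profile."""
    r, d, _ = locate_minimum_arrays(profile.distances, profile.rel_energies)
    return r, d
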