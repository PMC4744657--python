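"""Energy-calculator contract, surrogate force field, and energy-record I/O.

The external quantum-chemistry engine that produced the packaged
heat-of-formation table is never re-run here; its numbers are consumed
as :class:`PhaseEnergyRecord` rows.  For every pipeline stage that needs
a live energy function (hydrogen-position optimization, PES scans,
perturbation studies) a deliberately simple surrogate force field is
provided:

* harmonic bond terms ``k_b (b - b0)^2`` with ``b0`` the covalent-radius
  sum (overridable per element pair),
* harmonic angle terms ``k_th (theta - theta0)^2`` over all bonded
  angle triples,
* 12-6 Lennard-Jones terms ``4 eps [(sigma/r)^12 - (sigma/r)^6]`` over
  atom pairs separated by three or more bonds (1-2 and 1-3 excluded,
  1-4 at full strength),
* an aqueous phase that scales every pair well depth by a constant
  factor, standing in for the damping of nonbonded attraction by a
  polarizable continuum.

The surrogate is a testing device, not a fitted model: its parameters
are documented defaults, editable through a plain-text key-value file.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .elements import vdw_radius, covalent_radius
from .structure import MolecularStructure

__all__ = [
    "Phase",
    "PhaseEnergyRecord",
    "EnergyTableError",
    "read_energy_table",
    "write_energy_table",
    "EnergyBackend",
    "SurrogateParams",
    "SurrogateForceField",
    "read_mopac_heat_of_formation",
]

# phases are plain strings, validated centrally
GAS = "gas"
AQUEOUS = "aqueous"
Phase = str

ENERGY_TABLE_COLUMNS = [
    "structure_id",
    "n",
    "hof_pdb_gas",
    "hof_pdb_aq",
    "hof_opt_gas",
    "hof_opt_aq",
]


def _check_phase(phase: Phase) -> Phase:
    if phase not in (GAS, AQUEOUS):
        raise ValueError(f"phase must be 'gas' or 'aqueous', got {phase!r}")
    return phase


# ---------------------------------------------------------------------------
# energy records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseEnergyRecord:
    """Four heats of formation (kcal/mol) plus atom count for one protein.

    ``hof_pdb_*`` are single-point energies at the deposited geometry;
    ``hof_opt_*`` are energies after full geometry optimization, in gas
    phase and with implicit aqueous solvation respectively.
    """

    structure_id: str
    n: int
    hof_pdb_gas: float
    hof_pdb_aq: float
    hof_opt_gas: float
    hof_opt_aq: float

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError(f"{self.structure_id}: atom count must be positive")
        for name in ("hof_pdb_gas", "hof_pdb_aq", "hof_opt_gas", "hof_opt_aq"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{self.structure_id}: non-finite {name}")
        # optimization should lower the energy; a violation is suspicious
        # but not fatal (the record may come from a constrained run)
        if self.hof_opt_gas > self.hof_pdb_gas or self.hof_opt_aq > self.hof_pdb_aq:
            warnings.warn(
                f"{self.structure_id}: optimized energy above single-point energy"
            )

    def single_point(self, phase: Phase) -> float:
        return self.hof_pdb_gas if _check_phase(phase) == GAS else self.hof_pdb_aq

    def optimized(self, phase: Phase) -> float:
        return self.hof_opt_gas if _check_phase(phase) == GAS else self.hof_opt_aq


class EnergyTableError(ValueError):
    """Schema or parse failure in an energy-record CSV."""


def _clean_number(value) -> float:
    """Parse a number accepting Unicode minus signs and thousands commas."""
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip().replace("−", "-").replace("–", "-")
    s = s.replace(",", "")
    return float(s)


def read_energy_table(path: str | Path) -> list[PhaseEnergyRecord]:
    """Read a heat-of-formation CSV into records.

    Expected header: ``structure_id,n,hof_pdb_gas,hof_pdb_aq,hof_opt_gas,
    hof_opt_aq``.  Numbers are parsed at full precision; Unicode minus
    signs and thousands separators are accepted.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in ENERGY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise EnergyTableError(f"missing column(s) {missing} in {path}")
    records = []
    for _, row in df.iterrows():
        sid = str(row["structure_id"]).strip()
        try:
            records.append(
                PhaseEnergyRecord(
                    structure_id=sid,
                    n=int(_clean_number(row["n"])),
                    hof_pdb_gas=_clean_number(row["hof_pdb_gas"]),
                    hof_pdb_aq=_clean_number(row["hof_pdb_aq"]),
                    hof_opt_gas=_clean_number(row["hof_opt_gas"]),
                    hof_opt_aq=_clean_number(row["hof_opt_aq"]),
                )
            )
        except (ValueError, TypeError) as exc:
            if isinstance(exc, EnergyTableError):
                raise
            raise EnergyTableError(f"row {sid!r}: {exc}") from exc
    return records


def write_energy_table(records: list[PhaseEnergyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "structure_id": r.structure_id,
                "n": r.n,
                "hof_pdb_gas": r.hof_pdb_gas,
                "hof_pdb_aq": r.hof_pdb_aq,
                "hof_opt_gas": r.hof_opt_gas,
                "hof_opt_aq": r.hof_opt_aq,
            }
            for r in records
        ],
        columns=ENERGY_TABLE_COLUMNS,
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# backend contract
# ---------------------------------------------------------------------------


class EnergyBackend:
    """Contract every energy calculator must satisfy.

    ``evaluate`` must be deterministic for a fixed input, and
    ``gradient`` must agree with ``evaluate`` under central finite
    differences (checked in the test suite on small fixtures).
    """

    def evaluate(self, s: MolecularStructure, phase: Phase = GAS) -> float:
        raise NotImplementedError

    def gradient(self, s: MolecularStructure, phase: Phase = GAS) -> np.ndarray:
        raise NotImplementedError

    def optimize(
        self,
        s: MolecularStructure,
        phase: Phase = GAS,
        frozen: np.ndarray | None = None,
        gtol: float = 0.1,
        maxiter: int = 2000,
    ) -> tuple[MolecularStructure, float]:
        raise NotImplementedError

    def coordinate_function(self, s: MolecularStructure, phase: Phase = GAS):
        """Closure ``f(coords) -> (energy, gradient)`` over raw (n, 3)
        arrays, for optimizers that drive coordinates directly.  The
        default rebuilds a structure per call; backends may override
        with something faster."""

        def f(coords: np.ndarray):
            st = s.with_coords(coords)
            return self.evaluate(st, phase), self.gradient(st, phase)

        return f


# ---------------------------------------------------------------------------
# surrogate force field
# ---------------------------------------------------------------------------

_TWO_SIXTH = 2.0 ** (1.0 / 6.0)


@dataclass
class SurrogateParams:
    """Parameters of the surrogate force field.

    Units: ``k_bond`` kcal/mol/Å², ``k_angle`` kcal/mol/rad²,
    ``theta0_deg`` degrees, ``sigma``/``b0`` Å, ``epsilon`` kcal/mol.
    Per-element σ defaults to ``2 r_vdw / 2^(1/6)`` so an isolated pair
    has its 12-6 minimum at van der Waals contact; ε defaults to 0.1 for
    every element.  The aqueous phase multiplies pair well depths by
    ``aqueous_factor``.
    """

    k_bond: float = 300.0
    k_angle: float = 50.0
    theta0_deg: float = 109.47
    epsilon_default: float = 0.1
    aqueous_factor: float = 0.6
    sigma_overrides: dict[str, float] = field(default_factory=dict)
    epsilon_overrides: dict[str, float] = field(default_factory=dict)
    b0_overrides: dict[frozenset, float] = field(default_factory=dict)

    def sigma(self, element: str) -> float:
        if element in self.sigma_overrides:
            return self.sigma_overrides[element]
        return 2.0 * vdw_radius(element) / _TWO_SIXTH

    def epsilon(self, element: str) -> float:
        return self.epsilon_overrides.get(element, self.epsilon_default)

    def b0(self, elem_a: str, elem_b: str) -> float:
        key = frozenset((elem_a, elem_b))
        if key in self.b0_overrides:
            return self.b0_overrides[key]
        return covalent_radius(elem_a) + covalent_radius(elem_b)

    @classmethod
    def from_file(cls, path: str | Path) -> "SurrogateParams":
        """Load parameters from a plain-text key-value file.

        Scalar lines: ``k_bond 300.0``.  Per-element lines:
        ``sigma C 3.03`` / ``epsilon H 0.02``.  Bond-length lines:
        ``b0 O H 0.96``.  ``#`` starts a comment.
        """
        p = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            key = tok[0]
            if key in ("k_bond", "k_angle", "theta0_deg", "epsilon_default",
                       "aqueous_factor"):
                setattr(p, key, float(tok[1]))
            elif key == "sigma" and len(tok) == 3:
                p.sigma_overrides[tok[1].upper()] = float(tok[2])
            elif key == "epsilon" and len(tok) == 3:
                p.epsilon_overrides[tok[1].upper()] = float(tok[2])
            elif key == "b0" and len(tok) == 4:
                p.b0_overrides[frozenset((tok[1].upper(), tok[2].upper()))] = float(tok[3])
            else:
                raise ValueError(f"unrecognized parameter line: {raw!r}")
        return p


class _Topology:
    """Precomputed index arrays for one bond graph."""

    def __init__(self, s: MolecularStructure, params: SurrogateParams):
        n = len(s.atoms)
        idx = s.serial_to_index
        elements = [a.element for a in s.atoms]

        bond_pairs = sorted((idx[a], idx[b]) for a, b in s.bonds)
        self.bond_i = np.array([p[0] for p in bond_pairs], dtype=int)
        self.bond_j = np.array([p[1] for p in bond_pairs], dtype=int)
        self.b0 = np.array(
            [params.b0(elements[i], elements[j]) for i, j in bond_pairs]
        )

        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j in bond_pairs:
            adj[i].add(j)
            adj[j].add(i)

        # angles: every unordered neighbor pair around each central atom
        tri = []
        for j in range(n):
            nb = sorted(adj[j])
            for a in range(len(nb)):
                for b in range(a + 1, len(nb)):
                    tri.append((nb[a], j, nb[b]))
        self.ang_i = np.array([t[0] for t in tri], dtype=int)
        self.ang_j = np.array([t[1] for t in tri], dtype=int)
        self.ang_k = np.array([t[2] for t in tri], dtype=int)

        # nonbonded pairs: all i<j except 1-2 and 1-3
        excluded = {tuple(sorted(p)) for p in bond_pairs}
        excluded |= {tuple(sorted((t[0], t[2]))) for t in tri}
        pi, pj = np.triu_indices(n, k=1)
        mask = np.array(
            [(int(a), int(b)) not in excluded for a, b in zip(pi, pj)], dtype=bool
        )
        self.nb_i = pi[mask]
        self.nb_j = pj[mask]
        sig = np.array([params.sigma(e) for e in elements])
        eps = np.array([params.epsilon(e) for e in elements])
        # Lorentz-Berthelot combining
        self.nb_sigma = 0.5 * (sig[self.nb_i] + sig[self.nb_j])
        self.nb_eps = np.sqrt(eps[self.nb_i] * eps[self.nb_j])
        self.n = n


class SurrogateForceField(EnergyBackend):
    """Harmonic-bond / harmonic-angle / 12-6 surrogate energy backend."""

    def __init__(self, params: SurrogateParams | None = None):
        self.params = params or SurrogateParams()
        self._cache: tuple[int, frozenset, _Topology] | None = None

    # -- topology handling ------------------------------------------------

    def _topology(self, s: MolecularStructure) -> _Topology:
        key = (len(s.atoms), frozenset(s.bonds))
        if self._cache is not None and self._cache[:2] == key:
            return self._cache[2]
        topo = _Topology(s, self.params)
        self._cache = (key[0], key[1], topo)
        return topo

    # -- core numerics (operate on a raw coordinate array) -----------------

    def _energy_grad(
        self, topo: _Topology, coords: np.ndarray, phase: Phase, want_grad: bool
    ) -> tuple[float, np.ndarray | None]:
        p = self.params
        grad = np.zeros_like(coords) if want_grad else None
        energy = 0.0

        if topo.bond_i.size:
            dv = coords[topo.bond_i] - coords[topo.bond_j]
            d = np.linalg.norm(dv, axis=1)
            delta = d - topo.b0
            energy += float(np.sum(p.k_bond * delta**2))
            if want_grad:
                f = (2.0 * p.k_bond * delta / np.maximum(d, 1e-12))[:, None] * dv
                np.add.at(grad, topo.bond_i, f)
                np.add.at(grad, topo.bond_j, -f)

        if topo.ang_i.size:
            u = coords[topo.ang_i] - coords[topo.ang_j]
            v = coords[topo.ang_k] - coords[topo.ang_j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos = np.sum(u * v, axis=1) / np.maximum(nu * nv, 1e-12)
            cos = np.clip(cos, -1.0, 1.0)
            theta = np.arccos(cos)
            theta0 = math.radians(p.theta0_deg)
            dtheta = theta - theta0
            energy += float(np.sum(p.k_angle * dtheta**2))
            if want_grad:
                sin = np.sqrt(np.maximum(1.0 - cos**2, 1e-12))
                uh = u / nu[:, None]
                vh = v / nv[:, None]
                dth_di = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
                dth_dk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
                coef = (2.0 * p.k_angle * dtheta)[:, None]
                np.add.at(grad, topo.ang_i, coef * dth_di)
                np.add.at(grad, topo.ang_k, coef * dth_dk)
                np.add.at(grad, topo.ang_j, -coef * (dth_di + dth_dk))

        if topo.nb_i.size:
            dv = coords[topo.nb_i] - coords[topo.nb_j]
            d = np.linalg.norm(dv, axis=1)
            if np.any(d < 0.1):
                worst = int(np.argmin(d))
                warnings.warn(
                    "overlapping nonbonded pair "
                    f"(indices {topo.nb_i[worst]}-{topo.nb_j[worst]}, "
                    f"r={d[worst]:.3f} Å)"
                )
            d = np.maximum(d, 1e-6)
            eps = topo.nb_eps * (p.aqueous_factor if phase == AQUEOUS else 1.0)
            sr6 = (topo.nb_sigma / d) ** 6
            energy += float(np.sum(4.0 * eps * (sr6**2 - sr6)))
            if want_grad:
                # dE/dr = 4 eps (-12 s^12/r^13 + 6 s^6/r^7)
                dEdr = 4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6) / d
                f = (dEdr / d)[:, None] * dv
                np.add.at(grad, topo.nb_i, f)
                np.add.at(grad, topo.nb_j, -f)

        return energy, grad

    # -- EnergyBackend interface ------------------------------------------

    def evaluate(self, s: MolecularStructure, phase: Phase = GAS) -> float:
        _check_phase(phase)
        e, _ = self._energy_grad(self._topology(s), s.coords, phase, False)
        return e

    def gradient(self, s: MolecularStructure, phase: Phase = GAS) -> np.ndarray:
        _check_phase(phase)
        _, g = self._energy_grad(self._topology(s), s.coords, phase, True)
        return g

    def coordinate_function(self, s: MolecularStructure, phase: Phase = GAS):
        _check_phase(phase)
        topo = self._topology(s)

        def f(coords: np.ndarray):
            return self._energy_grad(topo, coords, phase, True)

        return f

    def optimize(
        self,
        s: MolecularStructure,
        phase: Phase = GAS,
        frozen: np.ndarray | None = None,
        gtol: float = 0.1,
        maxiter: int = 2000,
    ) -> tuple[MolecularStructure, float]:
        """Quasi-Newton minimization; ``frozen`` atoms keep their input
        coordinates bit-identically."""
        _check_phase(phase)
        topo = self._topology(s)
        x0 = s.coords
        if frozen is None:
            frozen = np.zeros(len(s.atoms), dtype=bool)
        frozen = np.asarray(frozen, dtype=bool)
        free = ~frozen
        if not free.any():
            return s.with_coords(x0), self.evaluate(s, phase)

        base = x0.copy()

        def fun(x_free: np.ndarray):
            coords = base.copy()
            coords[free] = x_free.reshape(-1, 3)
            e, g = self._energy_grad(topo, coords, phase, True)
            if not math.isfinite(e):
                d = np.linalg.norm(coords[topo.nb_i] - coords[topo.nb_j], axis=1)
                worst = int(np.argmin(d))
                raise FloatingPointError(
                    "non-finite surrogate energy; closest pair is atom indices "
                    f"{topo.nb_i[worst]}-{topo.nb_j[worst]} at {d[worst]:.4f} Å"
                )
            return e, g[free].ravel()

        res = minimize(
            fun,
            base[free].ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        coords = base.copy()
        coords[free] = res.x.reshape(-1, 3)
        # L-BFGS-B can in rare line-search failures return a worse point;
        # never accept an energy above the starting one
        e_final = float(res.fun)
        e_start, _ = self._energy_grad(topo, base, phase, False)
        if e_final > e_start:
            return s.with_coords(base), e_start
        return s.with_coords(coords), e_final


# ---------------------------------------------------------------------------
# optional external-engine adapter
# ---------------------------------------------------------------------------

_HOF_RE = re.compile(
    r"FINAL HEAT OF FORMATION\s*=\s*(-?[\d.]+)\s*KCAL/MOL", re.IGNORECASE
)


def read_mopac_heat_of_formation(path: str | Path) -> float:
    """Extract the final heat of formation (kcal/mol) from a
    semiempirical-program output file.  Optional plug-in point; nothing
    in the pipeline requires it."""
    text = Path(path).read_text(errors="replace")
    matches = _HOF_RE.findall(text)
    if not matches:
        raise ValueError(f"no 'FINAL HEAT OF FORMATION' line found in {path}")
    return float(matches[-1])
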