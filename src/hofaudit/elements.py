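"""Element property tables: covalent and van der Waals radii.

Covalent radii follow the Cordero 2008 compilation (single-bond values,
Å); van der Waals radii follow Bondi 1964 with the common extensions.
Both tables are deliberately explicit and versioned in-source so that
bond inference and clash detection are reproducible; either can be
overridden per call via the ``radii``/``vdw_radii`` keyword arguments of
the functions that consume them.

Only elements that occur in protein structures and common hetero
components are listed; an unknown symbol raises ``UnknownElementError``
rather than silently defaulting.
"""

from __future__ import annotations

__all__ = [
    "COVALENT_RADII",
    "VDW_RADII",
    "UnknownElementError",
    "covalent_radius",
    "vdw_radius",
    "normalize_element",
]

# Cordero et al. single-bond covalent radii, Å (C is the sp3 value).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "D": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "F": 0.57,
    "CL": 1.02,
    "BR": 1.20,
    "I": 1.39,
    "SE": 1.20,
    "B": 0.84,
    "NA": 1.66,
    "MG": 1.41,
    "K": 2.03,
    "CA": 1.76,
    "MN": 1.61,
    "FE": 1.52,
    "CO": 1.50,
    "NI": 1.24,
    "CU": 1.32,
    "ZN": 1.22,
}

# Bondi van der Waals radii, Å (metals use the Batsanov-style extensions).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "B": 1.92,
    "NA": 2.27,
    "MG": 1.73,
    "K": 2.75,
    "CA": 2.31,
    "MN": 2.05,
    "FE": 2.04,
    "CO": 2.00,
    "NI": 1.63,
    "CU": 1.40,
    "ZN": 1.39,
}


class UnknownElementError(ValueError):
    """Raised when an element symbol has no entry in the radius tables."""


def normalize_element(symbol: str) -> str:
    """Return the canonical upper-case element symbol.

    Raises
    ------
    UnknownElementError
        If the stripped symbol is not in the packaged tables.
    """
    sym = symbol.strip().upper()
    if sym not in COVALENT_RADII:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}")
    return sym


def covalent_radius(symbol: str, table: dict[str, float] | None = None) -> float:
    table = COVALENT_RADII if table is None else table
    sym = symbol.strip().upper()
    try:
        return table[sym]
    except KeyError:
        raise UnknownElementError(f"no covalent radius for element {symbol!r}") from None


def vdw_radius(symbol: str, table: dict[str, float] | None = None) -> float:
    table = VDW_RADII if table is None else table
    sym = symbol.strip().upper()
    try:
        return table[sym]
    except KeyError:
        raise UnknownElementError(f"no van der Waals radius for element {symbol!r}") from None
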