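"""Element tables and physical constants.

Covers Z = 1-36 (H through Kr), the range supported by the built-in
model-proatom library. Radii beyond that range must be supplied by the user.
"""

from __future__ import annotations

# Unit conversions (CODATA-pinned values used throughout the package).
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
AU_TO_DEBYE = 2.5417464519
HARTREE_TO_KCALMOL = 627.5094740631

SYMBOLS = [
    "H", "He",
    "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
    "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
]

MAX_Z = len(SYMBOLS)

SYMBOL_TO_Z = {s: i + 1 for i, s in enumerate(SYMBOLS)}
# Accept case-insensitive symbols on input.
_SYMBOL_LOOKUP = {s.lower(): z for s, z in SYMBOL_TO_Z.items()}


def atomic_number(symbol: str) -> int:
    """Map an element symbol to its atomic number (supported range Z=1-36)."""
    try:
        return _SYMBOL_LOOKUP[symbol.strip().lower()]
    except KeyError:
        raise ValueError(f"unsupported element symbol: {symbol!r}") from None


def symbol(z: int) -> str:
    if not 1 <= z <= MAX_Z:
        raise ValueError(f"unsupported atomic number: {z}")
    return SYMBOLS[z - 1]


# Bondi-style van der Waals radii in Angstrom. Values for main-group
# elements follow Bondi (1964); the few metals without a Bondi value use
# commonly adopted extensions. Overridable via the `radii` argument of the
# surface sampler.
VDW_RADII_ANGSTROM = {
    "H": 1.20, "He": 1.40,
    "Li": 1.81, "Be": 1.53, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Ni": 1.63, "Cu": 1.40, "Zn": 1.39,
    "Ga": 1.87, "Ge": 2.11, "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02,
}


def vdw_radius_bohr(element: str, radii: dict | None = None) -> float:
    """Van der Waals radius in bohr; raises if no radius is tabulated."""
    table = radii if radii is not None else VDW_RADII_ANGSTROM
    key = symbol(atomic_number(element))
    if key not in table:
        raise ValueError(f"no van der Waals radius tabulated for {element!r}")
    return table[key] * ANGSTROM_TO_BOHR


# Bragg-Slater-like covalent radii in Angstrom, used only to set the midpoint
# of the radial quadrature map per element; missing entries fall back to 1 bohr.
BRAGG_RADII_ANGSTROM = {
    "H": 0.35, "He": 0.35,
    "Li": 1.45, "Be": 1.05, "B": 0.85, "C": 0.70, "N": 0.65, "O": 0.60,
    "F": 0.50, "Ne": 0.45,
    "Na": 1.80, "Mg": 1.50, "Al": 1.25, "Si": 1.10, "P": 1.00, "S": 1.00,
    "Cl": 1.00, "Ar": 1.00,
    "K": 2.20, "Ca": 1.80, "Sc": 1.60, "Ti": 1.40, "V": 1.35, "Cr": 1.40,
    "Mn": 1.40, "Fe": 1.40, "Co": 1.35, "Ni": 1.35, "Cu": 1.35, "Zn": 1.35,
    "Ga": 1.30, "Ge": 1.25, "As": 1.15, "Se": 1.15, "Br": 1.15, "Kr": 1.10,
}


def radial_midpoint_bohr(z: int) -> float:
    """Midpoint R_m of the rational radial map: half the Bragg-like radius."""
    sym = symbol(z)
    r_ang = BRAGG_RADII_ANGSTROM.get(sym)
    if r_ang is None:
        return 1.0
    return 0.5 * r_ang * ANGSTROM_TO_BOHR
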