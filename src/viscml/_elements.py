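"""Elemental constants for the composition feature block and MD geometry.

Properties per element: atomic number Z, atomic mass (u), Pauling
electronegativity, covalent radius (Å), Bondi-type van der Waals radius
(Å), first ionization energy (eV), electron affinity (eV), period, group,
and valence electron count. The table covers the organic element set the
curation filter admits.
"""

from __future__ import annotations

#: property name -> index into each element tuple
PROPERTY_NAMES = (
    "atomic_number",
    "atomic_mass",
    "electronegativity",
    "covalent_radius",
    "vdw_radius",
    "ionization_energy",
    "electron_affinity",
    "period",
    "group",
    "valence_electrons",
)

ELEMENT_PROPERTIES: dict[str, tuple[float, ...]] = {
    #         Z   mass     EN    r_cov  r_vdw   IE      EA     per  grp  val
    "H": (1, 1.008, 2.20, 0.31, 1.20, 13.598, 0.754, 1, 1, 1),
    "C": (6, 12.011, 2.55, 0.76, 1.70, 11.260, 1.262, 2, 14, 4),
    "N": (7, 14.007, 3.04, 0.71, 1.55, 14.534, 0.000, 2, 15, 5),
    "O": (8, 15.999, 3.44, 0.66, 1.52, 13.618, 1.461, 2, 16, 6),
    "F": (9, 18.998, 3.98, 0.57, 1.47, 17.423, 3.401, 2, 17, 7),
    "Si": (14, 28.085, 1.90, 1.11, 2.10, 8.152, 1.390, 3, 14, 4),
    "P": (15, 30.974, 2.19, 1.07, 1.80, 10.487, 0.746, 3, 15, 5),
    "S": (16, 32.060, 2.58, 1.05, 1.80, 10.360, 2.077, 3, 16, 6),
    "Cl": (17, 35.450, 3.16, 1.02, 1.75, 12.968, 3.613, 3, 17, 7),
    "Br": (35, 79.904, 2.96, 1.20, 1.85, 11.814, 3.364, 4, 17, 7),
    "I": (53, 126.904, 2.66, 1.39, 1.98, 10.451, 3.059, 5, 17, 7),
}


def element_property(symbol: str, name: str) -> float:
    """Look up one property for one element symbol."""
    try:
        row = ELEMENT_PROPERTIES[symbol]
    except KeyError:
        raise KeyError(f"element {symbol!r} not in the bundled property table")
    return float(row[PROPERTY_NAMES.index(name)])


def vdw_radius(symbol: str) -> float:
    """Bondi-type van der Waals radius in Å."""
    return element_property(symbol, "vdw_radius")


def atomic_mass(symbol: str) -> float:
    """Atomic mass in unified atomic mass units."""
    return element_property(symbol, "atomic_mass")
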