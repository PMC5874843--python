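"""Element reference data: standard atomic weights, van der Waals radii, nonbonded defaults.

Weights are the 2021 IUPAC abridged (four-significant-figure) standard atomic
weights; they are the default table for molar-mass arithmetic and may be
overridden per call.  Radii follow Bondi's compilation with Rowland-Taylor
updates; elements missing from that set fall back to 2.0 Å.
"""

from __future__ import annotations

# 2021 IUPAC abridged standard atomic weights, g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.94, "Be": 9.012, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Ti": 47.867, "Cr": 51.996, "Mn": 54.938, "Fe": 55.845, "Co": 58.933,
    "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "Se": 78.971, "Br": 79.904,
    "Ag": 107.87, "I": 126.90, "Pt": 195.08, "Au": 196.97,
    # "X" is the package's generic Lennard-Jones probe site (synthetic toy
    # systems); unit weight, no physical meaning.
    "X": 1.0,
}

# van der Waals radii, Å (Bondi / Rowland-Taylor).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40, "Li": 1.82, "B": 1.92, "C": 1.70, "N": 1.55,
    "O": 1.52, "F": 1.47, "Ne": 1.54, "Na": 2.27, "Mg": 1.73, "Si": 2.10,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88, "K": 2.75, "Ca": 2.31,
    "Ni": 1.63, "Cu": 1.40, "Zn": 1.39, "Se": 1.90, "Br": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 2.0

# Per-element Lennard-Jones defaults (sigma Å, epsilon kcal/mol) for the
# bundled pair-potential energy model.  These are generic organic-forcefield
# magnitudes, adequate for geometry screening; they are configurable on the
# model and make no claim of quantum-chemical accuracy.
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (2.50, 0.030),
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "O": (3.12, 0.210),
    "P": (3.74, 0.200),
    "S": (3.60, 0.250),
    "Cl": (3.47, 0.265),
    "Br": (3.60, 0.320),
    "Na": (3.33, 0.003),
    "X": (3.40, 0.100),  # generic site used by synthetic toy systems
}
DEFAULT_LJ = (3.40, 0.100)

#: Coulomb constant, kcal Å mol^-1 e^-2.
COULOMB_CONSTANT = 332.0636


def atomic_weight(element: str, table: dict[str, float] | None = None) -> float:
    """Standard atomic weight of ``element`` in g/mol.

    Raises ``KeyError`` with the offending symbol if the element is not in
    the (possibly overridden) weight table.
    """
    tbl = ATOMIC_WEIGHTS if table is None else table
    try:
        return tbl[element]
    except KeyError:
        raise KeyError(f"no standard atomic weight for element symbol {element!r}") from None


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element, DEFAULT_VDW_RADIUS)


def lj_params(element: str) -> tuple[float, float]:
    return LJ_PARAMS.get(element, DEFAULT_LJ)
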