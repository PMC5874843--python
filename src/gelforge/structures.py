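"""Molecular data model, formula arithmetic, and coarse structure builders.

The in-memory currency of the whole pipeline is :class:`Molecule`: parallel
arrays of elements, Cartesian coordinates (Å), partial charges (e), van der
Waals radii (Å) and free-text role tags, plus an explicit bond list.  On top
of it sit idealized builders (PVA chains from standard bond lengths and
tetrahedral angles) and a rejection-sampling rigid packer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import elements as elem
from .errors import FormulaError, PackingError

__all__ = [
    "Atom", "Molecule", "MolecularFormula", "PolymerChain", "SimulationBox",
    "parse_formula", "molar_mass", "build_pva_chain", "random_pack",
    "tetrahedral_partners",
]

# Standard bond lengths used by the idealized builders, Å.
BOND_CC = 1.54
BOND_CO = 1.43
BOND_CH = 1.09
BOND_OH = 0.96
TETRAHEDRAL_ANGLE = np.degrees(np.arccos(-1.0 / 3.0))  # 109.47°


@dataclass
class Atom:
    """One atom: element symbol, position (Å), partial charge (e), vdW radius (Å)."""

    element: str
    position: np.ndarray
    charge: float = 0.0
    radius: float | None = None
    role_tag: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.radius is None:
            self.radius = elem.vdw_radius(self.element)
        if self.radius <= 0:
            raise ValueError(f"van der Waals radius must be positive, got {self.radius}")
        elem.atomic_weight(self.element)  # validates the symbol


class Molecule:
    """An ordered atom collection with bond topology.

    Stored column-wise (numpy arrays) for speed; `atoms` reconstructs
    row-wise :class:`Atom` views on demand.
    """

    def __init__(self, elements, positions, charges=None, radii=None,
                 role_tags=None, bonds=(), name=""):
        self.elements = list(elements)
        n = len(self.elements)
        self.positions = np.array(positions, dtype=float).reshape(n, 3)
        self.charges = (np.zeros(n) if charges is None
                        else np.array(charges, dtype=float))
        if radii is None:
            radii = [elem.vdw_radius(e) for e in self.elements]
        self.radii = np.array(radii, dtype=float)
        self.role_tags = list(role_tags) if role_tags is not None else [""] * n
        self.bonds = [tuple(sorted((int(i), int(j)))) for i, j in bonds]
        self.name = name
        self._validate()

    def _validate(self):
        n = len(self.elements)
        if not (len(self.charges) == len(self.radii) == len(self.role_tags) == n
                and self.positions.shape == (n, 3)):
            raise ValueError("inconsistent per-atom array lengths")
        if np.any(self.radii <= 0):
            raise ValueError("all van der Waals radii must be positive")
        for e in set(self.elements):
            elem.atomic_weight(e)
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) out of range for {n} atoms")

    # -- convenience -------------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms, bonds=(), name=""):
        atoms = list(atoms)
        return cls(
            elements=[a.element for a in atoms],
            positions=[a.position for a in atoms],
            charges=[a.charge for a in atoms],
            radii=[a.radius for a in atoms],
            role_tags=[a.role_tag for a in atoms],
            bonds=bonds, name=name,
        )

    @property
    def atoms(self):
        return [Atom(e, p, c, r, t) for e, p, c, r, t in zip(
            self.elements, self.positions, self.charges, self.radii, self.role_tags)]

    def __len__(self):
        return len(self.elements)

    def copy(self, name=None):
        return Molecule(self.elements, self.positions.copy(), self.charges.copy(),
                        self.radii.copy(), self.role_tags, list(self.bonds),
                        self.name if name is None else name)

    def transformed(self, rotation=None, translation=None, name=None):
        """New molecule with ``R x + t`` applied to every coordinate."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation).T
        if translation is not None:
            pos = pos + np.asarray(translation, dtype=float)
        out = self.copy(name=name)
        out.positions = np.array(pos)
        return out

    def centroid(self):
        return self.positions.mean(axis=0)

    def remove_atoms(self, indices):
        """Return (new molecule, old→new index map) with ``indices`` deleted.

        Bonds touching a removed atom are dropped; the map holds -1 for
        removed atoms.
        """
        drop = set(int(i) for i in indices)
        keep = [i for i in range(len(self)) if i not in drop]
        imap = np.full(len(self), -1, dtype=int)
        imap[keep] = np.arange(len(keep))
        mol = Molecule(
            [self.elements[i] for i in keep], self.positions[keep],
            self.charges[keep], self.radii[keep],
            [self.role_tags[i] for i in keep],
            [(imap[i], imap[j]) for i, j in self.bonds
             if i not in drop and j not in drop],
            self.name)
        return mol, imap

    def masses(self, table=None):
        return np.array([elem.atomic_weight(e, table) for e in self.elements])

    def formula(self) -> "MolecularFormula":
        comp: dict[str, int] = {}
        for e in self.elements:
            comp[e] = comp.get(e, 0) + 1
        return MolecularFormula(comp)

    def connected_components(self):
        """List of atom-index sets, one per bond-connected component."""
        parent = list(range(len(self)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in self.bonds:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        groups: dict[int, set] = {}
        for i in range(len(self)):
            groups.setdefault(find(i), set()).add(i)
        return list(groups.values())


@dataclass
class MolecularFormula:
    """Element → count map with Hill-order canonical string and mass arithmetic."""

    composition: dict[str, int]

    def __post_init__(self):
        if not self.composition:
            raise FormulaError("empty formula")
        for e, c in self.composition.items():
            if c < 1:
                raise FormulaError(f"count for {e} must be >= 1, got {c}")
            elem.atomic_weight(e)

    def to_string(self) -> str:
        comp = dict(self.composition)
        order = []
        if "C" in comp:
            order.append("C")
            if "H" in comp:
                order.append("H")
        order += sorted(e for e in comp if e not in order)
        return "".join(f"{e}{comp[e] if comp[e] > 1 else ''}" for e in order)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        comp = dict(self.composition)
        for e, c in other.composition.items():
            comp[e] = comp.get(e, 0) + c
        return MolecularFormula(comp)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a chemical-formula string (Hill or free element order).

    ``"C21H26O5"`` → ``{C: 21, H: 26, O: 5}``; an implicit count is 1.
    Unknown element symbols raise :class:`FormulaError` naming the token.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    comp: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"unparseable formula token at {text[pos:]!r}")
        symbol, count = m.group(1), int(m.group(2) or 1)
        try:
            elem.atomic_weight(symbol)
        except KeyError:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}") from None
        comp[symbol] = comp.get(symbol, 0) + count
        pos = m.end()
    return MolecularFormula(comp)


def molar_mass(formula: MolecularFormula | str, table=None) -> float:
    """Count-weighted sum of standard atomic weights, g/mol."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return float(sum(c * elem.atomic_weight(e, table)
                     for e, c in formula.composition.items()))


@dataclass
class PolymerChain:
    """A PVA chain: the molecule plus the indices of its graftable hydroxyl oxygens."""

    monomer_count: int
    molecule: Molecule
    hydroxyl_sites: list[int] = field(default_factory=list)

    def __post_init__(self):
        for i in self.hydroxyl_sites:
            if self.molecule.elements[i] != "O":
                raise ValueError(f"hydroxyl site {i} is not an oxygen")


@dataclass
class SimulationBox:
    """Axis-aligned orthorhombic box; origin at a corner, lengths in Å."""

    lengths: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.lengths <= 0):
            raise ValueError("box lengths must be positive")

    def contains(self, coords) -> bool:
        coords = np.asarray(coords)
        return bool(np.all(coords >= self.origin) and
                    np.all(coords <= self.origin + self.lengths))


def tetrahedral_partners(u, v):
    """Two unit vectors completing a tetrahedral center whose known bonds point along u, v."""
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    e1 = u + v
    e1 /= np.linalg.norm(e1)
    e3 = np.cross(u, v)
    e3 /= np.linalg.norm(e3)
    c, s = 1.0 / np.sqrt(3.0), np.sqrt(2.0 / 3.0)
    return -c * e1 + s * e3, -c * e1 - s * e3


def build_pva_chain(n_monomers: int, seed: int = 0) -> PolymerChain:
    """Idealized extended zig-zag PVA chain, ``-[CH2-CH(OH)]n-``, H-capped ends.

    Geometry uses standard bond lengths (C-C 1.54, C-O 1.43, C-H 1.09,
    O-H 0.96 Å) and tetrahedral angles; the hydroxyl side of each CH carbon
    alternates randomly (atactic) under ``seed``.  Deterministic given seed.
    """
    if n_monomers < 1:
        raise ValueError(f"n_monomers must be >= 1, got {n_monomers}")
    rng = np.random.default_rng(seed)

    n_backbone = 2 * n_monomers
    theta = np.radians(TETRAHEDRAL_ANGLE / 2.0)
    dx, dy = BOND_CC * np.sin(theta), BOND_CC * np.cos(theta)
    backbone = np.array([[i * dx, (i % 2) * dy, 0.0] for i in range(n_backbone)])

    elements, positions, roles, bonds = [], [], [], []
    hydroxyl_sites = []
    backbone_idx = []

    def add(el, pos, role):
        elements.append(el)
        positions.append(np.asarray(pos, float))
        roles.append(role)
        return len(elements) - 1

    for i in range(n_backbone):
        ci = add("C", backbone[i], "backbone")
        backbone_idx.append(ci)
        if i > 0:
            bonds.append((backbone_idx[i - 1], ci))
        # directions of the (real or virtual) backbone neighbours
        if i > 0:
            prev_dir = backbone[i - 1] - backbone[i]
        else:
            prev_dir = np.array([-dx, dy if i % 2 == 0 else -dy, 0.0])
        next_dir = (backbone[i + 1] - backbone[i]) if i < n_backbone - 1 else \
            np.array([dx, dy if i % 2 == 0 else -dy, 0.0])
        w1, w2 = tetrahedral_partners(prev_dir, next_dir)
        is_choh = (i % 2 == 1)  # odd backbone carbons carry the hydroxyl
        if is_choh:
            if rng.random() < 0.5:
                w1, w2 = w2, w1  # atactic flip
            o = add("O", backbone[i] + BOND_CO * w1, "hydroxyl-O")
            bonds.append((ci, o))
            ho = add("H", positions[o] + BOND_OH * w1, "hydroxyl-H")
            bonds.append((o, ho))
            h = add("H", backbone[i] + BOND_CH * w2, "H")
            bonds.append((ci, h))
            hydroxyl_sites.append(o)
        else:
            h1 = add("H", backbone[i] + BOND_CH * w1, "H")
            h2 = add("H", backbone[i] + BOND_CH * w2, "H")
            bonds.append((ci, h1))
            bonds.append((ci, h2))
        if i == 0 or i == n_backbone - 1:
            # H cap along the missing backbone direction
            cap_dir = prev_dir if i == 0 else next_dir
            cap_dir = cap_dir / np.linalg.norm(cap_dir)
            hc = add("H", backbone[i] + BOND_CH * cap_dir, "cap-H")
            bonds.append((ci, hc))

    mol = Molecule(elements, positions, role_tags=roles, bonds=bonds,
                   name=f"PVA{n_monomers}")
    return PolymerChain(n_monomers, mol, hydroxyl_sites)


def _random_rotation(rng) -> np.ndarray:
    """Uniform SO(3) rotation matrix via normalized Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _align_rotation(principal, target, spin_angle, tilt_axis, tilt_angle) -> np.ndarray:
    """Rotation taking ``principal`` onto ``target`` followed by spin about the target and a small tilt."""
    from scipy.spatial.transform import Rotation as R
    v = np.cross(principal, target)
    s, c = np.linalg.norm(v), float(np.dot(principal, target))
    if s < 1e-12:
        perp = np.array([1.0, 0, 0]) if abs(target[0]) < 0.9 else np.array([0, 1.0, 0])
        perp -= target * np.dot(perp, target)
        perp /= np.linalg.norm(perp)
        align = np.eye(3) if c > 0 else R.from_rotvec(np.pi * perp).as_matrix()
    else:
        align = R.from_rotvec(np.arccos(np.clip(c, -1, 1)) * v / s).as_matrix()
    spin = R.from_rotvec(target * spin_angle).as_matrix()
    tilt = R.from_rotvec(tilt_axis * tilt_angle).as_matrix()
    return tilt @ spin @ align


def random_pack(chains, box: SimulationBox, min_separation: float, seed: int = 0,
                attempt_budget: int = 10_000) -> list[PolymerChain]:
    """Place rigid chains in ``box`` with a minimum inter-chain atom-atom distance.

    Rejection sampling in up to three escalating whole-pack stages, each
    deterministic given ``seed``:

    1. *uniform* — orientation uniform on SO(3), translation uniform over the
       in-box positions, accept if the nearest distance to all placed atoms
       is at least ``min_separation``;
    2. *axis-biased* — orientations concentrate near the longest box axis
       (isotropic orientations of long rigid rods jam well below the target
       density of the default configuration);
    3. *lattice-guided* — candidate positions come from a shuffled transverse
       lattice with pitch ``min_separation + chain cross-diameter``, with
       random spin and axial offset.

    Every accepted placement satisfies the separation postcondition
    regardless of stage.  Raises :class:`PackingError` with the achieved
    count if the final stage exhausts its per-chain ``attempt_budget``.
    """
    last_err = None
    for stage in range(3):
        try:
            return _pack_stage(chains, box, min_separation,
                               np.random.default_rng([seed, stage]),
                               attempt_budget, stage)
        except PackingError as err:
            last_err = err
    raise last_err


def _pack_stage(chains, box, min_separation, rng, attempt_budget, stage):
    placed: list[PolymerChain] = []
    placed_coords: list[np.ndarray] = []
    tree = None
    long_axis = np.zeros(3)
    long_axis[int(np.argmax(box.lengths))] = 1.0
    short_dims = [d for d in range(3) if d != int(np.argmax(box.lengths))]

    lattice = None
    if stage == 2 and chains:
        base0 = chains[0].molecule.positions - chains[0].molecule.positions.mean(axis=0)
        _, _, vt = np.linalg.svd(base0, full_matrices=False)
        cross = base0 - np.outer(base0 @ vt[0], vt[0])
        pitch = min_separation + 2.0 * float(np.linalg.norm(cross, axis=1).max())
        axes = []
        for d in short_dims:
            n_sites = max(1, int(box.lengths[d] // pitch))
            offset = (box.lengths[d] - (n_sites - 1) * pitch) / 2.0
            axes.append(box.origin[d] + offset + pitch * np.arange(n_sites))
        lattice = [(a, b) for a in axes[0] for b in axes[1]]

    for ci, chain in enumerate(chains):
        base = chain.molecule.positions - chain.molecule.positions.mean(axis=0)
        _, _, vt = np.linalg.svd(base, full_matrices=False)
        principal = vt[0]
        sites = None
        if lattice is not None:
            sites = list(lattice)
            rng.shuffle(sites)
        ok = False
        for attempt in range(attempt_budget):
            if stage == 0:
                rot = _random_rotation(rng)
            else:
                tilt_ax = rng.normal(size=3)
                tilt_ax /= np.linalg.norm(tilt_ax)
                max_tilt = np.radians(3.0 if stage == 1 else 1.0)
                rot = _align_rotation(
                    principal, long_axis * (1 if rng.random() < 0.5 else -1),
                    rng.uniform(0, 2 * np.pi), tilt_ax, rng.uniform(0, max_tilt))
            cand = base @ rot.T
            lo, hi = cand.min(axis=0), cand.max(axis=0)
            span = box.lengths - (hi - lo)
            if np.any(span <= 0):
                continue
            shift = box.origin - lo + rng.uniform(0, 1, 3) * span
            if sites is not None:
                site = sites[attempt % len(sites)]
                center = -(lo + hi) / 2.0
                for d, val in zip(short_dims, site):
                    shift[d] = center[d] + val
                cand2 = cand + shift
                if not (np.all(cand2 >= box.origin) and
                        np.all(cand2 <= box.origin + box.lengths)):
                    continue
                cand = cand2
            else:
                cand = cand + shift
            if tree is not None:
                d, _ = tree.query(cand, k=1)
                if float(np.min(d)) < min_separation:
                    continue
            mol = chain.molecule.copy()
            mol.positions = cand
            placed.append(PolymerChain(chain.monomer_count, mol,
                                       list(chain.hydroxyl_sites)))
            placed_coords.append(cand)
            tree = cKDTree(np.vstack(placed_coords))
            ok = True
            break
        if not ok:
            raise PackingError(
                f"could not place chain {ci} within {attempt_budget} attempts",
                achieved=len(placed))
    return placed
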