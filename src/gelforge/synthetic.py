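"""Synthetic-data generators with machine-readable ground truth.

Every input class the pipeline consumes can be generated here with known
answers: toy ring hosts with an attractive cavity, two-ended rod guests,
gel/water/guest frames with known interior-water and captured-guest counts,
factorial response tables with known coefficients, and biphasic
(burst + zero-order) release curves.  The generators emulate the *logic* of
the real systems — cavity geometry, category counts, design structure — not
their thermodynamics; all are deterministic under a fixed seed and verify
their own ground truth by brute-force distance checks before returning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .release_stats import DesignTable, Factor
from .screening import CavityFrame
from .structures import Molecule
from .trajectory import Frame, Trajectory, fibonacci_sphere

__all__ = [
    "ToyHostSpec", "SyntheticTrajectorySpec", "FactorialSpec",
    "make_toy_host", "make_rod_guest", "make_trajectory",
    "make_factorial_table", "make_release_curve", "make_guest_stub",
]


@dataclass
class ToyHostSpec:
    """A ring of Lennard-Jones sites with an open central cavity."""

    rim_radius: float = 5.0
    n_rim_atoms: int = 12
    atom_radius: float = 1.7
    sigma: float = 3.4
    epsilon: float = 0.25
    axial_thickness: float = 0.0   # > 0 adds a second rim offset axially

    def __post_init__(self):
        if self.n_rim_atoms < 6:
            raise ValueError("need at least 6 rim atoms")
        if self.rim_radius <= self.atom_radius:
            raise ValueError("cavity closed: rim_radius must exceed atom radius")


def make_toy_host(spec: ToyHostSpec = ToyHostSpec()) -> tuple[Molecule, CavityFrame]:
    """Planar ring (or short tube) of LJ sites plus its exact cavity frame."""
    angles = 2 * np.pi * np.arange(spec.n_rim_atoms) / spec.n_rim_atoms
    ring = spec.rim_radius * np.column_stack(
        [np.cos(angles), np.sin(angles), np.zeros_like(angles)])
    if spec.axial_thickness > 0:
        off = np.array([0, 0, spec.axial_thickness / 2.0])
        coords = np.vstack([ring - off, ring + off])
    else:
        coords = ring
    n = len(coords)
    mol = Molecule(["X"] * n, coords, radii=[spec.atom_radius] * n,
                   role_tags=["rim"] * n, name="toy-host")
    frame = CavityFrame(center=np.zeros(3), axis=np.array([0, 0, 1.0]),
                        rim_radius=spec.rim_radius)
    return mol, frame


def make_rod_guest(length: float, n_sites: int | None = None
                   ) -> tuple[Molecule, tuple[list[int], list[int]]]:
    """Linear rod of LJ sites centred at the origin, with end-A/end-B markers.

    Returns (molecule, (end_A indices, end_B indices)); the marker sets are
    the first and last site and are disjoint, which requires at least two
    sites (length ≥ site spacing).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if n_sites is None:
        n_sites = max(2, int(round(length)) + 1)
    if n_sites < 2:
        raise ValueError("a rod needs at least two sites for distinct ends")
    z = np.linspace(-length / 2.0, length / 2.0, n_sites)
    coords = np.column_stack([np.zeros(n_sites), np.zeros(n_sites), z])
    bonds = [(i, i + 1) for i in range(n_sites - 1)]
    mol = Molecule(["X"] * n_sites, coords, bonds=bonds, name="rod-guest")
    return mol, ([0], [n_sites - 1])


def make_guest_stub(seed: int = 0) -> tuple[Molecule, tuple[list[int], list[int]]]:
    """Coarse two-ended corticosteroid-like guest, composition C21H26O5.

    Synthetic stand-in: an elongated heavy-atom cluster with two carbonyl
    oxygens on one end (the dienone end, marker A) and the remaining
    oxygens on the other (the hydroxyl end, marker B).  Only composition,
    size and two-endedness are meaningful; the geometry is schematic.
    """
    rng = np.random.default_rng(seed)
    n_c, n_o, n_h = 21, 5, 26
    # heavy atoms on a 11 Å × 4 Å cylinder
    z = np.linspace(-5.5, 5.5, n_c + n_o)
    ang = rng.uniform(0, 2 * np.pi, n_c + n_o)
    rad = rng.uniform(0.5, 2.0, n_c + n_o)
    heavy = np.column_stack([rad * np.cos(ang), rad * np.sin(ang), z])
    order = np.argsort(z)
    heavy = heavy[order]
    elements = ["O", "O"] + ["C"] * n_c + ["O", "O", "O"]
    positions = list(heavy)
    roles = (["dienone-O"] * 2 + ["C"] * n_c + ["hydroxyl-O"] * 3)
    h_parent = rng.integers(2, 2 + n_c, size=n_h)
    for p in h_parent:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        elements.append("H")
        positions.append(positions[p] + 1.09 * u)
        roles.append("H")
    bonds = [(i, i + 1) for i in range(n_c + n_o - 1)]
    bonds += [(int(p), 2 + n_c + 3 + k) for k, p in enumerate(h_parent)]
    mol = Molecule(elements, positions, role_tags=roles, bonds=bonds,
                   name="guest-stub")
    return mol, ([0, 1], [n_c + 2, n_c + 3, n_c + 4])


@dataclass
class SyntheticTrajectorySpec:
    """Frames around a hollow-shell gel with known category counts."""

    n_frames: int = 5
    n_waters_inside: int = 7
    n_waters_outside: int = 5
    n_guests_captured: int = 12
    n_guests_free: int = 18
    jitter_sigma: float = 0.05
    seed: int = 0
    shell_radius: float = 10.0
    n_gel_atoms: int = 400
    contact: float = 4.5
    water_shell: float = 3.0

    def __post_init__(self):
        if min(self.n_frames, self.n_waters_inside, self.n_waters_outside,
               self.n_guests_captured, self.n_guests_free) < 0:
            raise ValueError("counts must be non-negative")
        if self.jitter_sigma < 0:
            raise ValueError("jitter must be non-negative")


def make_trajectory(spec: SyntheticTrajectorySpec
                    ) -> tuple[Trajectory, dict]:
    """Trajectory with exact interior-water and captured-guest ground truth.

    The gel is a hollow sphere shell dense enough to close the flood-fill
    envelope; waters sit either deep inside the cavity or far outside,
    guests either within the contact distance of the shell or well beyond
    it.  After Gaussian jitter every category is re-verified by brute-force
    distance checks; generation retries (fresh jitter) up to 100 times and
    raises if the jitter is too large to preserve the categories.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.shell_radius
    gel = R * fibonacci_sphere(spec.n_gel_atoms)

    def build_frame(t):
        coords = [gel]
        tags = ["gel"] * spec.n_gel_atoms
        elements = ["C"] * spec.n_gel_atoms
        # waters: oxygens only
        for i in range(spec.n_waters_inside):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords.append((rng.uniform(0, 0.4 * R) * u)[None, :])
            tags.append("water")
            elements.append("O")
        for i in range(spec.n_waters_outside):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords.append(((R + 20.0 + rng.uniform(0, 10)) * u)[None, :])
            tags.append("water")
            elements.append("O")
        gi = 0
        for i in range(spec.n_guests_captured):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords.append(((R + rng.uniform(1.5, spec.contact - 1.0)) * u)[None, :])
            tags.append(f"guest_{gi}")
            elements.append("C")
            gi += 1
        for i in range(spec.n_guests_free):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords.append(((R + spec.contact + 10.0 + rng.uniform(0, 15)) * u)[None, :])
            tags.append(f"guest_{gi}")
            elements.append("C")
            gi += 1
        xyz = np.vstack([np.atleast_2d(c) for c in coords])
        for _ in range(100):
            jit = xyz + rng.normal(0, spec.jitter_sigma, xyz.shape) \
                if spec.jitter_sigma > 0 else xyz.copy()
            if _verify_categories(jit, tags, spec):
                masses = np.array([15.999 if e == "O" else 12.011
                                   for e in elements])
                radii = np.array([1.52 if e == "O" else 1.7 for e in elements])
                return Frame(jit, tags, masses, time=t, radii=radii,
                             elements=elements)
        raise ValueError("jitter too large to preserve category assignments")

    frames = [build_frame(0.1 * k) for k in range(spec.n_frames)]
    truth = {
        "waters_in_gel": spec.n_waters_inside,
        "captured_guests": spec.n_guests_captured,
        "n_guests": spec.n_guests_captured + spec.n_guests_free,
    }
    return Trajectory(frames), truth


def _verify_categories(xyz, tags, spec) -> bool:
    """Brute-force re-check of the intended inside/outside and captured/free labels."""
    gel_idx = [i for i, t in enumerate(tags) if t == "gel"]
    tree = cKDTree(xyz[gel_idx])
    R = spec.shell_radius
    n_win = spec.n_waters_inside
    water_idx = [i for i, t in enumerate(tags) if t == "water"]
    for k, i in enumerate(water_idx):
        r = np.linalg.norm(xyz[i])
        d = tree.query(xyz[i])[0]
        if k < n_win:       # intended inside: clearly interior
            if r > R - 2.0:
                return False
        else:               # intended outside: beyond shell and contact range
            if r < R + spec.water_shell + 2.0 or d <= spec.water_shell:
                return False
    guest_tags = sorted({t for t in tags if t.startswith("guest_")},
                        key=lambda s: int(s.split("_")[1]))
    for k, t in enumerate(guest_tags):
        idx = [i for i, tt in enumerate(tags) if tt == t]
        d = min(tree.query(xyz[i])[0] for i in idx)
        if k < spec.n_guests_captured:
            if d > spec.contact - 0.05:
                return False
        else:
            if d < spec.contact + 0.5:
                return False
    return True


@dataclass
class FactorialSpec:
    """Two-factor response surface y = b0 + b1 A + b2 B + b3 A·B + ε on coded levels."""

    coefficients: tuple = (69.95, 30.66, 0.0, 5.53)
    a_levels: tuple = (0.0, 2.44, 4.76, 9.10)
    b_levels: tuple = (1.0, 8.0, 24.5, 48.0)
    a_range: tuple = (0.0, 9.1)
    b_range: tuple = (1.0, 48.0)
    # (A level, B level, replicates); default mirrors the packaged 20-run design
    layout: tuple = (
        (0.0, 1.0, 2), (0.0, 48.0, 2), (2.44, 8.0, 6),
        (4.76, 24.5, 6), (9.10, 1.0, 2), (9.10, 48.0, 2),
    )
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise must be non-negative")
        if any(rep < 1 for _, _, rep in self.layout):
            raise ValueError("at least one replicate per cell")


def make_factorial_table(spec: FactorialSpec = FactorialSpec()
                         ) -> tuple[DesignTable, dict]:
    """Generate a factorial design table with known true coefficients."""
    import pandas as pd
    from .release_stats import code_factor

    rng = np.random.default_rng(spec.seed)
    b0, b1, b2, b3 = spec.coefficients
    rows_a, rows_b, y = [], [], []
    for a, b, rep in spec.layout:
        ca = code_factor(a, *spec.a_range)
        cb = code_factor(b, *spec.b_range)
        mu = b0 + b1 * ca + b2 * cb + b3 * ca * cb
        for _ in range(rep):
            rows_a.append(a)
            rows_b.append(b)
            y.append(mu + (rng.normal(0, spec.noise_sigma)
                           if spec.noise_sigma > 0 else 0.0))
    design = DesignTable(
        factors=[Factor("A", *spec.a_range), Factor("B", *spec.b_range)],
        natural=pd.DataFrame({"A": rows_a, "B": rows_b}),
        response=np.array(y))
    truth = {"b0": b0, "b1": b1, "b2": b2, "b3": b3,
             "noise_sigma": spec.noise_sigma}
    return design, truth


def make_release_curve(burst_pct: float, slope_pct_per_h: float, times,
                       noise_sigma: float = 0.0, seed: int = 0,
                       burst_window: float = 2.0) -> tuple[np.ndarray, np.ndarray, dict]:
    """Biphasic release curve: saturating burst joined continuously to a line.

    ``y(t) = burst·(1 − e^{−t/τ})/(1 − e^{−t_b/τ})`` for ``t ≤ t_b`` (so the
    curve passes exactly through the burst value at the window edge), then
    ``burst + slope·(t − t_b)``.  The final value may not exceed ~100%.
    Returns (times, percent, truth).
    """
    times = np.asarray(times, dtype=float)
    if burst_pct + slope_pct_per_h * float(times.max() - burst_window) > 102.0:
        raise ValueError("curve would exceed 100% release")
    tau = burst_window / 3.0
    norm = 1.0 - np.exp(-burst_window / tau)
    y = np.where(
        times <= burst_window,
        burst_pct * (1.0 - np.exp(-times / tau)) / norm,
        burst_pct + slope_pct_per_h * (times - burst_window))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0, noise_sigma, y.shape)
    truth = {"burst_pct": burst_pct, "slope_pct_per_h": slope_pct_per_h,
             "burst_window_h": burst_window}
    return times, np.asarray(y), truth
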