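"""Rigid-body host-guest screening.

Samples guest orientations around a host (uniform rotations, uniform shell
translations), evaluates the supermolecular interaction energy for every
pose, summarizes the ensemble (mean, standard error, lowest-k subset), and
classifies which end of a two-ended guest enters the host cavity — the
geometric analogue of the A/B inclusion modes of cyclodextrin complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import EnergyModel, interaction_energy
from .structures import Molecule

__all__ = [
    "Pose", "ComplexEnsemble", "CavityFrame", "ScreenSummary",
    "sample_orientations", "screen", "classify_inclusion", "rank_candidates",
]


@dataclass
class Pose:
    """A rigid placement: unit quaternion (w, x, y, z) + translation (Å).

    The translation is the guest-centroid offset from the host centroid.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.norm(self.rotation) - 1.0) > 1e-12:
            raise ValueError("quaternion must be normalized to 1e-12")

    def matrix(self) -> np.ndarray:
        w, x, y, z = self.rotation
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ])

    def apply(self, guest: Molecule, host_centroid) -> Molecule:
        """Rotate the guest about its centroid and place it at host centroid + translation."""
        c = guest.centroid()
        coords = (guest.positions - c) @ self.matrix().T
        coords = coords + np.asarray(host_centroid) + self.translation
        out = guest.copy()
        out.positions = coords
        return out


@dataclass
class CavityFrame:
    """Host cavity geometry: center, secondary→primary unit axis, rim radius (Å)."""

    center: np.ndarray
    axis: np.ndarray
    rim_radius: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            raise ValueError("degenerate (zero) cavity axis")
        self.axis = axis / norm
        if self.rim_radius <= 0:
            raise ValueError("rim_radius must be positive")

    def depth_radial(self, coords):
        """Signed axial depth and in-plane radial distance of coordinates."""
        rel = np.atleast_2d(coords) - self.center
        depth = rel @ self.axis
        radial = np.linalg.norm(rel - np.outer(depth, self.axis), axis=1)
        return depth, radial


@dataclass
class ComplexEnsemble:
    host: Molecule
    guest: Molecule
    poses: list[Pose]
    energies: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.poses) != len(self.energies):
            raise ValueError("poses and energies must have equal length")
        if self.labels is not None and len(self.labels) != len(self.poses):
            raise ValueError("labels length mismatch")
        if len(self.energies) and not np.all(np.isfinite(self.energies)):
            raise ValueError("non-finite pose energies")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (p, e) in enumerate(zip(self.poses, self.energies)):
            rows.append({
                "pose": i,
                "qw": p.rotation[0], "qx": p.rotation[1],
                "qy": p.rotation[2], "qz": p.rotation[3],
                "tx": p.translation[0], "ty": p.translation[1],
                "tz": p.translation[2],
                "delta_e_kcal_mol": e,
                "label": self.labels[i] if self.labels else "",
            })
        return pd.DataFrame(rows)


@dataclass
class ScreenSummary:
    """Ensemble statistics plus the lowest-k subset (indices sorted ascending by ΔE)."""

    ensemble: ComplexEnsemble
    mean: float
    se: float
    lowest_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def lowest_energies(self):
        return self.ensemble.energies[self.lowest_indices]

    @property
    def lowest_poses(self):
        return [self.ensemble.poses[i] for i in self.lowest_indices]


def _radius(mol: Molecule) -> float:
    rel = mol.positions - mol.centroid()
    return float(np.linalg.norm(rel, axis=1).max()) if len(mol) else 0.0


def sample_orientations(host: Molecule, guest: Molecule, n: int,
                        shell: tuple[float, float] | None = None,
                        seed: int = 0) -> list[Pose]:
    """Draw ``n`` poses: uniform rotations, translations uniform in a spherical shell.

    Rotations come from the normalized-Gaussian quaternion construction
    (uniform on SO(3)).  Translations are uniform by volume over the shell
    ``[r_min, r_max]`` around the host centroid, measured
    centroid-to-centroid.  The default shell reaches from 0 to
    host radius + guest radius + 5 Å.  Deterministic given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if shell is None:
        shell = (0.0, _radius(host) + _radius(guest) + 5.0)
    r_min, r_max = shell
    if r_min < 0 or r_max < r_min:
        raise ValueError(f"invalid shell ({r_min}, {r_max})")
    rng = np.random.default_rng(seed)
    poses = []
    for _ in range(n):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = (rng.uniform(r_min ** 3, r_max ** 3)) ** (1.0 / 3.0)
        poses.append(Pose(q, r * u))
    return poses


def _pose_energies(host, guest, model, poses, chunk=2048):
    """Vectorized inter-fragment ΔE when the model exposes a pair matrix; else per-pose Eq.-(1)."""
    if not hasattr(model, "pair_energy_matrix"):
        c = host.centroid()
        return np.array([interaction_energy(host, p.apply(guest, c), model)
                         for p in poses])
    sa, ea, qa = model.atom_params(host)
    sb, eb, qb = model.atom_params(guest)
    gc = guest.positions - guest.centroid()
    hc = host.centroid()
    energies = np.empty(len(poses))
    for start in range(0, len(poses), chunk):
        batch = poses[start:start + chunk]
        mats = np.stack([p.matrix() for p in batch])          # (B,3,3)
        trans = np.stack([p.translation for p in batch])      # (B,3)
        coords = np.einsum("bij,nj->bni", mats, gc) + (hc + trans)[:, None, :]
        em = model.pair_energy_matrix(host.positions, sa, ea, qa,
                                      coords, sb, eb, qb)
        energies[start:start + len(batch)] = em.sum(axis=(-1, -2))
    if not np.all(np.isfinite(energies)):
        raise ArithmeticError("non-finite pose energy encountered")
    return energies


def screen(host: Molecule, guest: Molecule, model: EnergyModel, n: int,
           k: int, seed: int = 0, shell=None) -> ScreenSummary:
    """Screen ``n`` random rigid poses and keep the ``k`` lowest-energy ones.

    Returns the ensemble mean ΔE and its standard error over all ``n``
    poses, plus the lowest-``k`` subset sorted ascending by ΔE (ties broken
    stably by pose index).
    """
    if n < k or k < 0:
        raise ValueError("need n >= k >= 0")
    poses = sample_orientations(host, guest, n, shell=shell, seed=seed)
    energies = _pose_energies(host, guest, model, poses)
    if n == 0:
        return ScreenSummary(ComplexEnsemble(host, guest, [], np.array([])),
                             float("nan"), float("nan"))
    mean = float(energies.mean())
    se = float(energies.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    order = np.argsort(energies, kind="stable")
    return ScreenSummary(ComplexEnsemble(host, guest, poses, energies),
                         mean, se, order[:k])


def classify_inclusion(host_frame: CavityFrame, guest_posed: Molecule,
                       markers: tuple, axial_extent: float = 4.0) -> str:
    """Label a posed guest ``"A"``, ``"B"`` or ``"none"`` against a cavity cylinder.

    ``"none"`` if no guest atom projects inside the cylinder of radius
    ``rim_radius`` and axial half-extent ``axial_extent`` about the cavity
    center; otherwise ``"A"`` when the end-A marker centroid sits deeper
    along the secondary→primary axis than the end-B centroid, ``"B"``
    otherwise.
    """
    end_a, end_b = markers
    if not len(end_a) or not len(end_b):
        raise ValueError("marker sets must be non-empty")
    if set(end_a) & set(end_b):
        raise ValueError("marker sets must be disjoint")
    depth, radial = host_frame.depth_radial(guest_posed.positions)
    inside = (np.abs(depth) <= axial_extent) & (radial <= host_frame.rim_radius)
    if not np.any(inside):
        return "none"
    depth_a = float(np.mean(depth[list(end_a)]))
    depth_b = float(np.mean(depth[list(end_b)]))
    return "A" if depth_a > depth_b else "B"


def cavity_frame_from_host(host: Molecule) -> CavityFrame:
    """Derive the cavity frame of a cyclodextrin-like host from its role tags.

    Center: centroid of the glycosidic oxygens; axis: normal of their ring
    plane (smallest principal direction), oriented secondary→primary so the
    wider secondary-hydroxyl rim sits at negative depth; rim radius: mean
    in-plane distance of the glycosidic oxygens from the center.
    """
    gly = [i for i, r in enumerate(host.role_tags) if r == "glycosidic-O"]
    if not gly:
        raise ValueError("host has no atoms tagged 'glycosidic-O'")
    pts = host.positions[gly]
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    axis = vt[-1]
    sec = [i for i, r in enumerate(host.role_tags) if r == "secondary-OH-O"]
    if sec:
        depth_sec = float(np.mean((host.positions[sec] - center) @ axis))
        if depth_sec > 0:
            axis = -axis
    depth = (pts - center) @ axis
    radial = np.linalg.norm((pts - center) - np.outer(depth, axis), axis=1)
    return CavityFrame(center, axis, float(radial.mean()))


def rank_candidates(conjugates, host: Molecule, model: EnergyModel,
                    n: int, seed: int = 0, shell=None) -> pd.DataFrame:
    """Screen each named candidate against the host and rank by mean ΔE.

    All candidates are screened with identical ``n``, model and seed policy
    (same seed, hence shared random streams).  Returns a table with columns
    ``id``, ``hydrogel``, ``mean_delta_e``, ``se`` sorted ascending by mean
    ΔE (best binder first).
    """
    conjugates = list(conjugates)
    if not conjugates:
        raise ValueError("empty candidate list")
    rows = []
    for name, mol in conjugates:
        s = screen(host, mol, model, n=n, k=0, seed=seed, shell=shell)
        rows.append({"hydrogel": name, "mean_delta_e": s.mean, "se": s.se})
    df = pd.DataFrame(rows).sort_values(
        "mean_delta_e", kind="stable").reset_index(drop=True)
    df.insert(0, "id", np.arange(1, len(df) + 1))
    return df
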