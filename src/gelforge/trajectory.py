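"""Structural observables over coordinate frames.

A :class:`Frame` is a tagged point cloud (gel / water / guest_i components)
with masses and optional per-atom radii; a :class:`Trajectory` is a
time-ordered list of frames with consistent atom ordering.  Observables:
mass-weighted radius of gyration, Shrake-Rupley solvent-accessible surface
area on a deterministic Fibonacci point lattice, water-in-gel counting with
a flood-fill interior envelope, guest capture by contact distance, and
geometric hydrogen bonds.  Frames are treated as whole molecules in free
space; periodic images must be resolved upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "Frame", "Trajectory", "ObservableSeries",
    "radius_of_gyration", "sasa", "count_waters_in_gel",
    "count_captured_guests", "count_hbonds", "series", "block_average",
]


@dataclass
class Frame:
    """One snapshot: coordinates (Å), component tags, masses (amu), time (ns)."""

    coordinates: np.ndarray
    identities: list[str]
    masses: np.ndarray
    time: float = 0.0
    radii: np.ndarray | None = None
    elements: list[str] | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.coordinates)
        if not (len(self.identities) == len(self.masses) == n):
            raise ValueError("per-atom array lengths disagree")
        if any(not t for t in self.identities):
            raise ValueError("identity tags must partition the atoms (no empty tags)")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if len(self.radii) != n:
                raise ValueError("radii length mismatch")

    def select(self, tag: str) -> np.ndarray:
        """Indices whose identity equals ``tag`` or starts with ``tag`` + separator."""
        return np.array([i for i, t in enumerate(self.identities)
                         if t == tag or t.startswith(tag + "_")], dtype=int)

    def guest_groups(self) -> dict[str, np.ndarray]:
        groups: dict[str, list[int]] = {}
        for i, t in enumerate(self.identities):
            if t.startswith("guest"):
                groups.setdefault(t, []).append(i)
        return {k: np.array(v, dtype=int) for k, v in groups.items()}


@dataclass
class Trajectory:
    frames: list[Frame]

    def __post_init__(self):
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        n0 = {len(f.coordinates) for f in self.frames}
        if len(n0) > 1:
            raise ValueError("inconsistent atom counts across frames")

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class ObservableSeries:
    times: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")


# ---------------------------------------------------------------------------


def radius_of_gyration(frame: Frame, selection) -> float:
    """Mass-weighted radius of gyration about the mass-weighted centroid, Å."""
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    m = frame.masses[idx]
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    r = frame.coordinates[idx]
    com = (m[:, None] * r).sum(axis=0) / m.sum()
    return float(np.sqrt((m * np.sum((r - com) ** 2, axis=1)).sum() / m.sum()))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(frame: Frame, selection, probe: float = 1.4, n_points: int = 960) -> float:
    """Shrake-Rupley solvent-accessible surface area of the selection, Å².

    Each selected atom's sphere of radius ``r + probe`` is sampled at
    ``n_points`` deterministic spiral-lattice points; points occluded by any
    other selected atom's inflated sphere are removed; the atom contributes
    its accessible fraction times 4π(r+probe)².
    """
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    if frame.radii is None:
        missing = frame.elements[idx[0]] if frame.elements else "<unknown>"
        raise ValueError(f"no van der Waals radius available (element {missing})")
    coords = frame.coordinates[idx]
    radii = frame.radii[idx] + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    total = 0.0
    r_max = radii.max()
    for a in range(len(idx)):
        pts = coords[a] + radii[a] * sphere
        neigh = [b for b in tree.query_ball_point(coords[a], radii[a] + r_max)
                 if b != a]
        if neigh:
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=-1)
            buried = np.any(d2 < (radii[neigh] ** 2)[None, :] - 1e-12, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        total += frac * 4.0 * np.pi * radii[a] ** 2
    return float(total)


def _interior_cells(gel_coords, cell: float, gel_radii=None):
    """Grid occupancy and interior mask for the gel envelope.

    Cells (edge ``cell`` Å) overlapping any gel atom *sphere* (center ±
    van der Waals radius, axis-aligned box approximation) are blocked; free
    cells reachable from the padded boundary by 6-connected flood fill are
    exterior; the rest are interior.  Sphere occupancy rather than
    center-point occupancy keeps the envelope closed independent of how the
    grid happens to align with a thin gel wall.
    Returns (origin, occupied mask, interior mask).
    """
    if gel_radii is None:
        gel_radii = np.zeros(len(gel_coords))
    lo = gel_coords.min(axis=0) - cell - gel_radii.max()
    hi = gel_coords.max(axis=0) + cell + gel_radii.max()
    shape = np.maximum(1, np.ceil((hi - lo) / cell).astype(int))
    occupied = np.zeros(shape, dtype=bool)
    ij_lo = np.clip(((gel_coords - gel_radii[:, None] - lo) / cell).astype(int),
                    0, shape - 1)
    ij_hi = np.clip(((gel_coords + gel_radii[:, None] - lo) / cell).astype(int),
                    0, shape - 1)
    spans = np.unique(np.hstack([ij_lo, ij_hi]), axis=0)
    for (x0, y0, z0), (x1, y1, z1) in zip(
            spans[:, :3], spans[:, 3:]):
        occupied[x0:x1 + 1, y0:y1 + 1, z0:z1 + 1] = True
    # flood fill from the boundary through free cells
    free = ~occupied
    seed = np.zeros(shape, dtype=bool)
    seed[0, :, :] = seed[-1, :, :] = True
    seed[:, 0, :] = seed[:, -1, :] = True
    seed[:, :, 0] = seed[:, :, -1] = True
    seed &= free
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    exterior = ndimage.binary_propagation(seed, mask=free, structure=struct)
    interior = free & ~exterior
    return lo, occupied, interior


def count_waters_in_gel(frame: Frame, shell: float = 3.0, cell: float = 2.0) -> int:
    """Waters (by oxygen position) within ``shell`` Å of the gel or inside its envelope.

    The envelope is the set of grid cells (edge ``cell`` Å) not reachable
    from the box boundary by 6-connected flood fill through gel-free cells.
    """
    gel = frame.select("gel")
    if gel.size == 0:
        raise ValueError("frame contains no gel atoms")
    water = frame.select("water")
    if frame.elements is not None:
        water = np.array([i for i in water if frame.elements[i] == "O"], dtype=int)
    if water.size == 0:
        return 0
    gel_xyz = frame.coordinates[gel]
    w_xyz = frame.coordinates[water]
    d, _ = cKDTree(gel_xyz).query(w_xyz, k=1)
    near = d <= shell
    gel_radii = frame.radii[gel] if frame.radii is not None else None
    lo, occupied, interior = _interior_cells(gel_xyz, cell, gel_radii)
    ijk = ((w_xyz - lo) / cell).astype(int)
    in_grid = np.all((ijk >= 0) & (ijk < np.array(occupied.shape)), axis=1)
    inside = np.zeros(len(water), dtype=bool)
    ok = np.where(in_grid)[0]
    inside[ok] = (interior | occupied)[ijk[ok, 0], ijk[ok, 1], ijk[ok, 2]]
    return int(np.count_nonzero(near | inside))


def _captured_mask(frame: Frame, contact: float):
    gel = frame.select("gel")
    groups = frame.guest_groups()
    if gel.size == 0 or not groups:
        return {}, {}
    tree = cKDTree(frame.coordinates[gel])
    mask = {}
    for tag, idx in groups.items():
        d, _ = tree.query(frame.coordinates[idx], k=1)
        mask[tag] = bool(np.min(d) <= contact)
    return mask, groups


def count_captured_guests(frame_or_traj, contact: float = 4.5,
                          persistence: int = 1):
    """Guests with any atom within ``contact`` Å of any gel atom.

    On a single :class:`Frame` (persistence 1) returns the captured count.
    On a :class:`Trajectory`, a guest counts as captured in a frame only if
    the contact held for ``persistence`` consecutive frames ending there;
    returns the per-frame array of counts.
    """
    if isinstance(frame_or_traj, Frame):
        mask, _ = _captured_mask(frame_or_traj, contact)
        return int(sum(mask.values()))
    traj = frame_or_traj
    per_frame = []
    for f in traj:
        mask, _ = _captured_mask(f, contact)
        per_frame.append(mask)
    tags = sorted({t for m in per_frame for t in m})
    counts = np.zeros(len(traj), dtype=int)
    for ti, t in enumerate(tags):
        run = 0
        for fi, m in enumerate(per_frame):
            run = run + 1 if m.get(t, False) else 0
            if run >= persistence:
                counts[fi] += 1
    return counts


def count_hbonds(frame: Frame, donors, acceptors, d_max: float = 3.5,
                 angle_min: float = 150.0) -> int:
    """Geometric hydrogen bonds D-H···A across different components.

    Criteria: donor-acceptor distance ≤ ``d_max`` Å and D-H···A angle at the
    hydrogen ≥ ``angle_min`` degrees; donor and acceptor must carry
    different identity tags.
    """
    coords = frame.coordinates
    count = 0
    acceptors = list(acceptors)
    for pair in donors:
        if len(pair) != 2 or pair[1] is None:
            raise ValueError(f"donor {pair!r} lacks an explicit hydrogen")
        d_idx, h_idx = pair
        for a_idx in acceptors:
            if frame.identities[a_idx] == frame.identities[d_idx]:
                continue
            if np.linalg.norm(coords[a_idx] - coords[d_idx]) > d_max:
                continue
            v1 = coords[d_idx] - coords[h_idx]
            v2 = coords[a_idx] - coords[h_idx]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang >= angle_min:
                count += 1
    return count


_OBSERVABLES = {
    "rgyr": lambda f, p: radius_of_gyration(f, p.get("selection", f.select("gel"))),
    "sasa": lambda f, p: sasa(f, p.get("selection", f.select("gel")),
                              probe=p.get("probe", 1.4),
                              n_points=p.get("n_points", 960)),
    "waters_in_gel": lambda f, p: count_waters_in_gel(
        f, shell=p.get("shell", 3.0), cell=p.get("cell", 2.0)),
    "captured_guests": lambda f, p: count_captured_guests(
        f, contact=p.get("contact", 4.5)),
    "hbonds": lambda f, p: count_hbonds(
        f, p["donors"], p["acceptors"],
        d_max=p.get("d_max", 3.5), angle_min=p.get("angle_min", 150.0)),
}


def series(trajectory: Trajectory, observable: str, params=None) -> ObservableSeries:
    """Evaluate a named observable on every frame, in frame order."""
    if observable not in _OBSERVABLES:
        raise ValueError(f"unknown observable {observable!r}; "
                         f"known: {sorted(_OBSERVABLES)}")
    if len(trajectory) < 1:
        raise ValueError("trajectory must contain at least one frame")
    params = params or {}
    fn = _OBSERVABLES[observable]
    times = np.array([f.time for f in trajectory])
    values = np.array([fn(f, params) for f in trajectory], dtype=float)
    return ObservableSeries(times, values, observable)


def block_average(s: ObservableSeries, n_blocks: int):
    """(mean, SE) from contiguous equal blocks; the remainder joins the last block."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    v = s.values
    if n_blocks > len(v):
        raise ValueError("more blocks than samples")
    size = len(v) // n_blocks
    means = [v[i * size: (i + 1) * size].mean() for i in range(n_blocks - 1)]
    means.append(v[(n_blocks - 1) * size:].mean())
    means = np.array(means)
    mean = float(means.mean())
    se = float(means.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else 0.0
    return mean, se
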