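"""Crosslinked hydrogel construction.

Builds the polymer matrix the way the wet chemistry does, step by step:
pack PVA chains into an orthorhombic box, esterify pairs of hydroxyls on
different chains with succinate diester bridges by cyclic iteration until
the stoichiometric target (10 PVA monomers : 2 SA by default), graft
cyclodextrins onto pendant succinate anchors, and scatter guest molecules
around the network.  All geometry is idealized; a short steepest-descent
relaxation with harmonic bond/angle restraints relieves steric clashes
around each new bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .energy import EnergyModel, LJCoulombModel
from .errors import CapacityError, CrosslinkShortfallError, PlacementError
from .structures import (Molecule, PolymerChain, SimulationBox,
                         build_pva_chain, molar_mass, random_pack)

__all__ = [
    "CrosslinkBond", "CDGraft", "HydrogelModel", "BuilderConfig",
    "target_crosslink_count", "build_matrix", "local_relax",
    "graft_cyclodextrins", "place_guests", "build_hydrogel",
    "make_gamma_cyclodextrin", "WATER_MASS",
]

WATER_MASS = molar_mass("H2O")  # 18.015 g/mol, lost per ester bond formed

# idealized bridge bond lengths, Å
_ESTER_CO = 1.36
_CARBONYL_CO = 1.21
_CC = 1.52
_CH = 1.09


@dataclass
class CrosslinkBond:
    """A succinate diester bridge between hydroxyl sites of two different chains.

    ``site_a``/``site_b`` are hydroxyl-site ordinals (0..monomer_count-1),
    stable under atom deletions in the parent chain.
    """

    chain_a: int
    site_a: int
    chain_b: int
    site_b: int
    bridge: Molecule
    formation_distance: float

    def __post_init__(self):
        if self.chain_a == self.chain_b:
            raise ValueError("crosslink must join two different chains")


@dataclass
class CDGraft:
    """A cyclodextrin ester-anchored through a pendant succinate to one chain site."""

    chain: int
    site: int
    anchor: Molecule       # pendant succinate fragment
    cd: Molecule           # cyclodextrin (primary-face OH hydrogen removed)
    cd_anchor_atom: int    # index of the anchoring primary-face oxygen in cd


@dataclass
class HydrogelModel:
    chains: list[PolymerChain]
    crosslinks: list[CrosslinkBond] = field(default_factory=list)
    grafted_cds: list[CDGraft] = field(default_factory=list)
    guests: list[Molecule] = field(default_factory=list)
    box: SimulationBox = None
    used_sites: set = field(default_factory=set)

    # -- bookkeeping -------------------------------------------------------

    @property
    def monomer_count(self) -> int:
        return sum(c.monomer_count for c in self.chains)

    @property
    def sa_count(self) -> int:
        return len(self.crosslinks) + len(self.grafted_cds)

    @property
    def ester_bond_count(self) -> int:
        # two esters per bridge, two per graft (chain anchor + CD anchor)
        return 2 * len(self.crosslinks) + 2 * len(self.grafted_cds)

    def gel_molecules(self):
        mols = [c.molecule for c in self.chains]
        mols += [x.bridge for x in self.crosslinks]
        for g in self.grafted_cds:
            mols += [g.anchor, g.cd]
        return mols

    def gel_coordinates(self) -> np.ndarray:
        return np.vstack([m.positions for m in self.gel_molecules()])

    def total_mass(self) -> float:
        mass = sum(molar_mass(m.formula()) for m in self.gel_molecules())
        return float(mass)

    def composition(self) -> dict:
        total = self.total_mass()
        cd_mass = sum(molar_mass(g.cd.formula()) for g in self.grafted_cds)
        consumed = 2 * len(self.crosslinks) + len(self.grafted_cds)
        total_sites = sum(len(c.hydroxyl_sites) for c in self.chains)
        return {
            "monomer_count": self.monomer_count,
            "sa_count": self.sa_count,
            "crosslink_count": len(self.crosslinks),
            "cd_count": len(self.grafted_cds),
            "guest_count": len(self.guests),
            "ester_bond_count": self.ester_bond_count,
            "cd_mass_fraction": cd_mass / total if total else 0.0,
            "molar_mass_g_mol": total,
            "consumed_hydroxyl_sites": consumed,
            "free_hydroxyl_sites": total_sites - consumed,
        }


@dataclass
class BuilderConfig:
    """Default construction parameters of the reference hydrogel systems."""

    n_chains: int = 56
    chain_length: int = 35
    box_lengths: tuple = (90.0, 80.0, 100.0)
    min_separation: float = 5.0
    crosslink_cutoff: float = 10.0
    pva_sa_ratio: tuple = (10, 2)
    n_cd: int = 0
    n_guests: int = 30
    guest_min_distance: float = 10.0
    guest_box_margin: float = 35.0
    seed: int = 0
    pack_attempts: int = 10_000
    place_attempts: int = 10_000
    max_stall: int = 10_000
    relax_steps: int = 25
    relax_radius: float = 6.0

    def __post_init__(self):
        if min(self.n_chains, self.chain_length, self.n_cd, self.n_guests) < 0:
            raise ValueError("counts must be non-negative")
        if min(self.pva_sa_ratio) <= 0:
            raise ValueError("ratio parts must be positive")


def target_crosslink_count(n_monomers: int, ratio=(10, 2)) -> int:
    """Number of SA crosslinkers for ``n_monomers`` at a PVA:SA monomer ratio.

    ``round(n_monomers * sa_parts / pva_parts)``: 1960 monomers at 10:2
    give 392.
    """
    pva_parts, sa_parts = ratio
    if pva_parts <= 0 or sa_parts <= 0:
        raise ValueError("ratio parts must be positive")
    if n_monomers < 0:
        raise ValueError("n_monomers must be >= 0")
    return int(round(n_monomers * sa_parts / pva_parts))


# ---------------------------------------------------------------------------
# steepest-descent relaxation


def _angle_terms(bonds, n_atoms):
    """All (i, j, k) triples centred on j implied by a bond list."""
    neigh = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        neigh[i].append(j)
        neigh[j].append(i)
    triples = []
    for j in range(n_atoms):
        nb = neigh[j]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                triples.append((nb[a], j, nb[b]))
    return triples


def _restraint_energy_gradient(coords, bonds, r0, angles, theta0,
                               bond_k, angle_k):
    e = 0.0
    grad = np.zeros_like(coords)
    if bonds:
        bi = np.array([b[0] for b in bonds])
        bj = np.array([b[1] for b in bonds])
        d = coords[bi] - coords[bj]
        r = np.linalg.norm(d, axis=1)
        dr = r - r0
        e += float(bond_k * np.sum(dr ** 2))
        g = (2.0 * bond_k * dr / np.maximum(r, 1e-12))[:, None] * d
        np.add.at(grad, bi, g)
        np.add.at(grad, bj, -g)
    for (i, j, k), t0 in zip(angles, theta0):
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            continue
        c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
        s = np.sqrt(max(1.0 - c * c, 1e-12))
        theta = np.arccos(c)
        e += angle_k * (theta - t0) ** 2
        pref = -2.0 * angle_k * (theta - t0) / s
        dci = (v / (nu * nv)) - c * u / (nu * nu)
        dck = (u / (nu * nv)) - c * v / (nv * nv)
        grad[i] += pref * dci
        grad[k] += pref * dck
        grad[j] -= pref * (dci + dck)
    return e, grad


def _relax_arrays(coords, movable, sig, eps, q, model, bonds, r0,
                  angles, theta0, max_steps, step_size, grad_tol,
                  bond_k, angle_k, exclude_pairs):
    coords = coords.copy()
    if max_steps <= 0:
        return coords

    def eg(x):
        e_nb, g_nb = model.nonbonded_energy_gradient(x, sig, eps, q,
                                                     exclude_pairs=exclude_pairs)
        e_r, g_r = _restraint_energy_gradient(x, bonds, r0, angles, theta0,
                                              bond_k, angle_k)
        g = g_nb + g_r
        g[~movable] = 0.0
        return e_nb + e_r, g

    energy, grad = eg(coords)
    if not np.isfinite(energy) or not np.all(np.isfinite(grad)):
        raise ArithmeticError("non-finite energy/gradient at relaxation start")
    alpha = step_size
    for _ in range(max_steps):
        gmax = float(np.abs(grad).max()) if grad.size else 0.0
        if gmax < grad_tol:
            break
        step = grad * (alpha / max(gmax, 1e-12))
        accepted = False
        for _ in range(12):
            trial = coords - step
            e_t, g_t = eg(trial)
            if np.isfinite(e_t) and e_t <= energy:
                coords, energy, grad = trial, e_t, g_t
                alpha = min(alpha * 1.2, 10 * step_size)
                accepted = True
                break
            step *= 0.5
            alpha *= 0.5
        if not accepted:
            break
    return coords


def local_relax(molecule: Molecule, model: EnergyModel | None = None,
                max_steps: int = 200, step_size: float = 0.02,
                grad_tol: float = 1e-3, movable=None,
                bond_k: float = 300.0, angle_k: float = 50.0) -> Molecule:
    """Steepest-descent relaxation of a molecular region.

    Minimizes the model's non-bonded energy (bonded and 1-3 pairs excluded)
    plus harmonic restraints holding bonds and angles at their starting
    values.  The energy is non-increasing across accepted steps; terminates
    at ``max_steps`` or when the gradient infinity-norm drops below
    ``grad_tol`` kcal/mol/Å.  ``max_steps=0`` returns the input unchanged.
    """
    model = model or LJCoulombModel()
    sig, eps, q = model.atom_params(molecule)
    coords = molecule.positions
    bonds = list(molecule.bonds)
    r0 = np.array([np.linalg.norm(coords[i] - coords[j]) for i, j in bonds])
    angles = _angle_terms(bonds, len(molecule))
    theta0 = []
    for i, j, k in angles:
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        c = np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)),
                    -1, 1)
        theta0.append(float(np.arccos(c)))
    exclude = set(tuple(sorted(b)) for b in bonds)
    exclude |= {tuple(sorted((i, k))) for i, j, k in angles}
    mov = np.ones(len(molecule), dtype=bool) if movable is None else \
        np.asarray(movable, dtype=bool)
    out = molecule.copy()
    out.positions = _relax_arrays(coords, mov, sig, eps, q, model,
                                  bonds, r0, angles, theta0,
                                  max_steps, step_size, grad_tol,
                                  bond_k, angle_k, exclude)
    return out


# ---------------------------------------------------------------------------
# bridge geometry


def _perp_basis(u):
    a = np.array([1.0, 0, 0]) if abs(u[0]) < 0.9 else np.array([0, 1.0, 0])
    p = np.cross(u, a)
    p /= np.linalg.norm(p)
    return p, np.cross(u, p)


def _succinate_fragment(o_a, o_b, name="SA-bridge") -> tuple[Molecule, int, int]:
    """Succinate diester fragment spanning two ester oxygens.

    Returns (fragment, index of C1 bonded to ``o_a``, index of C4 bonded to
    ``o_b``).  The fragment is ``-C(=O)-CH2-CH2-C(=O)-``: C4H4O2, the
    residue succinic acid leaves after forming two ester bonds.
    """
    o_a, o_b = np.asarray(o_a, float), np.asarray(o_b, float)
    d = o_b - o_a
    dist = np.linalg.norm(d)
    u = d / dist
    p, w = _perp_basis(u)
    c = [o_a + d * f for f in (0.2, 0.4, 0.6, 0.8)]
    zig = [0.45 * p * (1 if i % 2 else -1) for i in range(4)]
    c = [ci + zi for ci, zi in zip(c, zig)]
    elements = ["C", "O", "C", "H", "H", "C", "H", "H", "C", "O"]
    positions = [
        c[0], c[0] + _CARBONYL_CO * w,
        c[1], c[1] + _CH * w, c[1] - _CH * w,
        c[2], c[2] + _CH * w, c[2] - _CH * w,
        c[3], c[3] + _CARBONYL_CO * w,
    ]
    roles = ["carbonyl-C", "carbonyl-O", "CH2", "H", "H",
             "CH2", "H", "H", "carbonyl-C", "carbonyl-O"]
    bonds = [(0, 1), (0, 2), (2, 3), (2, 4), (2, 5),
             (5, 6), (5, 7), (5, 8), (8, 9)]
    frag = Molecule(elements, positions, role_tags=roles, bonds=bonds, name=name)
    return frag, 0, 8


def _site_oxygen(chain: PolymerChain, site: int) -> int:
    return chain.hydroxyl_sites[site]


def _delete_hydroxyl_h(chain: PolymerChain, site: int):
    """Remove the hydrogen of the hydroxyl at ``site`` (ester formation)."""
    mol = chain.molecule
    o_idx = _site_oxygen(chain, site)
    h_idx = None
    for i, j in mol.bonds:
        a, b = (i, j) if mol.elements[j] == "H" else (j, i)
        if a == o_idx and mol.elements[b] == "H":
            h_idx = b
            break
        if b == o_idx and mol.elements[a] == "H":
            h_idx = a
            break
    if h_idx is None:
        raise ValueError(f"hydroxyl at site {site} has no hydrogen (already esterified?)")
    new_mol, imap = mol.remove_atoms([h_idx])
    chain.molecule = new_mol
    chain.hydroxyl_sites = [int(imap[s]) for s in chain.hydroxyl_sites]


# ---------------------------------------------------------------------------
# assembly view for localized relaxation


def _assembly(model: HydrogelModel):
    mols = model.gel_molecules()
    offsets, bonds, n = [], [], 0
    for m in mols:
        offsets.append(n)
        bonds += [(i + n, j + n) for i, j in m.bonds]
        n += len(m)
    coords = np.vstack([m.positions for m in mols]) if mols else np.zeros((0, 3))
    # cross-fragment ester bonds
    nc = len(model.chains)
    for bi, x in enumerate(model.crosslinks):
        frag_off = offsets[nc + bi]
        oa = offsets[x.chain_a] + _site_oxygen(model.chains[x.chain_a], x.site_a)
        ob = offsets[x.chain_b] + _site_oxygen(model.chains[x.chain_b], x.site_b)
        bonds.append((oa, frag_off + 0))
        bonds.append((ob, frag_off + 8))
    base = nc + len(model.crosslinks)
    for gi, g in enumerate(model.grafted_cds):
        a_off = offsets[base + 2 * gi]
        cd_off = offsets[base + 2 * gi + 1]
        oc = offsets[g.chain] + _site_oxygen(model.chains[g.chain], g.site)
        bonds.append((oc, a_off + 0))
        bonds.append((a_off + 8, cd_off + g.cd_anchor_atom))
    return mols, offsets, coords, bonds


def _writeback(model: HydrogelModel, mols, offsets, coords):
    for m, off in zip(mols, offsets):
        m.positions = coords[off: off + len(m)].copy()


def _relax_region(model: HydrogelModel, emodel, center_coords,
                  radius: float, max_steps: int):
    """Relax all gel atoms within ``radius`` of the given coordinates."""
    if max_steps <= 0:
        return
    mols, offsets, coords, bonds = _assembly(model)
    tree = cKDTree(coords)
    region = set()
    for idx in tree.query_ball_point(np.atleast_2d(center_coords), radius):
        region.update(idx)
    region = np.array(sorted(region), dtype=int)
    if region.size == 0:
        return
    # frozen shell: interaction partners of the movable set
    shell = set()
    for idx in tree.query_ball_point(coords[region], 6.0):
        shell.update(idx)
    sub = np.array(sorted(shell), dtype=int)
    remap = {int(g): i for i, g in enumerate(sub)}
    movable = np.zeros(len(sub), dtype=bool)
    movable[[remap[int(g)] for g in region]] = True
    sub_bonds = [(remap[i], remap[j]) for i, j in bonds
                 if i in remap and j in remap]
    sub_coords = coords[sub]
    flat_elements = []
    flat_charges = []
    flat_radii = []
    for m in mols:
        flat_elements += m.elements
        flat_charges.append(m.charges)
        flat_radii.append(m.radii)
    flat_charges = np.concatenate(flat_charges)
    flat_radii = np.concatenate(flat_radii)
    sub_mol = Molecule([flat_elements[i] for i in sub], sub_coords,
                       flat_charges[sub], flat_radii[sub],
                       bonds=sub_bonds)
    relaxed = local_relax(sub_mol, emodel, max_steps=max_steps,
                          movable=movable)
    coords[sub] = relaxed.positions
    _writeback(model, mols, offsets, coords)


# ---------------------------------------------------------------------------
# build operations


def build_matrix(config: BuilderConfig, energy_model: EnergyModel | None = None
                 ) -> HydrogelModel:
    """Pack chains and crosslink them to the stoichiometric SA target.

    Cyclic iteration: uniformly pick an unused hydroxyl pair on distinct
    chains with inter-oxygen distance within the cutoff, insert an idealized
    succinate diester bridge, relax the surroundings, repeat until the
    target from :func:`target_crosslink_count` is met.  If no eligible pair
    remains first, raises :class:`CrosslinkShortfallError` carrying the
    partial model and achieved count.  Deterministic given ``config.seed``.
    """
    emodel = energy_model or LJCoulombModel()
    rng = np.random.default_rng([config.seed, 101])
    chains = [build_pva_chain(config.chain_length, seed=int(s))
              for s in rng.integers(0, 2 ** 31 - 1, size=config.n_chains)]
    box = SimulationBox(np.asarray(config.box_lengths, dtype=float))
    placed = random_pack(chains, box, config.min_separation,
                         seed=config.seed, attempt_budget=config.pack_attempts)
    model = HydrogelModel(chains=placed, box=box)
    target = target_crosslink_count(config.n_chains * config.chain_length,
                                    config.pva_sa_ratio)
    while len(model.crosslinks) < target:
        pair = _draw_eligible_pair(model, config.crosslink_cutoff, rng)
        if pair is None:
            raise CrosslinkShortfallError(
                f"no eligible hydroxyl pair left before target {target}",
                achieved=len(model.crosslinks), model=model)
        (ca, sa_), (cb, sb), dist = pair
        _delete_hydroxyl_h(model.chains[ca], sa_)
        _delete_hydroxyl_h(model.chains[cb], sb)
        o_a = model.chains[ca].molecule.positions[_site_oxygen(model.chains[ca], sa_)]
        o_b = model.chains[cb].molecule.positions[_site_oxygen(model.chains[cb], sb)]
        frag, _, _ = _succinate_fragment(o_a, o_b)
        model.crosslinks.append(CrosslinkBond(ca, sa_, cb, sb, frag, dist))
        model.used_sites.add((ca, sa_))
        model.used_sites.add((cb, sb))
        _relax_region(model, emodel, frag.positions, config.relax_radius,
                      config.relax_steps)
    return model


def _free_site_positions(model: HydrogelModel):
    chain_ids, site_ids, coords = [], [], []
    for ci, chain in enumerate(model.chains):
        for si in range(len(chain.hydroxyl_sites)):
            if (ci, si) in model.used_sites:
                continue
            chain_ids.append(ci)
            site_ids.append(si)
            coords.append(chain.molecule.positions[chain.hydroxyl_sites[si]])
    return (np.array(chain_ids, int), np.array(site_ids, int),
            np.array(coords).reshape(-1, 3))


def _draw_eligible_pair(model: HydrogelModel, cutoff: float, rng):
    """Uniform draw over currently eligible (distinct-chain, within-cutoff) site pairs."""
    chain_ids, site_ids, coords = _free_site_positions(model)
    if len(chain_ids) < 2:
        return None
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return None
    mask = chain_ids[pairs[:, 0]] != chain_ids[pairs[:, 1]]
    pairs = pairs[mask]
    if len(pairs) == 0:
        return None
    i, j = pairs[rng.integers(len(pairs))]
    dist = float(np.linalg.norm(coords[i] - coords[j]))
    return ((int(chain_ids[i]), int(site_ids[i])),
            (int(chain_ids[j]), int(site_ids[j])), dist)


# ---------------------------------------------------------------------------
# cyclodextrin model and grafting


def make_gamma_cyclodextrin(seed: int = 0) -> tuple[Molecule, int]:
    """Coarse idealized γ-cyclodextrin: eight glucopyranoside units on a ring.

    Synthetic stand-in: the composition is exact ((C6H10O5)8 = C48H80O40,
    1297 g/mol) and the toroidal topology is right — glycosidic oxygens on a
    ~6 Å ring, secondary hydroxyls on the wider face (−z), primary hydroxyls
    on the narrower face (+z) — but the intra-unit geometry is schematic,
    not a carbohydrate conformation.  Returns (molecule, number of
    primary-face hydroxyl oxygens).
    """
    ring_r = 6.0
    elements, positions, roles, bonds = [], [], [], []

    def add(el, pos, role):
        elements.append(el)
        positions.append(np.asarray(pos, float))
        roles.append(role)
        return len(elements) - 1

    unit_first_c = []
    for k in range(8):
        ang = 2 * np.pi * k / 8
        center = ring_r * np.array([np.cos(ang), np.sin(ang), 0.0])
        radial = center / np.linalg.norm(center)
        tang = np.array([-radial[1], radial[0], 0.0])
        up = np.array([0.0, 0.0, 1.0])
        # pyranose ring: C1..C5 + ring O on a small hexagon tilted off-plane
        hex_pts = []
        for m in range(6):
            a = 2 * np.pi * m / 6
            hex_pts.append(center + 1.45 * (np.cos(a) * radial + np.sin(a) * (0.7 * tang + 0.7 * up)))
        c_ring = [add("C", hex_pts[m], "ring-C") for m in range(5)]
        o_ring = add("O", hex_pts[5], "ring-O")
        unit_first_c.append(c_ring[0])
        for m in range(4):
            bonds.append((c_ring[m], c_ring[m + 1]))
        bonds.append((c_ring[4], o_ring))
        bonds.append((o_ring, c_ring[0]))
        for m in range(5):
            bonds.append((c_ring[m], add("H", hex_pts[m] + 1.09 * tang, "H")))
        # secondary hydroxyls on C2, C3 → wider (−z) face
        for m in (1, 2):
            o = add("O", hex_pts[m] - 1.43 * up, "secondary-OH-O")
            bonds.append((c_ring[m], o))
            bonds.append((o, add("H", positions[o] - 0.96 * up, "secondary-OH-H")))
        # exocyclic C6 + primary hydroxyl → narrower (+z) face
        c6 = add("C", hex_pts[4] + 1.52 * up, "C6")
        bonds.append((c_ring[4], c6))
        bonds.append((c6, add("H", positions[c6] + 1.09 * tang, "H")))
        bonds.append((c6, add("H", positions[c6] - 1.09 * tang, "H")))
        o6 = add("O", positions[c6] + 1.43 * up, "primary-OH-O")
        bonds.append((c6, o6))
        bonds.append((o6, add("H", positions[o6] + 0.96 * up, "primary-OH-H")))
        # glycosidic oxygen toward the next unit
        next_center = ring_r * np.array([np.cos(2 * np.pi * (k + 1) / 8),
                                         np.sin(2 * np.pi * (k + 1) / 8), 0.0])
        og = add("O", 0.5 * (center + next_center), "glycosidic-O")
        bonds.append((c_ring[0], og))
    # close the macrocycle: glycosidic O of unit k bonds C4 of unit k+1
    for k in range(8):
        og = [i for i, r in enumerate(roles) if r == "glycosidic-O"][k]
        c4_next = unit_first_c[(k + 1) % 8] + 3
        bonds.append((og, c4_next))
    mol = Molecule(elements, positions, role_tags=roles, bonds=bonds,
                   name="gamma-CD")
    n_primary = sum(1 for r in roles if r == "primary-OH-O")
    return mol, n_primary


def graft_cyclodextrins(model: HydrogelModel, n_cd: int, seed: int = 0,
                        cd_factory=make_gamma_cyclodextrin,
                        energy_model: EnergyModel | None = None,
                        clearance: float = 2.0, attempts: int = 200,
                        relax_steps: int = 0) -> HydrogelModel:
    """Ester-anchor ``n_cd`` cyclodextrins to the network via pendant succinates.

    Each graft esterifies one free chain hydroxyl with a fresh succinate
    whose far carboxylate esterifies a primary-face hydroxyl of the CD
    (the CD ring sits on the outward side of the chain, clash-checked
    against the existing gel).  Raises :class:`CapacityError` naming the
    number of reachable free anchors when ``n_cd`` exceeds capacity.
    Deterministic given ``seed``.
    """
    if n_cd == 0:
        return model
    emodel = energy_model or LJCoulombModel()
    rng = np.random.default_rng([seed, 202])
    placed = 0
    tried_sites: set = set()
    while placed < n_cd:
        chain_ids, site_ids, coords = _free_site_positions(model)
        avail = [(c, s, xyz) for c, s, xyz in
                 zip(chain_ids, site_ids, coords) if (c, s) not in tried_sites]
        if not avail:
            raise CapacityError(
                f"cannot graft {n_cd} cyclodextrins", available=placed)
        c, s, o_pos = avail[rng.integers(len(avail))]
        tried_sites.add((int(c), int(s)))
        gel_xyz = model.gel_coordinates()
        tree = cKDTree(gel_xyz)
        ok = False
        for _ in range(attempts):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            anchor_end = o_pos + 6.0 * u
            cd_mol, _ = cd_factory(seed=int(rng.integers(2 ** 31 - 1)))
            prim = [i for i, r in enumerate(cd_mol.role_tags)
                    if r == "primary-OH-O"]
            anchor_o = prim[0]
            # orient the CD so its +z (primary face) points back toward the anchor
            rotmat = _align_z(-u, rng)
            cd_mol = cd_mol.transformed(rotation=rotmat)
            shift = anchor_end - cd_mol.positions[anchor_o]
            cd_mol = cd_mol.transformed(translation=shift)
            d, _i = tree.query(cd_mol.positions, k=1)
            if float(np.min(d)) < clearance:
                continue
            # remove the anchoring hydroxyl's hydrogen (ester formation)
            h_idx = [j for a, j in _bond_partners(cd_mol, anchor_o)
                     if cd_mol.elements[j] == "H"]
            cd_mol, imap = cd_mol.remove_atoms(h_idx[:1])
            anchor_idx = int(imap[anchor_o])
            frag, _, _ = _succinate_fragment(o_pos, cd_mol.positions[anchor_idx],
                                             name="SA-anchor")
            _delete_hydroxyl_h(model.chains[c], s)
            model.grafted_cds.append(
                CDGraft(int(c), int(s), frag, cd_mol, anchor_idx))
            model.used_sites.add((int(c), int(s)))
            if relax_steps > 0:
                _relax_region(model, emodel, frag.positions, 6.0, relax_steps)
            placed += 1
            ok = True
            break
        if not ok:
            continue  # this site had no unclashed placement; try another
    return model


def _bond_partners(mol: Molecule, idx: int):
    out = []
    for i, j in mol.bonds:
        if i == idx:
            out.append((i, j))
        elif j == idx:
            out.append((j, i))
    return out


def _align_z(target, rng):
    """Rotation matrix sending +z to ``target`` (unit)."""
    from scipy.spatial.transform import Rotation as R
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, target)
    s = np.linalg.norm(v)
    c = float(np.dot(z, target))
    if s < 1e-12:
        return np.eye(3) if c > 0 else R.from_rotvec([np.pi, 0, 0]).as_matrix()
    return R.from_rotvec(np.arccos(np.clip(c, -1, 1)) * v / s).as_matrix()


# ---------------------------------------------------------------------------
# guest placement


def place_guests(model: HydrogelModel, guest: Molecule, n_guests: int = 30,
                 min_distance: float = 10.0, seed: int = 0,
                 box_margin: float = 35.0,
                 attempt_budget: int = 10_000) -> HydrogelModel:
    """Scatter rigid guest copies around the network.

    Guests land in the model box expanded by ``box_margin`` on every side
    (mirroring the larger solvent box the network is immersed in), with
    every guest-to-gel and guest-to-guest minimum atom distance at least
    ``min_distance``.  Raises :class:`PlacementError` with the achieved
    count on budget exhaustion.  Deterministic given ``seed``.
    """
    if n_guests == 0:
        return model
    rng = np.random.default_rng([seed, 303])
    margin = np.full(3, float(box_margin))
    lo = model.box.origin - margin
    span = model.box.lengths + 2 * margin
    gel_tree = cKDTree(model.gel_coordinates())
    base = guest.positions - guest.centroid()
    placed_coords = []
    from .structures import _random_rotation
    for g in range(n_guests):
        ok = False
        for _ in range(attempt_budget):
            rot = _random_rotation(rng)
            cand = base @ rot.T + lo + rng.uniform(0, 1, 3) * span
            d, _ = gel_tree.query(cand, k=1)
            if float(np.min(d)) < min_distance:
                continue
            if placed_coords:
                dg, _ = cKDTree(np.vstack(placed_coords)).query(cand, k=1)
                if float(np.min(dg)) < min_distance:
                    continue
            mol = guest.copy(name=f"{guest.name or 'guest'}_{g}")
            mol.positions = cand
            model.guests.append(mol)
            placed_coords.append(cand)
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place guest {g} within {attempt_budget} attempts",
                achieved=g)
    return model


def build_hydrogel(config: BuilderConfig, guest: Molecule | None = None,
                   energy_model: EnergyModel | None = None) -> HydrogelModel:
    """Full construction: matrix → CD grafting → guest placement."""
    model = build_matrix(config, energy_model=energy_model)
    if config.n_cd:
        graft_cyclodextrins(model, config.n_cd, seed=config.seed,
                            energy_model=energy_model)
    if config.n_guests and guest is not None:
        place_guests(model, guest, config.n_guests,
                     config.guest_min_distance, seed=config.seed,
                     box_margin=config.guest_box_margin)
    return model
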