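"""Pluggable total-energy models and the supermolecular interaction energy.

The pipeline's energetic contract is the supermolecular difference

    ΔE = E(complex) − [E(part 1) + E(part 2)]

evaluated at fixed internal geometry by any :class:`EnergyModel`.  The
bundled model is a Lennard-Jones + Coulomb pair potential with
Lorentz-Berthelot mixing; it stands behind the same interface a
quantum-chemical single-point evaluator would and makes no claim to
reproduce one.
"""

from __future__ import annotations

import numpy as np

from . import elements as elem

__all__ = ["EnergyModel", "LJCoulombModel", "interaction_energy"]


class EnergyModel:
    """Contract: map molecules with fixed internal geometry to a total energy, kcal/mol.

    The energy of the empty system is 0 and the energy is invariant under
    global rotation and translation.
    """

    def total_energy(self, molecules) -> float:
        raise NotImplementedError

    def atom_params(self, molecule):
        raise NotImplementedError


class LJCoulombModel(EnergyModel):
    """Lennard-Jones 12-6 plus Coulomb pair potential.

    Parameters
    ----------
    lj_params : mapping element -> (sigma Å, epsilon kcal/mol), optional
        Overrides merged onto the package defaults.
    coulomb_constant : float
        k_e in kcal Å mol^-1 e^-2 (default 332.0636).
    relative_permittivity : float
        Uniform dielectric screening of the Coulomb term.
    clash_floor : float or None
        Distances below this floor (Å) are clamped to it, so the energy of a
        near-overlapping pair stays finite and sampling remains robust.
    """

    def __init__(self, lj_params=None, coulomb_constant=elem.COULOMB_CONSTANT,
                 relative_permittivity=1.0, clash_floor=0.5):
        self.lj_params = dict(elem.LJ_PARAMS)
        if lj_params:
            self.lj_params.update(lj_params)
        self.ke = float(coulomb_constant)
        self.eps_r = float(relative_permittivity)
        self.clash_floor = clash_floor

    # -- parameter plumbing ------------------------------------------------

    def atom_params(self, molecule):
        """(sigma, epsilon, charge) arrays for one molecule."""
        sig = np.array([self.lj_params.get(e, elem.DEFAULT_LJ)[0]
                        for e in molecule.elements])
        eps = np.array([self.lj_params.get(e, elem.DEFAULT_LJ)[1]
                        for e in molecule.elements])
        return sig, eps, molecule.charges.astype(float)

    # -- energies ----------------------------------------------------------

    def pair_energy_matrix(self, coords_a, sig_a, eps_a, q_a,
                           coords_b, sig_b, eps_b, q_b):
        """Pair energies between two atom sets; supports a leading batch axis on set b."""
        diff = coords_b[..., :, None, :] - coords_a[None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        if self.clash_floor is not None:
            r = np.maximum(r, self.clash_floor)
        sig = 0.5 * (sig_b[:, None] + sig_a[None, :])   # Lorentz
        eps = np.sqrt(eps_b[:, None] * eps_a[None, :])  # Berthelot
        sr6 = (sig / r) ** 6
        e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
        e_c = self.ke * (q_b[:, None] * q_a[None, :]) / (self.eps_r * r)
        return e_lj + e_c

    def inter_energy(self, mol_a, mol_b) -> float:
        """Direct inter-fragment pairwise sum, kcal/mol."""
        sa, ea, qa = self.atom_params(mol_a)
        sb, eb, qb = self.atom_params(mol_b)
        return float(np.sum(self.pair_energy_matrix(
            mol_a.positions, sa, ea, qa, mol_b.positions, sb, eb, qb)))

    def total_energy(self, molecules) -> float:
        """Sum of all non-bonded pair energies over the combined atom set.

        Pairs joined by a bond within one molecule are excluded; all other
        pairs (intra- and inter-molecular) contribute.  Exclusions depend
        only on each molecule's own topology, so intramolecular terms cancel
        exactly in the supermolecular difference.
        """
        molecules = list(molecules)
        if not molecules:
            return 0.0
        coords, sig, eps, q = [], [], [], []
        excluded = set()
        offset = 0
        for mol in molecules:
            s, e, c = self.atom_params(mol)
            coords.append(mol.positions)
            sig.append(s)
            eps.append(e)
            q.append(c)
            for i, j in mol.bonds:
                excluded.add((offset + i, offset + j))
            offset += len(mol)
        coords = np.vstack(coords)
        sig, eps, q = np.concatenate(sig), np.concatenate(eps), np.concatenate(q)
        n = len(coords)
        if n < 2:
            return 0.0
        emat = self.pair_energy_matrix(coords, sig, eps, q, coords, sig, eps, q)
        mask = np.triu(np.ones((n, n), dtype=bool), k=1)
        for i, j in excluded:
            mask[i, j] = mask[j, i] = False
        return float(emat[mask].sum())

    # -- raw-array energy/gradient for relaxation --------------------------

    def nonbonded_energy_gradient(self, coords, sig, eps, q, exclude_pairs=()):
        """Energy and per-atom gradient of the non-bonded sum over one atom set."""
        n = len(coords)
        diff = coords[:, None, :] - coords[None, :, :]
        r2 = np.sum(diff * diff, axis=-1)
        np.fill_diagonal(r2, np.inf)
        for i, j in exclude_pairs:
            r2[i, j] = r2[j, i] = np.inf
        r = np.sqrt(r2)
        floor = self.clash_floor if self.clash_floor is not None else 0.0
        r_eff = np.maximum(r, floor) if floor else r
        sig_ij = 0.5 * (sig[:, None] + sig[None, :])
        eps_ij = np.sqrt(eps[:, None] * eps[None, :])
        sr6 = (sig_ij / r_eff) ** 6
        e_lj = 4.0 * eps_ij * (sr6 * sr6 - sr6)
        q_ij = q[:, None] * q[None, :]
        e_c = self.ke * q_ij / (self.eps_r * r_eff)
        energy = 0.5 * float(np.nansum(e_lj + e_c))
        # dE/dr; zero where the clamp is active (energy locally flat there)
        de_dr = np.where(r > floor,
                         (-24.0 * eps_ij * (2 * sr6 * sr6 - sr6) / r_eff
                          - self.ke * q_ij / (self.eps_r * r_eff ** 2)),
                         0.0)
        with np.errstate(invalid="ignore"):
            gmat = (de_dr / r)[:, :, None] * diff
        grad = np.nansum(np.where(np.isfinite(r)[:, :, None], gmat, 0.0), axis=1)
        return energy, grad


def interaction_energy(host, guest_posed, model: EnergyModel) -> float:
    """Supermolecular interaction energy ΔE in kcal/mol.

    Three total-energy evaluations: the complex at fixed geometry minus the
    isolated parts.  For rigid fragments under a pair potential this equals
    the direct inter-fragment pair sum.
    """
    e_complex = model.total_energy([host, guest_posed])
    e_parts = model.total_energy([host]) + model.total_energy([guest_posed])
    de = e_complex - e_parts
    if not np.isfinite(de):
        raise ArithmeticError(f"non-finite interaction energy: {de}")
    return float(de)
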