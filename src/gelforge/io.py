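"""Structure file I/O: XYZ and fixed-column PDB, single- and multi-model.

Both writers guarantee element+coordinate round-trips (1e-6 Å for XYZ,
1e-3 Å for the fixed-width PDB columns).  Parse failures raise
:class:`~gelforge.errors.StructureParseError` carrying the offending line
number.  PDB chain IDs encode the polymer chain index (A..Z, a..z, 0..9
cycling).
"""

from __future__ import annotations

import numpy as np

from .errors import StructureParseError
from .structures import Molecule

_CHAIN_IDS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
              "abcdefghijklmnopqrstuvwxyz0123456789")


def chain_id_for(index: int) -> str:
    return _CHAIN_IDS[index % len(_CHAIN_IDS)]


# ---------------------------------------------------------------------------
# XYZ

def _parse_xyz_block(lines, start):
    """Parse one XYZ block beginning at ``lines[start]``; returns (molecule, next_index)."""
    try:
        n = int(lines[start].split()[0])
    except (ValueError, IndexError):
        raise StructureParseError("expected atom count", line=start + 1)
    if start + 1 >= len(lines):
        raise StructureParseError("missing comment line", line=start + 2)
    comment = lines[start + 1].rstrip("\n")
    elements, coords = [], []
    for k in range(n):
        ln = start + 2 + k
        if ln >= len(lines):
            raise StructureParseError("unexpected end of file", line=ln + 1)
        parts = lines[ln].split()
        if len(parts) < 4:
            raise StructureParseError("expected 'element x y z'", line=ln + 1)
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise StructureParseError("bad coordinate field", line=ln + 1)
        elements.append(parts[0])
        coords.append(xyz)
    mol = Molecule(elements, np.array(coords).reshape(n, 3), name=comment.strip())
    return mol, start + 2 + n


def read_xyz(path) -> Molecule:
    with open(path) as fh:
        lines = fh.readlines()
    mol, _ = _parse_xyz_block(lines, 0)
    return mol


def write_xyz(molecule: Molecule, path, mode="w", comment=None):
    with open(path, mode) as fh:
        fh.write(f"{len(molecule)}\n")
        fh.write(f"{comment if comment is not None else molecule.name}\n")
        for e, (x, y, z) in zip(molecule.elements, molecule.positions):
            fh.write(f"{e:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz_frames(path) -> list[Molecule]:
    """Read a concatenated multi-frame XYZ file."""
    with open(path) as fh:
        lines = fh.readlines()
    frames, pos = [], 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        mol, pos = _parse_xyz_block(lines, pos)
        frames.append(mol)
    return frames


def write_xyz_frames(molecules, path):
    with open(path, "w") as fh:
        for i, mol in enumerate(molecules):
            fh.write(f"{len(mol)}\n")
            fh.write(f"{mol.name or f'frame {i}'}\n")
            for e, (x, y, z) in zip(mol.elements, mol.positions):
                fh.write(f"{e:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


# ---------------------------------------------------------------------------
# PDB (fixed columns)

def _parse_pdb_atom(line, ln):
    if len(line.rstrip("\n")) < 54:
        raise StructureParseError("ATOM/HETATM record shorter than coordinate fields",
                                  line=ln)
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        raise StructureParseError("bad coordinate field", line=ln)
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        name = line[12:16].strip()
        element = "".join(c for c in name if c.isalpha())[:2].capitalize()
        if element and element[0].isdigit():
            element = element[1:]
        # single-letter organic elements are far more common than two-letter ones
        if element not in ("Cl", "Br", "Na", "Mg", "Zn", "Fe", "Ca"):
            element = element[:1].upper()
    chain = line[21] if len(line) > 21 else " "
    res = line[17:20].strip() if len(line) >= 20 else ""
    return element, (x, y, z), chain, res


def read_pdb(path) -> Molecule:
    elements, coords, tags = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                e, xyz, chain, res = _parse_pdb_atom(line, ln)
                elements.append(e)
                coords.append(xyz)
                tags.append(f"{res}:{chain}".strip(":"))
    if not elements:
        raise StructureParseError("no ATOM/HETATM records found", line=None)
    return Molecule(elements, np.array(coords).reshape(-1, 3), role_tags=tags)


def write_pdb(molecule: Molecule, path, chain_indices=None, res_names=None,
              het_mask=None):
    """Write a single-model PDB.

    ``chain_indices`` maps each atom to a polymer-chain index (encoded in the
    chain-ID column); ``res_names`` and ``het_mask`` control residue naming
    and ATOM vs HETATM records.
    """
    n = len(molecule)
    chain_indices = chain_indices if chain_indices is not None else [0] * n
    res_names = res_names if res_names is not None else ["MOL"] * n
    het_mask = het_mask if het_mask is not None else [False] * n
    with open(path, "w") as fh:
        counters: dict[str, int] = {}
        for i in range(n):
            e = molecule.elements[i]
            counters[e] = counters.get(e, 0) + 1
            name = f"{e}{counters[e] % 1000}"[:4]
            rec = "HETATM" if het_mask[i] else "ATOM  "
            x, y, z = molecule.positions[i]
            fh.write(
                f"{rec}{(i % 99999) + 1:5d} {name:<4s} {res_names[i][:3]:>3s} "
                f"{chain_id_for(chain_indices[i])}{(chain_indices[i] % 9999) + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{e:>2s}\n")
        fh.write("END\n")


def read_pdb_frames(path) -> list[Molecule]:
    """Read a multi-model PDB (MODEL/ENDMDL blocks; a single block otherwise)."""
    frames = []
    cur_e, cur_c, cur_t = [], [], []
    saw_model = False
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                cur_e, cur_c, cur_t = [], [], []
            elif rec in ("ATOM", "HETATM"):
                e, xyz, chain, res = _parse_pdb_atom(line, ln)
                cur_e.append(e)
                cur_c.append(xyz)
                cur_t.append(f"{res}:{chain}".strip(":"))
            elif rec == "ENDMDL":
                frames.append(Molecule(cur_e, np.array(cur_c).reshape(-1, 3),
                                       role_tags=cur_t))
    if not saw_model:
        if not cur_e:
            raise StructureParseError("no ATOM/HETATM records found", line=None)
        frames.append(Molecule(cur_e, np.array(cur_c).reshape(-1, 3),
                               role_tags=cur_t))
    return frames


# ---------------------------------------------------------------------------
# dispatch

def read_structure(path, format: str | None = None) -> Molecule:
    fmt = _infer_format(path, format)
    return read_xyz(path) if fmt == "xyz" else read_pdb(path)


def write_structure(molecule: Molecule, path, format: str | None = None, **kw):
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        write_xyz(molecule, path, **kw)
    else:
        write_pdb(molecule, path, **kw)


def _infer_format(path, format):
    if format is not None:
        fmt = format.lower()
    else:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    if fmt not in ("xyz", "pdb"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    return fmt
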