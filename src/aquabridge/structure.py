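"""Structure I/O, crystallographic symmetry expansion and sphere extraction.

The in-memory model is deliberately small: an ordered list of
:class:`AtomRecord` plus optional unit-cell/space-group information.
Parsing of PDB and mmCIF files is delegated to :mod:`biotite`; hydrogens
present in input files are discarded on read and rebuilt later by the
chemistry module so that every run uses a uniform hydrogen model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import spacegroups

__all__ = [
    "AtomRecord",
    "Structure",
    "ReferenceSphere",
    "FormatError",
    "read_structure",
    "write_structure",
    "expand_symmetry",
    "extract_sphere",
    "prepare_for_rebuild",
    "prepare_ligand_pocket",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "CB", "OXT"}


class FormatError(ValueError):
    """Unreadable or malformed structure file."""


@dataclass
class AtomRecord:
    element: str
    name: str
    res_name: str
    chain: str
    res_id: int
    alt_loc: str = ""
    occupancy: float = 1.0
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    is_water: bool = False
    is_ligand: bool = False
    symmetry_copy: int | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self) -> tuple:
        sym = self.symmetry_copy
        return (self.chain, self.res_id, self.res_name, sym)


@dataclass
class Structure:
    atoms: list[AtomRecord] = field(default_factory=list)
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    # sequence of truncated residues, kept for rebuilding: key -> residue name
    rebuild_sequence: dict | None = None
    # fixed candidate pose of a deleted ligand (list of AtomRecord)
    ligand_pose: list | None = None

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def residues(self) -> dict:
        """Group atoms by residue, preserving file order."""
        out: dict[tuple, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def copy(self) -> "Structure":
        return Structure(
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            cell=self.cell,
            space_group=self.space_group,
            rebuild_sequence=dict(self.rebuild_sequence)
            if self.rebuild_sequence else None,
            ligand_pose=list(self.ligand_pose) if self.ligand_pose else None,
        )


@dataclass
class ReferenceSphere:
    """A 20 A atom neighbourhood around a central crystallographic water."""

    central_water: np.ndarray
    atoms: Structure
    radius: float = 20.0
    design_radius: float = 8.0
    eval_radius: float = 6.0

    def __post_init__(self):
        self.central_water = np.asarray(self.central_water, dtype=float)


# ---------------------------------------------------------------------------
# reading / writing

def _is_ligand(res_name: str, hetero: bool) -> bool:
    return bool(hetero) and res_name not in WATER_NAMES \
        and res_name not in STANDARD_AA


def _from_atom_array(arr) -> list[AtomRecord]:
    records = []
    occ = arr.occupancy if "occupancy" in arr.get_annotation_categories() \
        else np.ones(arr.array_length())
    alt = arr.altloc_id if "altloc_id" in arr.get_annotation_categories() \
        else [""] * arr.array_length()
    for i in range(arr.array_length()):
        el = str(arr.element[i]).upper()
        if el == "H" or el == "D":
            continue  # uniform hydrogen model: rebuilt downstream
        res_name = str(arr.res_name[i])
        records.append(AtomRecord(
            element=el,
            name=str(arr.atom_name[i]),
            res_name=res_name,
            chain=str(arr.chain_id[i]),
            res_id=int(arr.res_id[i]),
            alt_loc=str(alt[i]).strip(),
            occupancy=float(min(max(occ[i], 0.0), 1.0)),
            position=arr.coord[i],
            is_water=res_name in WATER_NAMES,
            is_ligand=_is_ligand(res_name, arr.hetero[i]),
        ))
    return records


def _read_pdb(path: str) -> Structure:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    arr = pdb.get_structure(
        model=1, altloc="occupancy", extra_fields=["occupancy"])
    cell = space_group = None
    for line in pdb.lines:
        if line.startswith("CRYST1"):
            try:
                cell = tuple(float(line[i:j]) for i, j in
                             [(6, 15), (15, 24), (24, 33),
                              (33, 40), (40, 47), (47, 54)])
            except ValueError:
                cell = None
            sg = line[55:66].strip()
            space_group = sg or None
            break
    # a CRYST1 of a 1x1x1 P1 placeholder cell means "no symmetry"
    if cell is not None and cell[0] <= 1.0 and cell[1] <= 1.0:
        cell = space_group = None
    return Structure(atoms=_from_atom_array(arr), cell=cell,
                     space_group=space_group)


def _read_mmcif(path: str) -> Structure:
    from biotite.structure.io import pdbx

    cif = pdbx.CIFFile.read(path)
    arr = pdbx.get_structure(
        cif, model=1, altloc="occupancy", extra_fields=["occupancy"])
    cell = space_group = None
    block = cif.block
    if "cell" in block:
        c = block["cell"]
        try:
            cell = tuple(float(c[k].as_item()) for k in
                         ["length_a", "length_b", "length_c",
                          "angle_alpha", "angle_beta", "angle_gamma"])
        except KeyError:
            cell = None
    if "symmetry" in block:
        try:
            space_group = block["symmetry"][
                "space_group_name_H-M"].as_item().strip()
        except KeyError:
            pass
    return Structure(atoms=_from_atom_array(arr), cell=cell,
                     space_group=space_group)


def read_structure(path: str, dialect: str = "pdb") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Alt-loc groups are resolved to the highest-occupancy conformer
    (ties: first in file); hydrogens are discarded.
    """
    try:
        if dialect == "pdb":
            return _read_pdb(path)
        if dialect in ("mmcif", "cif"):
            return _read_mmcif(path)
    except FormatError:
        raise
    except Exception as exc:  # parser errors from biotite
        raise FormatError(f"cannot read {path!r} as {dialect}: {exc}") from exc
    raise FormatError(f"unknown dialect {dialect!r}")


def write_structure(s: Structure, path: str) -> None:
    """Write a fixed-column PDB file (waters as HOH HETATM, occupancy 1.00)."""
    lines = []
    if s.cell is not None:
        a, b, c, al, be, ga = s.cell
        sg = s.space_group or "P 1"
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
            f"{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}   1")
    serial = 0
    for atom in s.atoms:
        serial += 1
        record = "HETATM" if (atom.is_water or atom.is_ligand) else "ATOM  "
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        x, y, z = atom.position
        lines.append(
            f"{record}{serial % 100000:5d} {name:<4.4s}{atom.alt_loc or ' ':1.1s}"
            f"{atom.res_name:<3.3s} {atom.chain[:1]:1s}{atom.res_id % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2.2s}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# crystallographic symmetry

def _orthogonalization_matrix(cell) -> np.ndarray:
    a, b, c, alpha, beta, gamma = cell
    al, be, ga = (math.radians(x) for x in (alpha, beta, gamma))
    cos_al, cos_be, cos_ga = math.cos(al), math.cos(be), math.cos(ga)
    sin_ga = math.sin(ga)
    v = math.sqrt(
        1 - cos_al ** 2 - cos_be ** 2 - cos_ga ** 2
        + 2 * cos_al * cos_be * cos_ga)
    return np.array([
        [a, b * cos_ga, c * cos_be],
        [0.0, b * sin_ga, c * (cos_al - cos_be * cos_ga) / sin_ga],
        [0.0, 0.0, c * v / sin_ga],
    ])


def expand_symmetry(s: Structure, center, radius: float,
                    translation_range: int = 2) -> Structure:
    """Add symmetry/lattice-translation copies near *center*.

    Every space-group image of the structure, shifted by lattice
    translations in a ``-translation_range..translation_range`` cube, is
    retained if any of its atoms lies within *radius* of *center*
    (closed ball).  Copies are tagged with their operator index.  Without
    cell or space-group information the input is returned unchanged.
    """
    if s.cell is None or s.space_group is None:
        return s.copy()
    center = np.asarray(center, dtype=float)
    ops = spacegroups.operators(s.space_group)
    M = _orthogonalization_matrix(s.cell)
    Minv = np.linalg.inv(M)

    coords = s.coords
    frac = coords @ Minv.T
    out = s.copy()
    rng = range(-translation_range, translation_range + 1)
    for op_idx, (rot, trans) in enumerate(ops):
        frac_img = frac @ rot.T + trans
        for nx in rng:
            for ny in rng:
                for nz in rng:
                    shift = np.array([nx, ny, nz], dtype=float)
                    if op_idx == 0 and not shift.any():
                        continue  # the original copy
                    cart = (frac_img + shift) @ M.T
                    d = np.linalg.norm(cart - center, axis=1)
                    if d.min() <= radius:
                        for atom, pos in zip(s.atoms, cart):
                            out.atoms.append(replace(
                                atom, position=pos.copy(),
                                symmetry_copy=op_idx))
    return out


def symmetry_images(s: Structure) -> list[np.ndarray]:
    """Cartesian coordinates of each space-group image of *s* (no lattice
    translations); convenience for testing operator application."""
    if s.cell is None or s.space_group is None:
        return [s.coords]
    M = _orthogonalization_matrix(s.cell)
    Minv = np.linalg.inv(M)
    frac = s.coords @ Minv.T
    return [(frac @ rot.T + trans) @ M.T
            for rot, trans in spacegroups.operators(s.space_group)]


# ---------------------------------------------------------------------------
# spheres and validation preparation

def extract_sphere(s: Structure, center, radius: float = 20.0,
                   design_radius: float = 8.0,
                   eval_radius: float = 6.0) -> ReferenceSphere:
    """All and only atoms within *radius* of *center* (closed ball)."""
    center = np.asarray(center, dtype=float)
    kept = [a for a in s.atoms
            if np.linalg.norm(a.position - center) <= radius]
    sub = Structure(atoms=[replace(a, position=a.position.copy())
                           for a in kept],
                    cell=s.cell, space_group=s.space_group)
    return ReferenceSphere(central_water=center, atoms=sub, radius=radius,
                           design_radius=design_radius,
                           eval_radius=eval_radius)


def _truncate_residue(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Reduce a residue to alanine/glycine backbone (N, CA, C, O, CB)."""
    return [a for a in atoms if a.name in ("N", "CA", "C", "O", "CB")]


def prepare_for_rebuild(sp: ReferenceSphere) -> Structure:
    """Strip waters and truncate residues near the sphere centre.

    Every residue with at least one atom within ``design_radius`` of the
    centre is reduced to alanine (glycine keeps no CB); the original
    sequence is retained in ``rebuild_sequence`` for rebuilding.
    """
    center = sp.central_water
    out_atoms: list[AtomRecord] = []
    sequence: dict = {}
    for key, atoms in sp.atoms.residues().items():
        if atoms[0].is_water:
            continue
        dmin = min(np.linalg.norm(a.position - center) for a in atoms)
        if dmin <= sp.design_radius and not atoms[0].is_ligand:
            sequence[key[:2]] = key[2]
            out_atoms.extend(_truncate_residue(atoms))
        else:
            out_atoms.extend(atoms)
    return Structure(atoms=[replace(a, position=a.position.copy())
                            for a in out_atoms],
                     cell=sp.atoms.cell, space_group=sp.atoms.space_group,
                     rebuild_sequence=sequence)


def prepare_ligand_pocket(s: Structure, ligand_id: str,
                          radius: float = 6.0) -> Structure:
    """Alanine-substitute residues near a ligand and delete the ligand.

    Residues with any atom closer than *radius* (strict) to any ligand atom
    are truncated; the ligand pose is kept in ``ligand_pose`` as a fixed
    candidate placement for rebuilding.
    """
    lig_atoms = [a for a in s.atoms
                 if a.is_ligand and a.res_name == ligand_id]
    if not lig_atoms:
        raise KeyError(f"ligand {ligand_id!r} not present")
    lig_coords = np.array([a.position for a in lig_atoms])

    out_atoms: list[AtomRecord] = []
    sequence: dict = {}
    for key, atoms in s.residues().items():
        if atoms and atoms[0].res_name == ligand_id and atoms[0].is_ligand:
            continue  # deleted, pose retained below
        coords = np.array([a.position for a in atoms])
        dmin = np.linalg.norm(
            coords[:, None, :] - lig_coords[None, :, :], axis=2).min()
        if dmin < radius and not atoms[0].is_water \
                and not atoms[0].is_ligand:
            sequence[key[:2]] = key[2]
            out_atoms.extend(_truncate_residue(atoms))
        else:
            out_atoms.extend(atoms)
    return Structure(atoms=[replace(a, position=a.position.copy())
                            for a in out_atoms],
                     cell=s.cell, space_group=s.space_group,
                     rebuild_sequence=sequence,
                     ligand_pose=[replace(a, position=a.position.copy())
                                  for a in lig_atoms])
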