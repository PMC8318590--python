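"""Protein structures, atom selection and geometric primitives.

A :class:`Structure` is a light container of atoms (chain, residue id,
residue name, atom name, element, coordinates in nm, occupancy) carrying a
``numbering_convention`` flag: ``"pdb"`` for mature-protein numbering as
found in crystal structures, ``"paper"`` after the 24-residue
signal-peptide offset has been applied (EGFR convention in which the
catalytic lysine is K745).

Geometric primitives — interatomic distances and Kabsch-superposed RMSD —
live here because every downstream stage (collective variables, clustering,
steered-run monitors) is built on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ANGSTROM_PER_NM, SIGNAL_PEPTIDE_OFFSET

__all__ = [
    "Atom",
    "AtomSelector",
    "Structure",
    "read_pdb",
    "write_pdb",
    "apply_numbering_offset",
    "atom_distance",
    "kabsch_rmsd",
]

#: Map from Greek-letter atom labels used in the kinase literature to
#: standard PDB atom names.
GREEK_TO_PDB = {"Nζ": "NZ", "Cδ": "CD", "Cγ": "CG", "Cβ": "CB", "Cα": "CA"}


@dataclass(frozen=True)
class Atom:
    chain: str
    resid: int
    resname: str
    name: str
    element: str
    coord: np.ndarray  # shape (3,), nm
    occupancy: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.chain}:{self.resid}:{self.name}: "
                             "coordinates must be a finite 3-vector")


@dataclass(frozen=True)
class AtomSelector:
    """Address of exactly one atom: chain, residue id, PDB atom name.

    Residue ids are interpreted in whatever convention the target
    :class:`Structure` carries; selectors written for paper numbering must
    be resolved against a paper-numbered structure.
    """

    chain: str
    resid: int
    name: str

    @classmethod
    def parse(cls, text: str) -> "AtomSelector":
        """Parse ``"chain:resid:atomname"`` (e.g. ``"A:745:NZ"``)."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"selector {text!r}: expected chain:resid:atomname")
        name = GREEK_TO_PDB.get(parts[2], parts[2])
        return cls(parts[0], int(parts[1]), name)

    def __str__(self) -> str:
        return f"{self.chain}:{self.resid}:{self.name}"


@dataclass
class Structure:
    atoms: list[Atom]
    label: str = ""
    numbering_convention: str = "pdb"

    def __post_init__(self):
        self._index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.resid, a.name)
            if key in self._index:
                raise ValueError(f"duplicate atom {key} in structure {self.label!r}")
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    def resolve(self, sel: AtomSelector) -> Atom:
        """Return the unique atom addressed by ``sel`` or raise ``KeyError``."""
        try:
            return self.atoms[self._index[(sel.chain, sel.resid, sel.name)]]
        except KeyError:
            raise KeyError(
                f"selector {sel} does not resolve in structure "
                f"{self.label!r} ({self.numbering_convention} numbering)"
            ) from None

    def coords(self, selection: list[AtomSelector] | None = None) -> np.ndarray:
        """Coordinates (n, 3) in nm, optionally restricted to a selection."""
        if selection is None:
            return np.array([a.coord for a in self.atoms])
        return np.array([self.resolve(s).coord for s in selection])

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Copy of this structure with every atom moved to ``coords``."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coord=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, label if label is not None else self.label,
                         self.numbering_convention)


_WATER_NAMES = {"HOH", "WAT", "SOL", "TIP", "TIP3", "TIP4"}


def read_pdb(path, label: str = "", keep_hetero: bool = False) -> Structure:
    """Read a PDB file into a :class:`Structure` (coordinates Å → nm).

    Alternate locations are resolved by keeping the highest-occupancy
    conformer (ties broken in favour of the lexicographically first altloc
    id, i.e. "A").  Waters and hetero groups are dropped unless
    ``keep_hetero`` is set.
    """
    import biotite.structure.io.pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(path)
    except FileNotFoundError:
        raise
    try:
        arr = pdb_file.get_structure(model=1, altloc="all",
                                     extra_fields=["occupancy"])
    except Exception as exc:  # biotite raises on structure-free files
        raise ValueError(f"{path}: no atoms ({exc})") from exc
    if arr.array_length() == 0:
        raise ValueError(f"{path}: no atoms")

    # altloc resolution: per (chain, resid, atom name) keep max occupancy,
    # tie -> first altloc id in sort order ("A" before "B").
    best: dict[tuple[str, int, str], int] = {}
    for i in range(arr.array_length()):
        if not keep_hetero and (arr.hetero[i] or arr.res_name[i] in _WATER_NAMES):
            continue
        key = (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.atom_name[i]))
        if key not in best:
            best[key] = i
        else:
            j = best[key]
            oi, oj = float(arr.occupancy[i]), float(arr.occupancy[j])
            if oi > oj or (oi == oj and str(arr.altloc_id[i]) < str(arr.altloc_id[j])):
                best[key] = i

    atoms = [
        Atom(
            chain=str(arr.chain_id[i]),
            resid=int(arr.res_id[i]),
            resname=str(arr.res_name[i]),
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            coord=np.asarray(arr.coord[i], dtype=float) / ANGSTROM_PER_NM,
            occupancy=float(arr.occupancy[i]),
        )
        for i in sorted(best.values())
    ]
    if not atoms:
        raise ValueError(f"{path}: no atoms after filtering")
    return Structure(atoms, label=label or str(path), numbering_convention="pdb")


def write_pdb(structure: Structure, path) -> None:
    """Write a structure to PDB format (coordinates nm → Å, 3 decimals)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n = len(structure.atoms)
    arr = struc.AtomArray(n)
    for i, a in enumerate(structure.atoms):
        arr.chain_id[i] = a.chain
        arr.res_id[i] = a.resid
        arr.res_name[i] = a.resname
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.coord[i] = a.coord * ANGSTROM_PER_NM
    arr.set_annotation("occupancy",
                       np.array([a.occupancy for a in structure.atoms]))
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(path)


def apply_numbering_offset(structure: Structure,
                           offset: int = SIGNAL_PEPTIDE_OFFSET) -> Structure:
    """Shift every residue id by ``offset`` and flip the convention flag.

    Mature-protein EGFR crystal structures number the catalytic lysine 721;
    the convention that counts the 24-residue membrane-targeting signal
    peptide numbers it 745.  The default +24 offset converts "pdb" to
    "paper" numbering (e.g. Q952 → Q976).  Applying it twice is an error.
    """
    if structure.numbering_convention != "pdb":
        raise ValueError("numbering offset already applied "
                         f"(convention is {structure.numbering_convention!r})")
    atoms = [replace(a, resid=a.resid + offset) for a in structure.atoms]
    out = Structure(atoms, structure.label, "paper")
    return out


def atom_distance(structure: Structure, a: AtomSelector, b: AtomSelector) -> float:
    """Euclidean distance in nm between two selected atoms."""
    return float(np.linalg.norm(structure.resolve(a).coord -
                                structure.resolve(b).coord))


def kabsch_rmsd(mobile: Structure, reference: Structure,
                selection: list[AtomSelector], superpose: bool = True) -> float:
    """RMSD in nm over ``selection``, optionally after optimal superposition.

    Superposition removes the centroids and applies the least-squares
    proper rotation (Kabsch); reflections are never used.  Both structures
    must resolve the selection identically; at least three atoms are
    required when superposing.
    """
    x = mobile.coords(selection)
    y = reference.coords(selection)
    if x.shape != y.shape:
        raise ValueError("selection resolves to different atom counts")
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
    if len(selection) < 3:
        raise ValueError("superposition requires at least 3 atoms")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # Kabsch: proper rotation from the SVD of the covariance, with the
    # determinant sign corrected so reflections are never used
    u, _, vt = np.linalg.svd(xc.T @ yc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    diff = xc @ rot.T - yc
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
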