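"""Reading protein/ligand structures and carving out the interaction region.

Proteins come from PDB files (Bio.PDB), ligands from SDF/MOL/MOL2 files
(RDKit). Everything downstream operates on heavy atoms only: hydrogens are
dropped at load time, waters are discarded, and of alternate locations only
the first ('A' or blank) is kept. The interaction region around a ligand is
the set of all ligand heavy atoms plus every protein heavy atom whose
minimum Euclidean distance to any ligand atom is <= cutoff (closed
threshold).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .elements import is_hydrogen, normalize_element

PROTEIN = "protein"
LIGAND = "ligand"

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Raised for unreadable or empty structure files."""


@dataclass(eq=False)
class Atom:
    """A heavy atom: element symbol, coordinates in Angstrom, origin tag."""

    index: int
    element: str
    coords: np.ndarray
    origin: str

    def __post_init__(self) -> None:
        self.element = normalize_element(self.element)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")
        if self.origin not in (PROTEIN, LIGAND):
            raise ValueError(f"unknown origin {self.origin!r}")
        if is_hydrogen(self.element):
            raise ValueError("hydrogen atoms are not representable here")


@dataclass
class MolecularComplex:
    """A 3D protein-ligand complex as two heavy-atom lists."""

    identifier: str
    protein_atoms: list[Atom]
    ligand_atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError("a complex needs at least one ligand atom")
        for a in self.protein_atoms:
            if a.origin != PROTEIN:
                raise ValueError("protein_atoms contains a non-protein atom")
        for a in self.ligand_atoms:
            if a.origin != LIGAND:
                raise ValueError("ligand_atoms contains a non-ligand atom")


@dataclass
class ComplexRegion:
    """The binding-site region: all ligand atoms + nearby protein atoms."""

    atoms: list[Atom]
    cutoff: float
    source_id: str = ""

    @property
    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.origin == PROTEIN]

    @property
    def ligand_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.origin == LIGAND]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(len(self.atoms), 3)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source_id": self.source_id,
            "cutoff": self.cutoff,
            "atoms": [
                {
                    "index": a.index,
                    "element": a.element,
                    "coords": a.coords.tolist(),
                    "origin": a.origin,
                }
                for a in self.atoms
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ComplexRegion":
        payload = json.loads(Path(path).read_text())
        atoms = [Atom(**a) for a in payload["atoms"]]
        return cls(atoms=atoms, cutoff=payload["cutoff"], source_id=payload["source_id"])


def read_protein(path: str | Path) -> list[Atom]:
    """Read heavy protein atoms from a PDB file.

    Keeps the first model only; drops waters, hydrogens/deuteriums and
    alternate locations other than the first ('A' or blank). The element is
    taken from the element column when present, else inferred from the atom
    name.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise StructureError(f"no models in {path}")
    atoms: list[Atom] = []
    idx = 0
    for residue in models[0].get_residues():
        if residue.get_resname().strip() in _WATER_RESNAMES:
            continue
        for atom in residue.get_atoms():
            if atom.get_altloc() not in (" ", "", "A"):
                continue
            element = (atom.element or "").strip()
            if not element:
                # fall back on the leading letters of the atom name
                name = atom.get_name().strip().lstrip("0123456789")
                element = name[:2] if name[:2].capitalize() in ("Cl", "Br", "Fe", "Zn", "Mg", "Se") else name[:1]
            if not element or is_hydrogen(element):
                continue
            atoms.append(Atom(index=idx, element=element, coords=atom.get_coord(), origin=PROTEIN))
            idx += 1
    if not atoms:
        raise StructureError(f"no heavy atoms found in {path}")
    return atoms


def read_ligand(path: str | Path, fmt: str | None = None) -> list[Atom]:
    """Read heavy ligand atoms from an SDF/MOL or MOL2 file.

    The format is inferred from the extension unless ``fmt`` is given.
    Element symbols are normalized (``"CL"`` -> ``"Cl"``; Sybyl types such
    as ``"C.3"`` reduce to their element).
    """
    from rdkit import Chem

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("sdf", "mol"):
        mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    else:
        raise StructureError(f"unknown ligand format {fmt!r} (expected sdf, mol or mol2)")
    if mol is None:
        raise StructureError(f"cannot parse {fmt} file {path}")
    if mol.GetNumConformers() == 0:
        raise StructureError(f"{path} has no 3D coordinates")
    conf = mol.GetConformer()
    atoms: list[Atom] = []
    idx = 0
    for rd_atom in mol.GetAtoms():
        symbol = normalize_element(rd_atom.GetSymbol())
        if is_hydrogen(symbol):
            continue
        pos = conf.GetAtomPosition(rd_atom.GetIdx())
        atoms.append(Atom(index=idx, element=symbol, coords=(pos.x, pos.y, pos.z), origin=LIGAND))
        idx += 1
    if not atoms:
        raise StructureError(f"no heavy atoms found in {path}")
    return atoms


def read_complex(protein_path: str | Path, ligand_path: str | Path, identifier: str = "",
                 ligand_fmt: str | None = None) -> MolecularComplex:
    identifier = identifier or Path(protein_path).stem
    return MolecularComplex(
        identifier=identifier,
        protein_atoms=read_protein(protein_path),
        ligand_atoms=read_ligand(ligand_path, fmt=ligand_fmt),
    )


def extract_region(complex_: MolecularComplex, cutoff: float) -> ComplexRegion:
    """Carve out all ligand atoms plus protein atoms within ``cutoff``.

    Membership uses the minimum distance to *any* ligand atom with a closed
    threshold (distance <= cutoff is kept). If no protein atom qualifies a
    warning is issued and the region contains the ligand only.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_coords = np.array([a.coords for a in complex_.ligand_atoms])
    kept: list[Atom] = []
    if complex_.protein_atoms:
        prot_coords = np.array([a.coords for a in complex_.protein_atoms])
        min_dist = cdist(prot_coords, lig_coords).min(axis=1)
        kept = [a for a, d in zip(complex_.protein_atoms, min_dist) if d <= cutoff]
    if not kept:
        warnings.warn(
            f"{complex_.identifier}: no protein atom within {cutoff} A of the ligand",
            stacklevel=2,
        )
    atoms = [
        Atom(index=i, element=a.element, coords=a.coords, origin=a.origin)
        for i, a in enumerate(kept + complex_.ligand_atoms)
    ]
    return ComplexRegion(atoms=atoms, cutoff=cutoff, source_id=complex_.identifier)
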