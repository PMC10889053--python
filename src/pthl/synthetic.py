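"""Seeded synthetic data: canonical shapes, complexes, benchmark tables.

Everything here is generated, not measured: the complexes are random heavy
atoms in a box (no bonds, no clash avoidance), and the benchmark tables are
ground-truth-known so every evaluation metric has a computable expected
value. Fixed seeds give bit-identical output (numpy Generator with integer
seeding). Written structure files use the smallest dialects the readers
accept: PDB ATOM/HETATM/END records with a populated element column, and a
V2000 molblock with zero bonds.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .elements import LIGAND_ELEMENTS, PROTEIN_ELEMENTS
from .structure import LIGAND, PROTEIN, Atom, MolecularComplex

# -- canonical point-cloud shapes with known homology ----------------------

_SQRT3 = np.sqrt(3.0)


def canonical_shape(name: str, scale: float = 1.0) -> tuple[np.ndarray, dict]:
    """Coordinates plus reference (beta_0, beta_1) at a stated threshold.

    Supported names: ``pair``, ``path3``, ``triangle``, ``filled_triangle``,
    ``tetrahedron``, ``two_clusters`` and ``circle_<n>`` (n points on a
    circle). The metadata dict records the threshold ``eta`` and the maximum
    hyperedge dimension at which the Betti numbers hold.
    """
    if name.startswith("circle_"):
        n = int(name.split("_", 1)[1])
        if n < 3:
            raise ValueError("circle needs at least 3 points")
        angles = 2 * np.pi * np.arange(n) / n
        radius = scale
        coords = np.stack([radius * np.cos(angles), radius * np.sin(angles),
                           np.zeros(n)], axis=1)
        chord = 2 * radius * np.sin(np.pi / n)
        # at the adjacent-chord threshold the cycle closes: one loop
        return coords, {"eta": chord * 1.001, "betti0": 1, "betti1": 1, "max_dim": 1}

    s = scale
    shapes: dict[str, tuple[np.ndarray, dict]] = {
        "pair": (
            np.array([[0, 0, 0], [s, 0, 0]], dtype=float),
            {"eta": s, "betti0": 1, "betti1": 0, "max_dim": 1},
        ),
        "path3": (
            np.array([[0, 0, 0], [s, 0, 0], [2 * s, 0, 0]], dtype=float),
            {"eta": s, "betti0": 1, "betti1": 0, "max_dim": 1},
        ),
        "triangle": (
            np.array([[0, 0, 0], [s, 0, 0], [s / 2, s * _SQRT3 / 2, 0]]),
            {"eta": s, "betti0": 1, "betti1": 1, "max_dim": 1},
        ),
        "filled_triangle": (
            np.array([[0, 0, 0], [s, 0, 0], [s / 2, s * _SQRT3 / 2, 0]]),
            {"eta": s, "betti0": 1, "betti1": 0, "max_dim": 2},
        ),
        "tetrahedron": (
            np.array([[0, 0, 0], [s, 0, 0], [s / 2, s * _SQRT3 / 2, 0],
                      [s / 2, s / (2 * _SQRT3), s * np.sqrt(2.0 / 3.0)]]),
            # 1-skeleton only: beta_1 = |E| - |V| + 1 = 6 - 4 + 1
            {"eta": s, "betti0": 1, "betti1": 3, "max_dim": 1},
        ),
        "two_clusters": (
            np.vstack([
                np.array([[0, 0, 0], [s, 0, 0], [s / 2, s * _SQRT3 / 2, 0]]),
                np.array([[0, 0, 0], [s, 0, 0], [s / 2, s * _SQRT3 / 2, 0]])
                + np.array([10 * s, 0, 0]),
            ]),
            {"eta": s, "betti0": 2, "betti1": 2, "max_dim": 1},
        ),
    }
    try:
        return shapes[name]
    except KeyError:
        raise ValueError(f"unknown canonical shape {name!r}") from None


# -- random point clouds ---------------------------------------------------

def random_cloud(n: int, box: float = 3.0, seed: int = 0) -> np.ndarray:
    """Uniform random points in a cube of side ``box`` Angstrom."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, box, size=(n, 3))


# -- synthetic protein-ligand complexes ------------------------------------

def _sample_elements(rng, spec, n, default_pool) -> list[str]:
    if isinstance(spec, dict):
        out: list[str] = []
        for element, count in spec.items():
            out.extend([element] * count)
        if len(out) != n:
            raise ValueError("element counts must sum to the atom count")
        return out
    pool = list(spec) if spec is not None else list(default_pool)
    return list(rng.choice(pool, size=n))


def synthetic_complex(n_protein: int = 60, n_ligand: int = 15,
                      protein_elements=None, ligand_elements=None,
                      box: float = 16.0, seed: int = 0,
                      identifier: str | None = None,
                      out_dir: str | Path | None = None):
    """A random heavy-atom protein-ligand complex (optionally written to disk).

    The ligand occupies a small central box (a quarter of ``box``) and the
    protein atoms fill the surrounding cube, emulating a binding pocket.
    ``protein_elements`` / ``ligand_elements`` are either pools to sample
    from or ``{element: count}`` dicts realized exactly. Returns the
    complex, or ``(complex, pdb_path, sdf_path)`` when ``out_dir`` is given.
    """
    if n_protein < 1 or n_ligand < 1:
        raise ValueError("atom counts must be >= 1")
    rng = np.random.default_rng(seed)
    identifier = identifier or f"synthetic-{seed}"
    lig_box = box / 4.0
    lig_coords = rng.uniform(-lig_box / 2, lig_box / 2, size=(n_ligand, 3))
    prot_coords = rng.uniform(-box / 2, box / 2, size=(n_protein, 3))
    prot_elems = _sample_elements(rng, protein_elements, n_protein, PROTEIN_ELEMENTS)
    lig_elems = _sample_elements(rng, ligand_elements, n_ligand, LIGAND_ELEMENTS)
    complex_ = MolecularComplex(
        identifier=identifier,
        protein_atoms=[Atom(i, e, c, PROTEIN)
                       for i, (e, c) in enumerate(zip(prot_elems, prot_coords))],
        ligand_atoms=[Atom(i, e, c, LIGAND)
                      for i, (e, c) in enumerate(zip(lig_elems, lig_coords))],
    )
    if out_dir is None:
        return complex_
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / f"{identifier}_protein.pdb"
    sdf_path = out_dir / f"{identifier}_ligand.sdf"
    write_protein_pdb(complex_.protein_atoms, pdb_path)
    write_ligand_sdf(complex_.ligand_atoms, sdf_path, name=identifier)
    return complex_, pdb_path, sdf_path


def write_protein_pdb(atoms, path: str | Path) -> None:
    """Minimal PDB: ATOM records with the element column populated."""
    lines = []
    for i, atom in enumerate(atoms, start=1):
        x, y, z = atom.coords
        name = atom.element[:4]
        lines.append(
            f"ATOM  {i:5d} {name:<4s} ALA A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ligand_sdf(atoms, path: str | Path, name: str = "LIG") -> None:
    """Minimal V2000 molblock with zero bonds."""
    n = len(atoms)
    lines = [name, "  pthl", "", f"{n:3d}{0:3d}  0  0  0  0  0  0  0  0999 V2000"]
    for atom in atoms:
        x, y, z = atom.coords
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {atom.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    lines += ["M  END", "$$$$"]
    Path(path).write_text("\n".join(lines) + "\n")


# -- synthetic benchmark tables --------------------------------------------

def benchmark_tables(n_clusters: int = 65, cluster_size: int = 3,
                     n_ligands: int = 195, n_poses: int = 100,
                     n_targets: int = 65, n_binders: int = 3,
                     noise: float = 0.0, seed: int = 0):
    """Ground-truth-known cluster / pose / screen tables.

    With ``noise = 0`` the predictions equal the ground truth, so ranking,
    docking and screening metrics are all perfect; ``noise`` adds Gaussian
    perturbation of that standard deviation to every predicted quantity.
    The default shapes mirror the CASF-style benchmarks: 65 clusters of 3,
    195 ligands with 100 poses each, 65 targets with 3 true binders.
    Returns ``(clusters, poses, screens)`` DataFrames.
    """
    rng = np.random.default_rng(seed)

    rows = []
    for c in range(n_clusters):
        # spread affinities so noise-free rankings are unambiguous
        base = rng.uniform(2.0, 9.0)
        offsets = np.arange(cluster_size) * rng.uniform(0.8, 1.5)
        expt = base + offsets
        pred = expt + noise * rng.standard_normal(cluster_size)
        for j in range(cluster_size):
            rows.append({"cluster_id": c, "complex_id": f"c{c}_m{j}",
                         "expt": expt[j], "pred": pred[j]})
    clusters = pd.DataFrame(rows)

    rows = []
    for lig in range(n_ligands):
        rmsds = np.concatenate([
            rng.uniform(0.2, 1.8, size=1),            # at least one native pose
            rng.uniform(0.5, 10.0, size=n_poses - 1),
        ])
        scores = -rmsds + noise * rng.standard_normal(n_poses)
        for p in range(n_poses):
            rows.append({"ligand_id": f"lig{lig}", "pose_id": p,
                         "rmsd": rmsds[p], "score": scores[p]})
    poses = pd.DataFrame(rows)

    rows = []
    for t in range(n_targets):
        binder_idx = set(rng.choice(n_ligands, size=n_binders, replace=False).tolist())
        for lig in range(n_ligands):
            is_binder = lig in binder_idx
            affinity = rng.uniform(6.0, 10.0) if is_binder else rng.uniform(1.0, 5.0)
            s1 = affinity + noise * rng.standard_normal()
            s2 = float(np.clip((0.9 if is_binder else 0.1)
                               + noise * rng.standard_normal(), 0.0, 1.0))
            rows.append({"target_id": f"t{t}", "ligand_id": f"lig{lig}",
                         "is_binder": is_binder, "s1": s1, "s2": s2,
                         "affinity": affinity})
    screens = pd.DataFrame(rows)
    return clusters, poses, screens
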