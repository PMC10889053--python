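import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pthl.structure import LIGAND, PROTEIN, Atom, ComplexRegion, MolecularComplex


def make_region(atom_specs, cutoff=12.0, source_id="test"):
    """Build a ComplexRegion from (element, coords, origin) triples."""
    atoms = [
        Atom(index=i, element=e, coords=np.asarray(c, dtype=float), origin=o)
        for i, (e, c, o) in enumerate(atom_specs)
    ]
    return ComplexRegion(atoms=atoms, cutoff=cutoff, source_id=source_id)


@pytest.fixture
def cc_region():
    """One protein carbon at the origin, one ligand carbon 3.0 A away."""
    return make_region([
        ("C", (0.0, 0.0, 0.0), PROTEIN),
        ("C", (3.0, 0.0, 0.0), LIGAND),
    ])


@pytest.fixture
def small_complex():
    from pthl.synthetic import synthetic_complex

    return synthetic_complex(n_protein=25, n_ligand=8, box=12.0, seed=11)


@pytest.fixture
def tiny_sequences():
    """Random (n, T, 143, 6) tensors for model tests."""
    rng = np.random.default_rng(42)
    return rng.normal(size=(30, 6, 143, 6))
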