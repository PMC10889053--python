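"""Chemical element tables shared across the package.

Only heavy elements matter here: hydrogens are stripped on input and never
reach the topological layers. Pauling electronegativities drive the default
orientation of directed hyperedges; atoms of more electronegative elements
come first in the vertex ordering.
"""

from __future__ import annotations

#: Pauling electronegativity, used as the default directed-hyperedge
#: orientation key. Elements missing from the table sort last (value 0.0).
PAULING_ELECTRONEGATIVITY: dict[str, float] = {
    "H": 2.20,
    "B": 2.04,
    "C": 2.55,
    "N": 3.04,
    "O": 3.44,
    "F": 3.98,
    "Na": 0.93,
    "Mg": 1.31,
    "P": 2.19,
    "S": 2.58,
    "Cl": 3.16,
    "K": 0.82,
    "Ca": 1.00,
    "Mn": 1.55,
    "Fe": 1.83,
    "Co": 1.88,
    "Ni": 1.91,
    "Cu": 1.90,
    "Zn": 1.65,
    "Se": 2.55,
    "Br": 2.96,
    "I": 2.66,
}

#: Heavy elements tracked on the protein side of the interface.
PROTEIN_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S")

#: Heavy elements tracked on the ligand side of the interface.
LIGAND_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")

_HYDROGEN = frozenset({"H", "D", "T"})


def normalize_element(symbol: str) -> str:
    """Normalize an element symbol to canonical capitalization.

    ``"CL"`` -> ``"Cl"``, ``" c"`` -> ``"C"``. Sybyl atom types such as
    ``"C.3"`` or ``"N.ar"`` are reduced to their element part.
    """
    s = symbol.strip().split(".")[0]
    if not s:
        raise ValueError(f"empty element symbol: {symbol!r}")
    return s[0].upper() + s[1:].lower()


def is_hydrogen(symbol: str) -> bool:
    return normalize_element(symbol) in _HYDROGEN


def electronegativity(symbol: str) -> float:
    return PAULING_ELECTRONEGATIVITY.get(normalize_element(symbol), 0.0)
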