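"""Directed hypergraphs (hyperdigraphs) from point clouds, with chain algebra.

A k-directed hyperedge is an ordered tuple of k+1 distinct vertices; a
hyperdigraph is a graded collection of such tuples over a vertex set. The
ambient chain group C_k(V) is freely generated by *all* ordered (k+1)-tuples,
with the alternating-sign boundary

    d(x_0, ..., x_k) = sum_i (-1)^i (x_0, ..., x_i-hat, ..., x_k),

where each face is an ordered subtuple (distinct tuples are distinct,
orthonormal generators; reversing a tuple does not negate it). F_k denotes
the span of the stored k-edges and

    Omega_k = { x in span(F_k) : d x in span(F_{k-1}) }

is the admissible chain space on which the Laplacians act.

The Vietoris-Rips hyperdigraph at scale eta keeps every vertex subset whose
diameter (max pairwise distance) is <= eta, ordered by an orientation rule.
The default rule sorts vertices by descending Pauling electronegativity with
the vertex index as tie-break, so directions encode element differences; on
bare point clouds it degenerates to index order. VR output is closed under
faces, hence Omega_k = span(F_k) there; the general Omega machinery matters
for hand-built hyperdigraphs with missing faces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.linalg import null_space
from scipy.spatial.distance import squareform, pdist

from .elements import electronegativity

#: Rank / null-space decision tolerance for chain-space computations.
RANK_TOL = 1e-8

Edge = tuple[int, ...]


@dataclass(frozen=True)
class OrientationRule:
    """Total order on vertices used to orient hyperedges.

    ``key(v)`` must be a sortable value; ties are always broken by the
    vertex index, so the induced order is total and deterministic.
    """

    key: Callable[[int], object]
    name: str = "custom"

    def orient(self, vertices: Iterable[int]) -> Edge:
        return tuple(sorted(vertices, key=lambda v: (self.key(v), v)))

    @classmethod
    def by_index(cls) -> "OrientationRule":
        return cls(key=lambda v: 0, name="index")

    @classmethod
    def by_electronegativity(cls, elements: Sequence[str]) -> "OrientationRule":
        """More electronegative atoms first; vertex index breaks ties."""
        chi = [electronegativity(e) for e in elements]
        return cls(key=lambda v: -chi[v], name="electronegativity")


class Hyperdigraph:
    """Graded sets of directed hyperedges over ``n_vertices`` vertices."""

    def __init__(self, n_vertices: int,
                 edges: dict[int, Sequence[Edge]] | None = None,
                 weights: dict[Edge, float] | None = None) -> None:
        self.n_vertices = int(n_vertices)
        self.edges: dict[int, list[Edge]] = {}
        self.weights = dict(weights) if weights else None
        for k, es in (edges or {}).items():
            for e in es:
                self.add_edge(e, dim=k)

    def add_edge(self, edge: Edge, dim: int | None = None) -> None:
        edge = tuple(int(v) for v in edge)
        k = len(edge) - 1
        if dim is not None and dim != k:
            raise ValueError(f"edge {edge} has dimension {k}, not {dim}")
        if len(set(edge)) != len(edge):
            raise ValueError(f"repeated vertex in hyperedge {edge}")
        if edge and max(edge) >= self.n_vertices:
            raise ValueError(f"vertex index out of range in {edge}")
        bucket = self.edges.setdefault(k, [])
        if edge not in bucket:
            bucket.append(edge)

    def edge_list(self, k: int) -> list[Edge]:
        return list(self.edges.get(k, []))

    @property
    def max_dim(self) -> int:
        populated = [k for k, es in self.edges.items() if es]
        return max(populated) if populated else -1

    def contains(self, other: "Hyperdigraph") -> bool:
        """True if every hyperedge of ``other`` is also an edge of self."""
        for k, es in other.edges.items():
            mine = set(self.edges.get(k, []))
            if not set(es) <= mine:
                return False
        return True

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hyperdigraph):
            return NotImplemented
        return (self.n_vertices == other.n_vertices
                and {k: set(v) for k, v in self.edges.items() if v}
                == {k: set(v) for k, v in other.edges.items() if v})

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_vertices": self.n_vertices,
            "edges": {str(k): [list(e) for e in es] for k, es in self.edges.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "Hyperdigraph":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(text_or_path)
        payload = json.loads(text)
        edges = {int(k): [tuple(e) for e in es] for k, es in payload["edges"].items()}
        return cls(n_vertices=payload["n_vertices"], edges=edges)


def vr_hyperdigraph(points: np.ndarray, eta: float, max_dim: int = 2,
                    orientation: OrientationRule | None = None,
                    weight: str = "diameter") -> Hyperdigraph:
    """Vietoris-Rips hyperdigraph of a point cloud at scale ``eta``.

    Every vertex subset of size <= max_dim+1 whose weight is <= eta becomes
    exactly one directed hyperedge, oriented by ``orientation``. The weight
    of a subset is its diameter (max pairwise distance) by default, or half
    of it with ``weight="radius"``. All 0-edges are always present and the
    result is closed under faces.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    dmat = squareform(pdist(points)) if n > 1 else np.zeros((n, n))
    return vr_hyperdigraph_from_distances(dmat, eta, max_dim=max_dim,
                                          orientation=orientation, weight=weight)


def vr_hyperdigraph_from_distances(dmat: np.ndarray, eta: float, max_dim: int = 2,
                                   orientation: OrientationRule | None = None,
                                   weight: str = "diameter") -> Hyperdigraph:
    """VR hyperdigraph from a (possibly infinite-entry) distance matrix."""
    if eta < 0:
        raise ValueError("eta must be >= 0")
    if weight not in ("diameter", "radius"):
        raise ValueError("weight must be 'diameter' or 'radius'")
    scale = 1.0 if weight == "diameter" else 0.5
    dmat = np.asarray(dmat, dtype=float)
    n = dmat.shape[0]
    rule = orientation or OrientationRule.by_index()
    hd = Hyperdigraph(n_vertices=n)
    weights: dict[Edge, float] = {}
    for v in range(n):
        hd.add_edge((v,))
        weights[(v,)] = 0.0
    # adjacency at scale eta; only subsets whose pairs are all adjacent qualify
    adj = (dmat * scale <= eta) & ~np.eye(n, dtype=bool)
    adj &= np.isfinite(dmat)
    for k in range(1, max_dim + 1):
        for subset in combinations(range(n), k + 1):
            idx = np.array(subset)
            sub = adj[np.ix_(idx, idx)]
            if sub[np.triu_indices(k + 1, 1)].all():
                e = rule.orient(subset)
                hd.add_edge(e)
                weights[e] = float(np.max(dmat[np.ix_(idx, idx)]) * scale)
    hd.weights = weights
    return hd


def ambient_boundary(edge: Edge) -> list[tuple[Edge, int]]:
    """Faces of an ordered tuple with alternating signs (+, -, +, ...)."""
    if len(edge) <= 1:
        return []
    return [
        (edge[:i] + edge[i + 1:], 1 if i % 2 == 0 else -1)
        for i in range(len(edge))
    ]


@dataclass
class OmegaBasis:
    """Orthonormal basis of Omega_k expressed in F_k (edge-list) coordinates."""

    dimension: int
    edges: list[Edge]
    basis: np.ndarray  # shape (|F_k|, dim Omega_k), orthonormal columns

    @property
    def dim(self) -> int:
        return self.basis.shape[1]


def omega_basis(hd: Hyperdigraph, k: int, tol: float = RANK_TOL) -> OmegaBasis:
    """Orthonormal basis of {x in span(F_k) : d x in span(F_{k-1})}.

    Computed as the null space of the boundary components landing on face
    tuples *outside* F_{k-1}. For face-closed hyperdigraphs (VR output) there
    are no such components and Omega_k = span(F_k).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    edges = hd.edge_list(k)
    m = len(edges)
    if m == 0:
        return OmegaBasis(dimension=k, edges=[], basis=np.zeros((0, 0)))
    if k == 0:
        return OmegaBasis(dimension=0, edges=edges, basis=np.eye(m))
    lower = set(hd.edge_list(k - 1))
    bad_rows: dict[Edge, int] = {}
    entries: list[tuple[int, int, int]] = []
    for j, e in enumerate(edges):
        for face, sign in ambient_boundary(e):
            if face not in lower:
                i = bad_rows.setdefault(face, len(bad_rows))
                entries.append((i, j, sign))
    if not bad_rows:
        return OmegaBasis(dimension=k, edges=edges, basis=np.eye(m))
    constraint = np.zeros((len(bad_rows), m))
    for i, j, sign in entries:
        constraint[i, j] += sign
    basis = null_space(constraint, rcond=tol)
    return OmegaBasis(dimension=k, edges=edges, basis=basis)


def boundary_matrix(hd: Hyperdigraph, k: int, tol: float = RANK_TOL) -> np.ndarray:
    """Matrix of d_k : Omega_k -> Omega_{k-1} in the orthonormal Omega bases.

    d_0 is the empty map: the returned matrix has zero rows for k = 0 and
    zero columns when dimension k has no admissible chains. The composite
    B_k @ B_{k+1} vanishes to numerical tolerance (chain-complex identity).
    """
    omega_k = omega_basis(hd, k, tol=tol)
    if k == 0:
        return np.zeros((0, omega_k.dim))
    omega_km1 = omega_basis(hd, k - 1, tol=tol)
    if omega_k.dim == 0 or omega_km1.dim == 0:
        return np.zeros((omega_km1.dim, omega_k.dim))
    row_index = {e: i for i, e in enumerate(omega_km1.edges)}
    ambient = np.zeros((len(omega_km1.edges), len(omega_k.edges)))
    for j, e in enumerate(omega_k.edges):
        for face, sign in ambient_boundary(e):
            i = row_index.get(face)
            if i is not None:
                ambient[i, j] += sign
    # components on faces outside F_{k-1} vanish on Omega_k, so projecting
    # onto the stored rows is exact
    return omega_km1.basis.T @ ambient @ omega_k.basis
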