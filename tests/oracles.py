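"""Independent rank-nullity homology oracles for the test suite.

These build boundary matrices directly from edge tuples over the full chain
groups and compute Betti numbers by rank-nullity, and persistent Betti
numbers by the cycle/boundary subspace-intersection formula. They share no
code with the package's Omega-basis / Laplacian path, so agreement between
the two is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def faces_with_signs(edge: tuple[int, ...]):
    for i in range(len(edge)):
        yield edge[:i] + edge[i + 1:], (-1.0) ** i


def chain_boundary_matrix(edges_k: list, edges_km1: list) -> np.ndarray:
    """Boundary matrix with rows the (k-1)-edges and columns the k-edges.

    Faces absent from ``edges_km1`` are simply dropped, which is exact for
    face-closed complexes (the only ones these oracles are applied to).
    """
    rows = {e: i for i, e in enumerate(edges_km1)}
    mat = np.zeros((len(edges_km1), len(edges_k)))
    for j, e in enumerate(edges_k):
        for face, sign in faces_with_signs(e):
            i = rows.get(face)
            if i is not None:
                mat[i, j] += sign
    return mat


def _rank(mat: np.ndarray, tol: float = 1e-8) -> int:
    if mat.size == 0:
        return 0
    return int(np.linalg.matrix_rank(mat, tol=tol))


def betti_oracle(edges_by_dim: dict[int, list], k: int) -> int:
    """beta_k = dim C_k - rank d_k - rank d_{k+1} (rank-nullity)."""
    e_k = edges_by_dim.get(k, [])
    if not e_k:
        return 0
    e_km1 = edges_by_dim.get(k - 1, []) if k > 0 else []
    e_kp1 = edges_by_dim.get(k + 1, [])
    d_k = chain_boundary_matrix(e_k, e_km1) if k > 0 else np.zeros((0, len(e_k)))
    d_kp1 = chain_boundary_matrix(e_kp1, e_k)
    return len(e_k) - _rank(d_k) - _rank(d_kp1)


def _null_basis(mat: np.ndarray, n_cols: int, tol: float = 1e-8) -> np.ndarray:
    if mat.size == 0:
        return np.eye(n_cols)
    _, s, vt = np.linalg.svd(mat, full_matrices=True)
    rank = int(np.sum(s > tol * max(mat.shape)))
    return vt[rank:].T


def persistent_betti_oracle(edges_a: dict[int, list], edges_b: dict[int, list],
                            k: int) -> int:
    """beta_k^{a,b} = dim Z_k^a - dim(Z_k^a intersect B_k^b).

    Cycles of the smaller complex that die as boundaries in the larger one
    are removed; everything is expressed in the C_k coordinates of the
    larger complex.
    """
    e_k_a = edges_a.get(k, [])
    if not e_k_a:
        return 0
    e_k_b = edges_b.get(k, [])
    col_b = {e: i for i, e in enumerate(e_k_b)}
    # cycles of the a-complex
    d_k_a = (chain_boundary_matrix(e_k_a, edges_a.get(k - 1, []))
             if k > 0 else np.zeros((0, len(e_k_a))))
    z_a = _null_basis(d_k_a, len(e_k_a))
    # embed a-cycles into b-coordinates
    embed = np.zeros((len(e_k_b), len(e_k_a)))
    for j, e in enumerate(e_k_a):
        embed[col_b[e], j] = 1.0
    z_in_b = embed @ z_a
    # boundaries coming from the b-complex
    d_kp1_b = chain_boundary_matrix(edges_b.get(k + 1, []), e_k_b)
    dim_z = _rank(z_in_b)
    dim_b = _rank(d_kp1_b)
    if dim_b == 0:
        return dim_z
    joint = _rank(np.hstack([z_in_b, d_kp1_b]))
    dim_intersection = dim_z + dim_b - joint
    return dim_z - dim_intersection


def connected_components_oracle(dmat: np.ndarray, threshold: float) -> int:
    """Union-find component count of the threshold graph of a distance matrix."""
    n = dmat.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(dmat[i, j]) and dmat[i, j] <= threshold:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})
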