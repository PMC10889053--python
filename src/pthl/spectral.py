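"""Combinatorial and persistent hyperdigraph Laplacians and their spectra.

The k-th combinatorial Laplacian on the admissible chain space Omega_k is

    L_k = B_{k+1} B_{k+1}^T + B_k^T B_k,

with B_k the boundary matrix between orthonormal Omega bases; in particular
L_0 = B_1 B_1^T, which for a 1-dimensional hyperdigraph equals the graph
Laplacian D - A of the underlying undirected graph for any orientation.
L_k is symmetric positive semidefinite; the multiplicity of its zero
eigenvalue is the k-th Betti number (components, loops, cavities for
k = 0, 1, 2), while the positive (non-harmonic) spectrum carries geometry.

For nested hyperdigraphs H_a <= H_b the persistent Laplacian couples the two
scales:

    Delta_k^{a,b} = d_{k+1}^{a,b} (d_{k+1}^{a,b})^* + (d_k^a)^* d_k^a,

where d_{k+1}^{a,b} is the boundary of H_b restricted to the chains of
Omega_{k+1}^b whose boundary already lies in Omega_k^a. Its kernel dimension
is the persistent Betti number beta_k^{a,b}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigvalsh, null_space

from .hyperdigraph import (
    RANK_TOL,
    Hyperdigraph,
    ambient_boundary,
    boundary_matrix,
    omega_basis,
)

#: Relative zero-eigenvalue threshold: |lambda| < tol * max(1, lambda_max).
ZERO_TOL = 1e-8


@dataclass
class LaplacianSpectrum:
    """Eigenvalues of L_k, sorted ascending, with exact zeros resolved."""

    dimension: int
    eigenvalues: np.ndarray
    zero_tolerance: float = ZERO_TOL

    @property
    def zero_multiplicity(self) -> int:
        return int(np.count_nonzero(self.eigenvalues == 0.0))

    @property
    def positive(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues > 0.0]


@dataclass
class SpectralSummary:
    """The six statistics of an L_0 spectrum used by the embedding.

    Zero multiplicity, then mean / population standard deviation / min /
    max / sum of the strictly positive eigenvalues. When no positive
    eigenvalue exists all five positive statistics are 0.
    """

    zero_multiplicity: int
    mean_pos: float
    std_pos: float
    min_pos: float
    max_pos: float
    sum_pos: float

    def as_vector(self) -> np.ndarray:
        return np.array([
            self.zero_multiplicity, self.mean_pos, self.std_pos,
            self.min_pos, self.max_pos, self.sum_pos,
        ])


def laplacian(hd: Hyperdigraph, k: int, tol: float = RANK_TOL) -> np.ndarray:
    """Dense symmetric matrix of L_k on Omega_k (0x0 when Omega_k = 0)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    b_up = boundary_matrix(hd, k + 1, tol=tol)
    if k == 0:
        mat = b_up @ b_up.T
    else:
        b_down = boundary_matrix(hd, k, tol=tol)
        mat = b_up @ b_up.T + b_down.T @ b_down
    return (mat + mat.T) / 2.0


def spectrum(matrix: np.ndarray, zero_tol: float = ZERO_TOL,
             dimension: int = 0) -> LaplacianSpectrum:
    """Ascending eigenvalues with near-zero values snapped to exactly 0.

    Raises if the matrix is asymmetric beyond tolerance or indefinite beyond
    the zero threshold.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        return LaplacianSpectrum(dimension=dimension, eigenvalues=np.zeros(0),
                                 zero_tolerance=zero_tol)
    scale = max(1.0, float(np.abs(matrix).max()))
    if not np.allclose(matrix, matrix.T, atol=zero_tol * scale):
        raise ValueError("matrix is not symmetric to tolerance")
    eigs = eigvalsh((matrix + matrix.T) / 2.0)
    threshold = zero_tol * max(1.0, float(eigs[-1]) if len(eigs) else 1.0)
    if eigs.size and eigs[0] < -threshold:
        raise ValueError(f"matrix is not positive semidefinite: lambda_min={eigs[0]}")
    eigs = np.where(np.abs(eigs) < threshold, 0.0, eigs)
    eigs = np.clip(eigs, 0.0, None)
    return LaplacianSpectrum(dimension=dimension, eigenvalues=np.sort(eigs),
                             zero_tolerance=zero_tol)


def summarize(spec: LaplacianSpectrum) -> SpectralSummary:
    """The six embedding statistics of a spectrum."""
    pos = spec.positive
    if pos.size == 0:
        return SpectralSummary(spec.zero_multiplicity, 0.0, 0.0, 0.0, 0.0, 0.0)
    return SpectralSummary(
        zero_multiplicity=spec.zero_multiplicity,
        mean_pos=float(pos.mean()),
        std_pos=float(pos.std()),  # population std
        min_pos=float(pos.min()),
        max_pos=float(pos.max()),
        sum_pos=float(pos.sum()),
    )


def betti(hd: Hyperdigraph, k: int) -> int:
    """k-th Betti number as the zero multiplicity of L_k."""
    return spectrum(laplacian(hd, k), dimension=k).zero_multiplicity


def persistent_laplacian(hd_a: Hyperdigraph, hd_b: Hyperdigraph, k: int,
                         tol: float = RANK_TOL) -> np.ndarray:
    """Matrix of the persistent Laplacian Delta_k^{a,b} on Omega_k^a.

    Requires hd_a to be contained in hd_b (every edge of a is an edge of b).
    The up-persistent term restricts the boundary of hd_b to

        Omega_{k+1}^{a,b} = { x in Omega_{k+1}^b : d x in Omega_k^a },

    computed as a null space after projecting the ambient boundary image
    onto the orthogonal complement of Omega_k^a. For hd_a == hd_b this
    reduces to ``laplacian(hd_a, k)``.
    """
    if not hd_b.contains(hd_a):
        raise ValueError("hd_a is not contained in hd_b")
    omega_a = omega_basis(hd_a, k, tol=tol)
    b_down = boundary_matrix(hd_a, k, tol=tol)
    down_term = b_down.T @ b_down
    if omega_a.dim == 0:
        return np.zeros((0, 0))

    omega_b_up = omega_basis(hd_b, k + 1, tol=tol)
    if omega_b_up.dim == 0:
        mat = down_term
        return (mat + mat.T) / 2.0

    # ambient tuple space: faces of F_{k+1}^b together with F_k^a
    ambient_index: dict[tuple[int, ...], int] = {}
    for e in omega_a.edges:
        ambient_index.setdefault(e, len(ambient_index))
    cols = []
    for e in omega_b_up.edges:
        col: dict[int, float] = {}
        for face, sign in ambient_boundary(e):
            i = ambient_index.setdefault(face, len(ambient_index))
            col[i] = col.get(i, 0.0) + sign
        cols.append(col)
    n_amb = len(ambient_index)
    bdry = np.zeros((n_amb, len(omega_b_up.edges)))
    for j, col in enumerate(cols):
        for i, v in col.items():
            bdry[i, j] = v
    image = bdry @ omega_b_up.basis  # ambient rep of d on Omega_{k+1}^b

    # Omega_k^a embedded in the ambient coordinates (orthonormal columns)
    embed = np.zeros((n_amb, len(omega_a.edges)))
    for j, e in enumerate(omega_a.edges):
        embed[ambient_index[e], j] = 1.0
    u = embed @ omega_a.basis

    residual = image - u @ (u.T @ image)
    if residual.size == 0 or np.linalg.norm(residual) < tol:
        z = np.eye(omega_b_up.dim)
    else:
        z = null_space(residual, rcond=tol)
    persistent_b = u.T @ image @ z  # Omega_{k+1}^{a,b} -> Omega_k^a
    mat = persistent_b @ persistent_b.T + down_term
    return (mat + mat.T) / 2.0


def spectral_summary(hd: Hyperdigraph, k: int = 0) -> SpectralSummary:
    """Convenience: L_k spectrum statistics of a hyperdigraph."""
    return summarize(spectrum(laplacian(hd, k), dimension=k))
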