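"""Laplacian assembly, spectra, Betti numbers and persistent Laplacians."""

import numpy as np
import pytest

from oracles import betti_oracle, persistent_betti_oracle
from pthl.hyperdigraph import Hyperdigraph, OrientationRule, vr_hyperdigraph
from pthl.spectral import (
    betti,
    laplacian,
    persistent_laplacian,
    spectrum,
    summarize,
)
from pthl.synthetic import canonical_shape, random_cloud


def _path3():
    return vr_hyperdigraph(np.array([[0, 0, 0], [1, 0, 0], [2.0, 0, 0]]),
                           eta=1.0, max_dim=1)


def test_path_graph_l0_is_degree_minus_adjacency():
    np.testing.assert_allclose(
        laplacian(_path3(), 0),
        [[1, -1, 0], [-1, 2, -1], [0, -1, 1]],
        atol=1e-12,
    )


def test_empty_edge_set_gives_zero_l0():
    hd = Hyperdigraph(4, edges={0: [(v,) for v in range(4)]})
    np.testing.assert_allclose(laplacian(hd, 0), np.zeros((4, 4)))


def test_filled_triangle_l1_spectrum_is_all_threes():
    coords, meta = canonical_shape("filled_triangle")
    hd = vr_hyperdigraph(coords, eta=meta["eta"], max_dim=2)
    eigs = spectrum(laplacian(hd, 1), dimension=1).eigenvalues
    np.testing.assert_allclose(eigs, [3.0, 3.0, 3.0], atol=1e-9)


@pytest.mark.parametrize("matrix, expected", [
    ([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], [0.0, 1.0, 3.0]),
    (np.zeros((4, 4)), [0.0] * 4),
    ([[1, -1], [-1, 1]], [0.0, 2.0]),
])
def test_spectrum_known_eigenvalues(matrix, expected):
    np.testing.assert_allclose(spectrum(np.array(matrix, dtype=float)).eigenvalues,
                               expected, atol=1e-9)


def test_spectrum_rejects_asymmetric_input():
    with pytest.raises(ValueError):
        spectrum(np.array([[0.0, 1.0], [0.0, 0.0]]))


@pytest.mark.parametrize("eigs, expected", [
    ([0.0, 2.0], (1, 2, 0, 2, 2, 2)),
    ([0.0] * 4, (4, 0, 0, 0, 0, 0)),
    ([0.0, 1.0, 3.0], (1, 2, 1, 1, 3, 4)),  # mean 2, population std 1
])
def test_summary_statistics(eigs, expected):
    summary = summarize(spectrum(np.diag(eigs)))
    np.testing.assert_allclose(summary.as_vector(), expected)


def test_betti_counts_components_and_cycles():
    two_points = Hyperdigraph(2, edges={0: [(0,), (1,)]})
    assert betti(two_points, 0) == 2

    coords, meta = canonical_shape("circle_8")
    circle = vr_hyperdigraph(coords, eta=meta["eta"], max_dim=1)
    assert betti(circle, 0) == 1
    assert betti(circle, 1) == 1

    coords, meta = canonical_shape("filled_triangle")
    filled = vr_hyperdigraph(coords, eta=meta["eta"], max_dim=2)
    assert betti(filled, 1) == 0


def test_betti_matches_rank_nullity_oracle_on_random_clouds():
    for seed in range(12):
        hd = vr_hyperdigraph(random_cloud(9, box=2.2, seed=seed), eta=1.4, max_dim=3)
        for k in range(3):
            assert betti(hd, k) == betti_oracle(hd.edges, k), (seed, k)


def test_persistent_laplacian_reduces_to_laplacian_at_equal_scales():
    hd = vr_hyperdigraph(random_cloud(7, seed=4), eta=1.6, max_dim=2)
    for k in range(2):
        np.testing.assert_allclose(persistent_laplacian(hd, hd, k),
                                   laplacian(hd, k), atol=1e-9)


def test_persistent_kernel_k0_path_into_triangle():
    pts = np.array([[0, 0, 0], [1, 0, 0], [2.0, 0, 0]])
    hd_a = vr_hyperdigraph(pts, eta=1.0, max_dim=1)   # path: 2 edges
    hd_b = vr_hyperdigraph(pts, eta=2.0, max_dim=1)   # all three edges
    delta = persistent_laplacian(hd_a, hd_b, 0)
    assert spectrum(delta).zero_multiplicity == 1
    assert spectrum(delta).zero_multiplicity == persistent_betti_oracle(hd_a.edges, hd_b.edges, 0)


def test_persistent_kernel_k1_loop_dies_under_cone():
    coords, meta = canonical_shape("circle_8")
    augmented = np.vstack([coords, [[0.0, 0.0, 0.1]]])
    far = np.vstack([coords, [[50.0, 50.0, 50.0]]])
    hd_a = vr_hyperdigraph(far, eta=meta["eta"], max_dim=1)       # loop alive
    hd_b = vr_hyperdigraph(augmented, eta=2.5, max_dim=2)         # coned off
    assert hd_b.contains(hd_a)
    delta = persistent_laplacian(hd_a, hd_b, 1)
    assert spectrum(delta).zero_multiplicity == 0
    assert persistent_betti_oracle(hd_a.edges, hd_b.edges, 1) == 0


def test_persistent_requires_containment():
    pts = np.array([[0, 0, 0], [1.0, 0, 0]])
    hd_small = vr_hyperdigraph(pts, eta=0.5, max_dim=1)
    hd_large = vr_hyperdigraph(pts, eta=1.0, max_dim=1)
    with pytest.raises(ValueError):
        persistent_laplacian(hd_large, hd_small, 0)


def test_persistent_kernel_monotone_in_larger_scale():
    points = random_cloud(9, box=2.0, seed=8)
    eta_a = 0.9
    hd_a = vr_hyperdigraph(points, eta=eta_a, max_dim=2)
    previous = None
    for eta_b in (0.9, 1.2, 1.5, 2.0, 3.0):
        hd_b = vr_hyperdigraph(points, eta=eta_b, max_dim=2)
        kernel = spectrum(persistent_laplacian(hd_a, hd_b, 0)).zero_multiplicity
        if previous is not None:
            assert kernel <= previous
        previous = kernel


def test_laplacians_psd_and_l0_degree_bounded():
    """All L_k are PSD; lambda_0^max <= 2 d_0 with d_0 the max vertex degree.

    The factor-2 degree bound is specific to the graph Laplacian L_0; for
    k >= 1 the spectral radius can exceed twice the cofacet count (the
    filled triangle has L_1 eigenvalues 3 with a single cofacet per edge).
    """
    for seed in range(10):
        hd = vr_hyperdigraph(random_cloud(8, box=2.0, seed=seed), eta=1.3, max_dim=2)
        for k in range(3):
            mat = laplacian(hd, k)
            if mat.size == 0:
                continue
            assert np.linalg.eigvalsh(mat).min() >= -1e-8
        l0 = laplacian(hd, 0)
        degree = np.zeros(hd.n_vertices)
        for (i, j) in hd.edge_list(1):
            degree[i] += 1
            degree[j] += 1
        if degree.max() > 0:
            assert np.linalg.eigvalsh(l0).max() <= 2 * degree.max() + 1e-8


def test_graph_laplacian_equivalence_any_orientation():
    """L_0 = D - A of the underlying graph for arbitrary edge orientations."""
    rng = np.random.default_rng(0)
    for trial in range(10):
        n = int(rng.integers(3, 9))
        adjacency = np.zeros((n, n))
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.5:
                    adjacency[i, j] = adjacency[j, i] = 1
                    edges.append((j, i) if rng.random() < 0.5 else (i, j))
        hd = Hyperdigraph(n, edges={0: [(v,) for v in range(n)], 1: edges})
        expected = np.diag(adjacency.sum(axis=1)) - adjacency
        np.testing.assert_allclose(laplacian(hd, 0), expected, atol=1e-10)
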