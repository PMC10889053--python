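"""Element scheme, filtration schedules and the topological sequence tensor."""

import numpy as np
import pytest

from oracles import connected_components_oracle
from pthl.embedding import (
    ElementScheme,
    FiltrationSchedule,
    TopologicalSequence,
    cross_distance_matrix,
    element_scheme,
    embed_complex,
    load_sequence,
    preset,
    save_sequence,
)
from pthl.hyperdigraph import vr_hyperdigraph_from_distances
from pthl.spectral import laplacian, spectrum, summarize
from pthl.structure import LIGAND, PROTEIN
from conftest import make_region


def test_scheme_counts():
    scheme = element_scheme()
    assert len(scheme.protein_sets) == 11
    assert len(scheme.ligand_sets) == 13
    assert scheme.n_combos == 143


def test_scheme_combo_order_and_labels():
    scheme = element_scheme()
    labels = scheme.labels()
    assert labels[0] == "protein:C|ligand:C"
    assert scheme.combo_index(1, 0) == 13  # protein-major ordering
    assert labels[13].startswith("protein:N|")


@pytest.mark.parametrize("name, n_steps, last", [
    ("large", 100, 10.0),
    ("small", 50, 12.0),
])
def test_presets(name, n_steps, last):
    cutoff, schedule = preset(name)
    assert len(schedule) == n_steps
    assert schedule.grid[-1] == pytest.approx(last, abs=1e-9)
    assert np.all(np.diff(schedule.grid) > 0)
    assert cutoff == {"large": 20.0, "small": 12.0}[name]


def test_preset_unknown_name():
    with pytest.raises(ValueError):
        preset("medium")


def test_schedule_validation():
    with pytest.raises(ValueError):
        FiltrationSchedule(0.0, 10.0, -0.1)
    with pytest.raises(ValueError):
        FiltrationSchedule(2.0, 12.0, 0.3)  # step does not divide the span


def test_cross_distance_matrix_cases(cc_region):
    cdm = cross_distance_matrix(cc_region, {"C"}, {"C"})
    assert cdm.n_atoms == 2
    assert cdm.distances[0, 1] == pytest.approx(3.0)
    assert np.isinf(cdm.distances[0, 0])

    empty = cross_distance_matrix(cc_region, {"N"}, {"C"})
    assert empty.n_atoms == 0

    region = make_region([
        ("C", (0, 0, 0), PROTEIN),
        ("C", (0, 1, 0), PROTEIN),
        ("O", (0, 0, 2), LIGAND),
    ])
    cdm = cross_distance_matrix(region, {"C"}, {"O"})
    assert np.isinf(cdm.distances[0, 1])  # protein-protein
    assert np.isfinite(cdm.distances[0, 2]) and np.isfinite(cdm.distances[1, 2])


def test_worked_example_k2_signature(cc_region):
    """One protein C at 3.0 A from one ligand C: below 3.0 the combo shows
    two components, at/above it the K2 spectrum {0, 2}; exactly the 25
    C-containing combos are populated."""
    _, schedule = preset("small")
    seq = embed_complex(cc_region, schedule=schedule)
    scheme = element_scheme()
    grid = schedule.grid
    expected_combos = {
        ci for ci, pset, lset in scheme.combos() if "C" in pset and "C" in lset
    }
    assert len(expected_combos) == 25
    disconnected = np.array([2, 0, 0, 0, 0, 0], dtype=float)
    connected = np.array([1, 2, 0, 2, 2, 2], dtype=float)
    for ci in range(scheme.n_combos):
        for ti, d in enumerate(grid):
            value = seq.tensor[ti, ci]
            if ci in expected_combos:
                expected = connected if d >= 3.0 else disconnected
                np.testing.assert_allclose(value, expected, atol=1e-9,
                                           err_msg=f"combo {ci} at d={d}")
            else:
                np.testing.assert_allclose(value, 0.0, atol=1e-12)


def test_empty_region_gives_zero_tensor():
    region = make_region([], cutoff=12.0)
    _, schedule = preset("small")
    seq = embed_complex(region, schedule=schedule)
    assert seq.tensor.shape == (50, 143, 6)
    assert np.all(seq.tensor == 0.0)


def test_tensor_shape_small_preset(small_complex):
    seq = embed_complex(small_complex, preset_name="small")
    assert seq.tensor.shape == (50, 143, 6)
    assert np.all(np.isfinite(seq.tensor))


def test_zero_multiplicity_monotone_along_filtration(small_complex):
    seq = embed_complex(small_complex, preset_name="small")
    zero_mult = seq.tensor[:, :, 0]
    assert np.all(np.diff(zero_mult, axis=0) <= 1e-12)


def test_tensor_invariant_under_atom_permutation(small_complex):
    seq = embed_complex(small_complex, preset_name="small")
    rng = np.random.default_rng(1)
    atoms = list(small_complex.protein_atoms)
    rng.shuffle(atoms)
    from pthl.structure import MolecularComplex

    shuffled = MolecularComplex(small_complex.identifier, atoms,
                                small_complex.ligand_atoms)
    seq2 = embed_complex(shuffled, preset_name="small")
    np.testing.assert_allclose(seq.tensor, seq2.tensor, atol=1e-9)


def test_embedding_agrees_with_hyperdigraph_laplacian_route(small_complex):
    """The fast D - A evaluation must match the full VR-hyperdigraph path."""
    from pthl.structure import extract_region

    region = extract_region(small_complex, 12.0)
    scheme = element_scheme()
    _, schedule = preset("small")
    seq = embed_complex(region, schedule=schedule)
    rng = np.random.default_rng(0)
    combos = list(scheme.combos())
    for _ in range(6):
        ci, pset, lset = combos[rng.integers(len(combos))]
        ti = int(rng.integers(len(schedule)))
        d = schedule.grid[ti]
        cdm = cross_distance_matrix(region, pset, lset)
        if cdm.n_atoms == 0:
            np.testing.assert_allclose(seq.tensor[ti, ci], 0.0)
            continue
        hd = vr_hyperdigraph_from_distances(cdm.distances, eta=d, max_dim=1)
        expected = summarize(spectrum(laplacian(hd, 0))).as_vector()
        np.testing.assert_allclose(seq.tensor[ti, ci], expected, atol=1e-9)


def test_full_combo_components_match_union_find(small_complex):
    """At the last grid value the all-element combo's zero multiplicity is
    the component count of the threshold graph (union-find oracle)."""
    from pthl.structure import extract_region

    region = extract_region(small_complex, 12.0)
    scheme = element_scheme()
    seq = embed_complex(region, preset_name="small")
    ci = scheme.combo_index(10, 12)  # {C,N,O,S} x all-9
    cdm = cross_distance_matrix(region, scheme.protein_sets[10], scheme.ligand_sets[12])
    expected = connected_components_oracle(cdm.distances, 12.0)
    assert seq.tensor[-1, ci, 0] == expected


def test_pair_membership_counts_by_set_inclusion(cc_region):
    """A C-C protein-ligand pair contributes to exactly (supersets of C on
    each side)^2 = 5 x 5 combos."""
    scheme = element_scheme()
    count = 0
    for _, pset, lset in scheme.combos():
        cdm = cross_distance_matrix(cc_region, pset, lset)
        count += int(np.isfinite(cdm.distances).sum() // 2)
    n_p = sum("C" in s for s in scheme.protein_sets)
    n_l = sum("C" in s for s in scheme.ligand_sets)
    assert count == n_p * n_l == 25


def test_save_load_roundtrip_and_csv(tmp_path, cc_region):
    seq = embed_complex(cc_region, preset_name="small")
    path = tmp_path / "seq.h5"
    save_sequence(seq, path)
    loaded = load_sequence(path)
    np.testing.assert_array_equal(loaded.tensor, seq.tensor)
    assert loaded.cutoff == seq.cutoff
    assert loaded.scheme_version == seq.scheme_version
    assert loaded.source_id == seq.source_id
    assert len(loaded.schedule) == len(seq.schedule)

    df = seq.to_dataframe()
    assert len(df) == 50 * 143
    assert df["combo_label"].iloc[0] == "protein:C|ligand:C"

    bad = tmp_path / "bad.h5"
    bad.write_text("not hdf5")
    with pytest.raises(ValueError):
        load_sequence(bad)
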