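"""Scoring, ranking, docking and screening metrics."""

import numpy as np
import pandas as pd
import pytest

from pthl.evaluation import (
    KCAL_PER_LOG_UNIT,
    consensus,
    docking_success,
    load_table,
    ranking_power,
    rmsd,
    scoring_metrics,
    screening_metrics,
)


def test_scoring_perfect_and_anticorrelated():
    expt = np.array([2.0, 5.0, 7.5, 9.0])
    perfect = scoring_metrics(expt, expt)
    assert perfect.pcc == pytest.approx(1.0)
    assert perfect.rmse == pytest.approx(0.0)
    assert scoring_metrics(-expt, expt).pcc == pytest.approx(-1.0)


def test_scoring_kcal_conversion():
    expt = np.array([1.0, 2.0, 3.0])
    pred = expt + 1.0  # RMSE exactly 1 in -log units
    res = scoring_metrics(pred, expt)
    assert res.rmse == pytest.approx(1.0)
    assert res.rmse_kcal == pytest.approx(1.3633)
    assert KCAL_PER_LOG_UNIT == 1.3633


def test_scoring_rejects_degenerate_input():
    with pytest.raises(ValueError):
        scoring_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        scoring_metrics([1.0], [2.0])


def _clusters(rows):
    return pd.DataFrame(rows, columns=["cluster_id", "complex_id", "expt", "pred"])


def test_ranking_perfect_and_reversed():
    rows = [(c, f"{c}{j}", j + c, j + c) for c in range(4) for j in range(3)]
    assert ranking_power(_clusters(rows)) == (1.0, 1.0)
    rows = [(c, f"{c}{j}", j, -j) for c in range(4) for j in range(3)]
    assert ranking_power(_clusters(rows)) == (0.0, 0.0)


def test_ranking_mixed_counts():
    """2 perfect clusters, 1 top-correct-only, 1 wrong -> (0.5, 0.75)."""
    rows = []
    for c in (0, 1):  # perfectly ordered
        rows += [(c, f"{c}{j}", j, j) for j in range(3)]
    rows += [(2, "2a", 3.0, 9.0), (2, "2b", 2.0, 1.0), (2, "2c", 1.0, 5.0)]  # top ok
    rows += [(3, "3a", 3.0, 1.0), (3, "3b", 2.0, 2.0), (3, "3c", 1.0, 3.0)]  # wrong
    assert ranking_power(_clusters(rows)) == (0.5, 0.75)


def test_ranking_ties_fail_high_level_by_default():
    rows = [(0, "a", 2.0, 2.0), (0, "b", 2.0, 1.0), (0, "c", 1.0, 0.5)]
    high, low = ranking_power(_clusters(rows))
    assert high == 0.0
    high_any, _ = ranking_power(_clusters(rows), tie_policy="any_order")
    assert high_any == 1.0


def test_ranking_requires_uniform_cluster_size():
    rows = [(0, "a", 1, 1), (0, "b", 2, 2), (1, "c", 1, 1)]
    with pytest.raises(ValueError):
        ranking_power(_clusters(rows))


def test_rmsd_cases():
    a = np.zeros((3, 3))
    assert rmsd(a, a) == 0.0
    assert rmsd(a, a + [2.0, 0, 0]) == pytest.approx(2.0)
    a = np.zeros((2, 3))
    b = np.array([[3.0, 0, 0], [0, 4.0, 0]])
    assert rmsd(a, b) == pytest.approx(np.sqrt((9 + 16) / 2))
    with pytest.raises(ValueError):
        rmsd(np.zeros((2, 3)), np.zeros((3, 3)))


def _poses(rows):
    return pd.DataFrame(rows, columns=["ligand_id", "pose_id", "rmsd", "score"])


def test_docking_threshold_strictly_below_two():
    assert docking_success(_poses([("l", 0, 1.6, 5.0), ("l", 1, 8.0, 1.0)])) == 1.0
    assert docking_success(_poses([("l", 0, 2.0, 5.0), ("l", 1, 8.0, 1.0)])) == 0.0


def test_docking_rate_over_ligands():
    rows = []
    for lig in range(10):
        native_top = lig < 7
        rows.append((f"l{lig}", 0, 1.0 if native_top else 5.0, 10.0))
        rows.append((f"l{lig}", 1, 1.0, 1.0))
    assert docking_success(_poses(rows)) == pytest.approx(0.7)


def test_docking_tie_break_by_pose_id():
    rows = [("l", 1, 5.0, 3.0), ("l", 0, 1.0, 3.0)]
    assert docking_success(_poses(rows)) == 1.0  # pose 0 wins the tie


def test_docking_invariant_under_monotone_score_transform():
    rng = np.random.default_rng(0)
    rows = [(f"l{i}", p, rng.uniform(0, 8), rng.normal())
            for i in range(6) for p in range(10)]
    df = _poses(rows)
    base = docking_success(df)
    warped = df.assign(score=np.exp(df["score"] / 2.0))
    assert docking_success(warped) == base


def _screens(rows, with_affinity=False):
    cols = ["target_id", "ligand_id", "is_binder", "s1", "s2"]
    if with_affinity:
        cols.append("affinity")
    return pd.DataFrame(rows, columns=cols)


def test_ef_single_target_formula():
    """100 candidates, 5 binders, the top candidate is a binder: EF_1% = 20."""
    rows = [("t", "hit", True, 10.0, 1.0)]
    rows += [("t", f"b{i}", True, 1.0, 0.1) for i in range(4)]
    rows += [("t", f"d{i}", False, 5.0, 0.5) for i in range(95)]
    out = screening_metrics(_screens(rows), alphas=(0.01,))
    assert out.loc[0, "ef"] == pytest.approx(1 / (5 * 0.01))
    assert out.loc[0, "success_rate"] == 1.0


def test_ef_zero_when_binders_rank_last():
    rows = [("t", f"d{i}", False, 10.0 - i * 0.01, 1.0) for i in range(98)]
    rows += [("t", f"b{i}", True, 0.0, 0.0) for i in range(2)]
    out = screening_metrics(_screens(rows), alphas=(0.01,))
    assert out.loc[0, "ef"] == 0.0
    assert out.loc[0, "success_rate"] == 0.0


def test_top_alpha_set_size_uses_ceiling():
    """195 candidates -> ceil(1.95) = 2 selected at 1%."""
    rows = [("t", f"c{i}", i < 2, 195.0 - i, 1.0) for i in range(195)]
    out = screening_metrics(_screens(rows), alphas=(0.01,))
    # both binders sit at ranks 1-2, so both are inside the top-1% set of 2
    assert out.loc[0, "ef"] == pytest.approx(2 / (2 * 0.01))


def test_ef_bounded_and_random_near_one():
    rng = np.random.default_rng(1)
    efs = []
    for seed in range(120):
        scores = rng.permutation(200).astype(float)
        rows = [("t", f"c{i}", i < 20, scores[i], 1.0) for i in range(200)]
        out = screening_metrics(_screens(rows), alphas=(0.10,))
        ef = out.loc[0, "ef"]
        assert 0.0 <= ef <= 1 / 0.10
        efs.append(ef)
    assert np.mean(efs) == pytest.approx(1.0, abs=3 * np.std(efs) / np.sqrt(len(efs)))


def test_screening_uses_best_binder_when_affinities_present():
    # best binder (affinity 9) ranks outside top-1, weaker binder inside
    rows = [
        ("t", "weak", True, 10.0, 1.0, 6.0),
        ("t", "best", True, 1.0, 1.0, 9.0),
    ] + [("t", f"d{i}", False, 5.0, 1.0, 2.0) for i in range(98)]
    out = screening_metrics(_screens(rows, with_affinity=True), alphas=(0.01,))
    assert out.loc[0, "success_rate"] == 0.0


def test_consensus_full_size_and_identical_models():
    rng = np.random.default_rng(2)
    expt = rng.normal(size=40)
    models = [expt + rng.normal(scale=0.5, size=40) for _ in range(5)]
    full = consensus(models, expt, size=5, repeats=10, seed=0)
    assert full["pcc"].nunique() == 1  # all repetitions identical
    same = consensus([models[0]] * 5, expt, size=3, repeats=10, seed=0)
    assert same["pcc"].std() == 0.0


def test_consensus_mean_pcc_nondecreasing_in_size():
    rng = np.random.default_rng(3)
    expt = rng.normal(size=60)
    models = [expt + rng.normal(scale=1.0, size=60) for _ in range(12)]
    means = [consensus(models, expt, size=s, repeats=80, seed=4)["pcc"].mean()
             for s in (1, 3, 6, 12)]
    assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


def test_consensus_validates_size():
    with pytest.raises(ValueError):
        consensus([np.arange(4.0)], np.arange(4.0), size=0)
    with pytest.raises(ValueError):
        consensus([np.arange(4.0)], np.arange(4.0), size=2)


def test_load_table_checks_columns(tmp_path):
    path = tmp_path / "c.csv"
    pd.DataFrame({"cluster_id": [0], "complex_id": ["a"], "expt": [1.0],
                  "pred": [1.0]}).to_csv(path, index=False)
    assert len(load_table(path, "clusters")) == 1
    bad = tmp_path / "bad.csv"
    pd.DataFrame({"x": [1]}).to_csv(bad, index=False)
    with pytest.raises(ValueError):
        load_table(bad, "poses")
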