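"""CASF-style evaluation: scoring, ranking, docking and screening power.

Tables are plain pandas DataFrames with documented columns:

* clusters: ``cluster_id, complex_id, expt, pred`` — clusters of complexes
  sharing a protein; used for ranking power.
* poses: ``ligand_id, pose_id, rmsd, score`` — candidate docking poses with
  their RMSD to the native pose; used for docking power.
* screens: ``target_id, ligand_id, is_binder, s1, s2`` (optional
  ``affinity``) — per-target candidate ligands with a regression score S1
  and a binder probability S2; ranked by S = S1 * S2 for screening power.

Affinities are in -log Kd/Ki units; the kcal/mol conversion multiplies by
1.3633. Docking success uses the strict 2 A native-pose threshold. The
top-alpha selection size is ceil(alpha * n), so at least one compound is
always selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

#: -log10(Kd) -> kcal/mol at room temperature.
KCAL_PER_LOG_UNIT = 1.3633

DEFAULT_ALPHAS = (0.01, 0.05, 0.10)


@dataclass
class ScoringResult:
    pcc: float
    rmse: float
    rmse_kcal: float


def scoring_metrics(pred, expt) -> ScoringResult:
    """Pearson correlation and RMSE (in -log units and kcal/mol)."""
    pred = np.asarray(pred, dtype=float)
    expt = np.asarray(expt, dtype=float)
    if pred.shape != expt.shape or pred.ndim != 1 or len(pred) < 2:
        raise ValueError("pred and expt must be equal-length vectors of length >= 2")
    if np.std(pred) == 0.0 or np.std(expt) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    pcc = float(pearsonr(pred, expt).statistic)
    rmse = float(np.sqrt(np.mean((pred - expt) ** 2)))
    return ScoringResult(pcc=pcc, rmse=rmse, rmse_kcal=KCAL_PER_LOG_UNIT * rmse)


def ranking_power(clusters: pd.DataFrame, tie_policy: str = "fail") -> tuple[float, float]:
    """High- and low-level ranking success rates over clusters.

    High-level success: the predicted affinities order every complex in the
    cluster exactly as the experimental ones. Low-level success: the
    top-affinity complex is also ranked first by the prediction. Clusters
    with tied experimental affinities count as failures for the high-level
    metric under the default tie policy.
    """
    if tie_policy not in ("fail", "any_order"):
        raise ValueError("tie_policy must be 'fail' or 'any_order'")
    sizes = clusters.groupby("cluster_id").size()
    if sizes.nunique() != 1:
        raise ValueError("cluster sizes must be uniform within a benchmark")
    high = low = 0
    groups = list(clusters.groupby("cluster_id"))
    for _, grp in groups:
        expt = grp["expt"].to_numpy(dtype=float)
        pred = grp["pred"].to_numpy(dtype=float)
        has_ties = len(np.unique(expt)) != len(expt)
        expt_order = np.argsort(-expt, kind="stable")
        pred_order = np.argsort(-pred, kind="stable")
        if pred_order[0] == expt_order[0]:
            low += 1
        if has_ties and tie_policy == "fail":
            continue
        if np.array_equal(expt_order, pred_order):
            high += 1
    n = len(groups)
    return high / n, low / n


def rmsd(coords_a, coords_b) -> float:
    """Root mean square deviation between two conformations (no fitting).

    Docking poses share the receptor frame, so no superposition is applied.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def docking_success(poses: pd.DataFrame, threshold: float = 2.0) -> float:
    """Fraction of ligands whose top-scored pose is native (RMSD < threshold).

    Score ties are broken deterministically by the lowest pose id.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    successes = 0
    groups = list(poses.groupby("ligand_id"))
    for _, grp in groups:
        grp = grp.sort_values(["score", "pose_id"], ascending=[False, True],
                              kind="stable")
        top = grp.iloc[0]
        if top["rmsd"] < threshold:
            successes += 1
    return successes / len(groups)


def screening_metrics(screens: pd.DataFrame,
                      alphas=DEFAULT_ALPHAS) -> pd.DataFrame:
    """Per-alpha screening success rate and enrichment factor.

    Candidates are ranked per target by S = S1 * S2 descending; the
    top-alpha set has ceil(alpha * n) members. Success at alpha is the
    fraction of targets whose best true binder (highest ``affinity`` when
    that column is present, else any binder) lands in the top-alpha set.
    EF_alpha is (binders in top alpha) / (total binders * alpha), averaged
    over targets.
    """
    records = []
    groups = list(screens.groupby("target_id"))
    for alpha in alphas:
        hits = 0
        efs = []
        for _, grp in groups:
            if len(grp) == 0:
                raise ValueError("empty candidate list")
            n_binders = int(grp["is_binder"].sum())
            if n_binders == 0:
                raise ValueError("every target needs at least one true binder")
            scores = grp["s1"].to_numpy(dtype=float) * grp["s2"].to_numpy(dtype=float)
            order = np.argsort(-scores, kind="stable")
            n_top = math.ceil(alpha * len(grp))
            top = grp.iloc[order[:n_top]]
            if "affinity" in grp.columns:
                binders = grp[grp["is_binder"].astype(bool)]
                best = binders.loc[binders["affinity"].idxmax(), "ligand_id"]
                if best in set(top["ligand_id"]):
                    hits += 1
            elif top["is_binder"].any():
                hits += 1
            efs.append(float(top["is_binder"].sum()) / (n_binders * alpha))
        records.append({
            "alpha": alpha,
            "success_rate": hits / len(groups),
            "ef": float(np.mean(efs)),
        })
    return pd.DataFrame(records)


def consensus(model_predictions, expt, size: int, repeats: int = 400,
              seed: int = 0) -> pd.DataFrame:
    """Metric distribution of random consensus averages of model predictions.

    Each repetition averages ``size`` randomly chosen prediction vectors
    (without replacement) and records PCC and RMSE against ``expt``.
    """
    preds = [np.asarray(p, dtype=float) for p in model_predictions]
    if size < 1:
        raise ValueError("consensus size must be >= 1")
    if size > len(preds):
        raise ValueError("consensus size exceeds the number of models")
    expt = np.asarray(expt, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        chosen = np.sort(rng.choice(len(preds), size=size, replace=False))
        avg = np.mean([preds[i] for i in chosen], axis=0)
        res = scoring_metrics(avg, expt)
        rows.append({"repeat": rep, "pcc": res.pcc, "rmse": res.rmse})
    return pd.DataFrame(rows)


# -- CSV loaders ----------------------------------------------------------

_TABLE_COLUMNS = {
    "clusters": ["cluster_id", "complex_id", "expt", "pred"],
    "poses": ["ligand_id", "pose_id", "rmsd", "score"],
    "screens": ["target_id", "ligand_id", "is_binder", "s1", "s2"],
}


def load_table(path, kind: str) -> pd.DataFrame:
    """Read an evaluation CSV and check its column contract."""
    if kind not in _TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table is missing columns: {missing}")
    return df
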