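"""Simulated multi-position training data from neutral statistics.

Given the neutral-position feature statistics and the fitted ratio-model
bank, a simulated dataset is drawn by sampling every feature column
independently from a normal distribution whose moments are the neutral
moments scaled by the bank's predicted ratios:

    mean = neutral_mean * mean_ratio(theta)     (or + difference)
    var  = neutral_var  * var_ratio(theta)      (clipped at the floor)

The "adjusted" dataset applies the predictions of all 13 positions; the
"unadjusted" control uses the neutral-position prediction everywhere. Row
counts mirror the reference real dataset. Feature independence is an
explicit modelling assumption: no cross-feature covariance is preserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, classification_error, fit, predict
from .features import FeatureMatrix
from .position_regression import (
    VAR_FLOOR,
    NeutralStats,
    RatioModelBank,
    rep_split_indices,
)
from .synthetic_emg import PositionGrid, WristPosition


def _draw(
    neutral: NeutralStats,
    grid: PositionGrid,
    n_per_cell: int,
    seed: int,
    ratio_fn,
    provenance: str,
) -> FeatureMatrix:
    rng = np.random.default_rng(seed)
    C = len(neutral.classes)
    F = len(neutral.columns)
    blocks, labels = [], []
    for p_idx, pos in enumerate(grid.positions):
        mean_r, var_r = ratio_fn(pos)  # (C, F) each
        for ci, cls in enumerate(neutral.classes):
            m = neutral.mean[ci] * mean_r[ci]
            if hasattr(ratio_fn, "diff_mode"):
                dm = ratio_fn.diff_mode[ci]
                m = np.where(dm, neutral.mean[ci] + mean_r[ci], m)
            v = np.maximum(neutral.variance[ci] * var_r[ci], VAR_FLOOR)
            blocks.append(
                rng.standard_normal((n_per_cell, F)) * np.sqrt(v) + m
            )
            labels.append(
                pd.DataFrame(
                    {
                        "class": cls,
                        "position_index": p_idx,
                        "rep_index": -1,
                        "window_index": np.arange(n_per_cell),
                    }
                )
            )
    return FeatureMatrix(
        X=np.concatenate(blocks, axis=0),
        columns=list(neutral.columns),
        labels=pd.concat(labels, ignore_index=True),
        provenance=provenance,
    )


def simulate_adjusted(
    neutral: NeutralStats,
    bank: RatioModelBank,
    grid: PositionGrid,
    n_per_cell: int,
    seed: int = 0,
) -> FeatureMatrix:
    """Simulated dataset with bank-predicted moments at every position."""
    if bank.columns != neutral.columns:
        raise ValueError("bank does not cover the feature columns")

    def ratio_fn(pos: WristPosition):
        out = bank.predict(pos)
        return out["mean"], out["var"]

    ratio_fn.diff_mode = bank.diff_mode
    return _draw(neutral, grid, n_per_cell, seed, ratio_fn, "adjusted")


def simulate_unadjusted(
    neutral: NeutralStats,
    grid: PositionGrid,
    n_per_cell: int,
    seed: int = 0,
) -> FeatureMatrix:
    """Control dataset: every position drawn from the neutral distribution."""
    C = len(neutral.classes)
    F = len(neutral.columns)
    ones = np.ones((C, F))

    def ratio_fn(pos: WristPosition):
        return ones, ones

    return _draw(neutral, grid, n_per_cell, seed, ratio_fn, "unadjusted")


def three_dataset_comparison(
    real: FeatureMatrix,
    adjusted: FeatureMatrix,
    unadjusted: FeatureMatrix,
    seed: int = 0,
) -> dict:
    """Train one LDA per dataset, test all on held-out real data.

    The real classifier trains on the real training repetitions; the
    simulated classifiers train on their full datasets (they are synthetic
    by construction). All three are tested on the real test *repetitions*
    from all 13 positions — holding out whole repetitions keeps overlapping
    sliding windows of one hold from straddling the train/test boundary.
    Using the same seed as ``compute_targets`` aligns the real training
    repetitions with the ones that produced the ratio targets. Errors are
    averaged across positions; the relative improvement of adjusted over
    unadjusted training is 100 * (err_unadj - err_adj) / err_unadj.
    """
    for sim in (adjusted, unadjusted):
        if sim.columns != real.columns:
            raise ValueError("simulated columns do not match the real dataset")
    spec = ClassifierSpec(kind="lda", seed=seed)
    idx = rep_split_indices(real.labels, seed=seed)
    tr, va, te = (real.take(idx[k]) for k in ("train", "validation", "test"))
    truth = te.labels["class"].to_numpy()
    pos = te.labels["position_index"].to_numpy()
    errors = {}
    for name, train_set in (
        ("real", tr),
        ("adjusted", adjusted),
        ("unadjusted", unadjusted),
    ):
        model = fit(spec, train_set, va)
        errors[name] = classification_error(predict(model, te), truth, pos)
    e_u, e_a = errors["unadjusted"], errors["adjusted"]
    improvement = float("nan") if e_u == 0 else 100.0 * (e_u - e_a) / e_u
    return {
        "errors": errors,
        "relative_improvement_pct": improvement,
        "muscle_set": real.muscle_set,
        "n_test_rows": te.n_rows,
    }
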