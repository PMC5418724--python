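"""Experiment orchestration: classifier grid, position-subset search,
training paradigms and the real-vs-simulated comparison.

All experiments consume extracted feature matrices and report
classification-error tables (percentages, averaged across wrist positions)
keyed by condition. Every run is reproducible from its seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import (
    ClassifierSpec,
    DataSplit,
    classification_error,
    evaluate,
    fit,
    predict,
    split,
)
from .features import MUSCLE_SETS, FeatureMatrix, extract
from .preprocessing import WindowSpec

FEATURE_SETS = ("TDAR", "TDAR+POS")


def relative_improvement(err_a: float, err_b: float) -> float:
    """100 * (err_a - err_b) / err_a; positive when b is better.

    Undefined (NaN) when the reference error is zero.
    """
    if err_a == 0:
        return float("nan")
    return 100.0 * (err_a - err_b) / err_a


@dataclass
class ExperimentResult:
    """Long-format error table plus the seeds that produced it."""

    table: pd.DataFrame
    seeds: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)
        Path(path).with_suffix(".seeds.json").write_text(json.dumps(self.seeds))

    @staticmethod
    def from_csv(path: str | Path) -> "ExperimentResult":
        seeds_path = Path(path).with_suffix(".seeds.json")
        seeds = json.loads(seeds_path.read_text()) if seeds_path.exists() else {}
        return ExperimentResult(table=pd.read_csv(path), seeds=seeds)


@dataclass
class SubsetSearchResult:
    """Best training-position combination per subset size."""

    best: dict[int, tuple[tuple[int, ...], float]]
    n_evaluated: dict[int, int]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_positions": list(self.best),
                "best_combination": [
                    "+".join(map(str, c)) for c, _ in self.best.values()
                ],
                "error_pct": [e for _, e in self.best.values()],
                "n_evaluated": [self.n_evaluated[n] for n in self.best],
            }
        )


def grid_features(
    trials,
    wspec: WindowSpec | None = None,
    muscle_sets=MUSCLE_SETS,
) -> dict[str, dict[str, FeatureMatrix]]:
    """Extract the six matrices of the grid: muscle set x {TDAR, TDAR+POS}.

    The combined matrix is extracted once and the POS columns dropped for
    the TDAR variant, so both feature sets share the same windows.
    """
    out: dict[str, dict[str, FeatureMatrix]] = {}
    for ms in muscle_sets:
        with_pos = extract(trials, wspec, muscle_set=ms, include_pos=True)
        out[ms] = {"TDAR": with_pos.drop_pos(), "TDAR+POS": with_pos}
    return out


def run_grid(
    features: dict[str, dict[str, FeatureMatrix]],
    *,
    classifier_kinds=("lda", "qda", "lnn", "mlpann"),
    split_seed: int = 0,
    net_seed: int = 0,
    max_iter: int = 300,
) -> ExperimentResult:
    """Two-fold cross-validated error for every classifier x feature set x
    muscle set cell, plus the relative change from adding POS features."""
    rows = []
    for ms, by_fs in features.items():
        for fs in FEATURE_SETS:
            fm = by_fs[fs]
            for kind in classifier_kinds:
                spec = ClassifierSpec(kind=kind, seed=net_seed, max_iter=max_iter)
                res = evaluate(spec, fm, DataSplit(seed=split_seed))
                rows.append(
                    {
                        "classifier": kind,
                        "feature_set": fs,
                        "muscle_set": ms,
                        "error_pct": res["error"],
                        "fold1_error_pct": res["fold_errors"][0],
                        "fold2_error_pct": res["fold_errors"][1],
                    }
                )
    table = pd.DataFrame(rows)
    # relative change in error from adding wrist position features
    rel = []
    for (kind, ms), grp in table.groupby(["classifier", "muscle_set"]):
        e = grp.set_index("feature_set")["error_pct"]
        rel.append(
            {
                "classifier": kind,
                "muscle_set": ms,
                "relative_change_pct": relative_improvement(
                    e["TDAR"], e["TDAR+POS"]
                ),
            }
        )
    table = table.merge(pd.DataFrame(rel), on=["classifier", "muscle_set"])
    return ExperimentResult(
        table=table, seeds={"split_seed": split_seed, "net_seed": net_seed}
    )


def subset_search(
    features: FeatureMatrix,
    n_range=range(1, 14),
    *,
    positions: list[int] | None = None,
    spec: ClassifierSpec | None = None,
    dsplit: DataSplit | None = None,
) -> SubsetSearchResult:
    """Exhaustive search over training-position subsets.

    For each n, an LDA (by default) is trained on the training-split rows of
    every n-position combination and tested on the test-split rows of all
    positions; the combination with the lowest error wins, ties broken by
    the lexicographically smallest position tuple.
    """
    spec = spec or ClassifierSpec(kind="lda")
    dsplit = dsplit or DataSplit()
    pool = sorted(positions) if positions is not None else sorted(
        set(features.labels["position_index"])
    )
    tr, va, te = split(features, dsplit)
    truth = te.labels["class"].to_numpy()
    te_pos = te.labels["position_index"].to_numpy()
    tr_pos = tr.labels["position_index"].to_numpy()
    va_pos = va.labels["position_index"].to_numpy()

    best: dict[int, tuple[tuple[int, ...], float]] = {}
    n_eval: dict[int, int] = {}
    for n in n_range:
        if not 1 <= n <= len(pool):
            raise ValueError(f"subset size {n} outside 1..{len(pool)}")
        best_err, best_combo = np.inf, None
        count = 0
        for combo in combinations(pool, n):
            count += 1
            mask = np.isin(tr_pos, combo)
            sub_tr = tr.take(np.flatnonzero(mask))
            sub_va = va.take(np.flatnonzero(np.isin(va_pos, combo)))
            model = fit(spec, sub_tr, sub_va)
            err = classification_error(predict(model, te), truth, te_pos)
            if err < best_err:  # strict: ties keep the lexicographically first
                best_err, best_combo = err, combo
        best[n] = (best_combo, float(best_err))
        n_eval[n] = count
    return SubsetSearchResult(best=best, n_evaluated=n_eval)


#: named training-position presets (grid index convention of PositionGrid:
#: per DOF/direction, end-range precedes mid-range)
POSITION_PRESETS = {
    "all": tuple(range(13)),
    "end_range": (0, 1, 3, 5, 7, 9, 11),
    "mid_range": (0, 2, 4, 6, 8, 10, 12),
}


def compare_paradigms(
    features: FeatureMatrix,
    *,
    spec: ClassifierSpec | None = None,
    dsplit: DataSplit | None = None,
) -> ExperimentResult:
    """Generalised vs position-specific training.

    Paradigm 1: one classifier trained with data from all wrist positions,
    tested on each position separately, errors averaged. Paradigm 2: one
    classifier per position, trained and tested within that position,
    errors averaged across the position-specific classifiers.
    """
    spec = spec or ClassifierSpec(kind="lda")
    dsplit = dsplit or DataSplit()
    tr, va, te = split(features, dsplit)
    truth = te.labels["class"].to_numpy()
    te_pos = te.labels["position_index"].to_numpy()
    positions = sorted(set(features.labels["position_index"]))

    model = fit(spec, tr, va)
    pred = predict(model, te)
    p1_errors = [
        classification_error(pred[te_pos == p], truth[te_pos == p])
        for p in positions
    ]

    tr_pos = tr.labels["position_index"].to_numpy()
    va_pos = va.labels["position_index"].to_numpy()
    p2_errors = []
    for p in positions:
        m = fit(
            spec,
            tr.take(np.flatnonzero(tr_pos == p)),
            va.take(np.flatnonzero(va_pos == p)),
        )
        rows = np.flatnonzero(te_pos == p)
        p2_errors.append(
            classification_error(predict(m, te.take(rows)), truth[rows])
        )

    table = pd.DataFrame(
        {
            "paradigm": [1, 2],
            "error_pct": [float(np.mean(p1_errors)), float(np.mean(p2_errors))],
            "n_positions": [len(positions)] * 2,
        }
    )
    return ExperimentResult(
        table=table,
        seeds={"split_seed": dsplit.seed, "net_seed": spec.seed},
    )
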