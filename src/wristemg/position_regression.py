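"""Feature mean/variance as a function of wrist position (the ratio model).

For every (class, channel, feature) pair, two small regression networks —
3 inputs (the wrist angles), 3 tanh hidden units, 1 linear output — learn
how the feature's mean and variance at a wrist position relate to its mean
and variance at neutral:

    mean_ratio(theta) = mean(feature | class, theta) / mean(feature | class, 0)
    var_ratio(theta)  = var(feature | class, theta) / var(feature | class, 0)

Per (class, position) cell, 50% of the rows (the statistics split) provide
the training targets; means/variances computed on the disjoint 20% and 30%
splits provide validation targets (early stopping) and test targets (the
reported r²). Wrist angles are rescaled to [-1, 1] by the grid's end range
before entering the tanh network.

Signed features whose neutral mean is essentially zero (possible for AR
coefficients) make a mean *ratio* numerically meaningless; those switch to
a difference-from-neutral target, flagged per regressor. Regressors whose
training targets are constant up to sampling noise (amplitude-invariant
features under a pure amplitude modulation) are flagged degenerate: they
predict the constant and their r² is undefined (NaN), excluded from
bank-level averages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._nets import MLPSpec, train_networks
from .features import FeatureMatrix
from .synthetic_emg import PositionGrid, WristPosition

VAR_FLOOR = 1e-12
#: |neutral mean| below this fraction of the cross-position spread of the
#: per-position means switches the mean target from ratio to difference
_DIFF_MODE_TOL = 1e-3
#: a regressor is degenerate when its training and validation targets do
#: not correlate at least this strongly across the 13 positions (no
#: reproducible position dependence beyond sampling noise). With ~10^3
#: regressors screened per bank, the gate sits at the ~99.9% null quantile
#: of the correlation (n = 13) so that flat targets essentially never slip
#: through; genuinely position-dependent targets correlate near 1.
_RELIABILITY_MIN = 0.8


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size < 2:
        raise ValueError("need at least two points")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true is constant; r^2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class NeutralStats:
    """Per (class, feature-column) mean and variance at the neutral position,
    from the statistics split."""

    classes: list[str]
    columns: list[str]
    mean: np.ndarray  # (C, F)
    variance: np.ndarray  # (C, F), floored at VAR_FLOOR


@dataclass
class RatioTargets:
    """Ratio targets per split role, plus regressor input angles."""

    classes: list[str]
    columns: list[str]
    angles_deg: np.ndarray  # (13, 3)
    angle_scale: np.ndarray  # (3,) end-range used to normalise inputs
    # target arrays keyed by split role: each (C, 13, F)
    mean_targets: dict[str, np.ndarray]
    var_targets: dict[str, np.ndarray]
    diff_mode: np.ndarray  # (C, F) bool: mean target is a difference
    neutral: NeutralStats

    @property
    def inputs(self) -> np.ndarray:
        """Normalised network inputs, (13, 3) in [-1, 1]."""
        return self.angles_deg / self.angle_scale


def _cell_stats(
    X: np.ndarray, labels: pd.DataFrame, classes, n_pos: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(class, position) column means and variances: (C, P, F) each."""
    C, F = len(classes), X.shape[1]
    mean = np.full((C, n_pos, F), np.nan)
    var = np.full((C, n_pos, F), np.nan)
    cl = labels["class"].to_numpy()
    po = labels["position_index"].to_numpy()
    for ci, c in enumerate(classes):
        for p in range(n_pos):
            rows = X[(cl == c) & (po == p)]
            if len(rows) == 0:
                raise ValueError(f"no rows for cell ({c}, position {p})")
            mean[ci, p] = rows.mean(axis=0)
            var[ci, p] = rows.var(axis=0, ddof=1) if len(rows) > 1 else 0.0
    return mean, var


def rep_split_indices(
    labels: pd.DataFrame, stats_fraction: float = 0.5, seed: int = 0
) -> dict[str, np.ndarray]:
    """Per-cell split at the *repetition* level.

    Sliding windows overlap heavily within a repetition, so rows are not
    independent; estimating the train/validation/test target statistics on
    disjoint repetitions keeps their sampling noise independent. Roughly
    ``stats_fraction`` of the repetitions feed the training targets, ~20%
    the validation targets and the rest the test targets.
    """
    rng = np.random.default_rng(seed)
    cl = labels["class"].to_numpy()
    po = labels["position_index"].to_numpy()
    re = labels["rep_index"].to_numpy()
    out = {"train": [], "validation": [], "test": []}
    for c in np.unique(cl):
        for p in np.unique(po):
            cell = np.flatnonzero((cl == c) & (po == p))
            reps = np.unique(re[cell])
            R = len(reps)
            if R < 3:
                raise ValueError(
                    "need at least 3 repetitions per cell to form "
                    "statistics/validation/test splits"
                )
            perm = reps[rng.permutation(R)]
            n_st = int(np.clip(round(stats_fraction * R), 1, R - 2))
            n_va = int(np.clip(round(0.2 * R), 1, R - n_st - 1))
            groups = {
                "train": perm[:n_st],
                "validation": perm[n_st : n_st + n_va],
                "test": perm[n_st + n_va :],
            }
            for role, rr in groups.items():
                out[role].append(cell[np.isin(re[cell], rr)])
    return {k: np.sort(np.concatenate(v)) for k, v in out.items()}


def compute_targets(
    features: FeatureMatrix,
    grid: PositionGrid,
    stats_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[NeutralStats, RatioTargets]:
    """Form ratio targets from per-cell statistics on three disjoint splits.

    The statistics split (default 50% of repetitions) provides the training
    targets; the ~20% / ~30% remainders provide validation and test targets.
    """
    fm = features.drop_pos() if features.has_pos else features
    idx = rep_split_indices(fm.labels, stats_fraction, seed)
    classes = sorted(set(fm.labels["class"]))
    n_pos = len(grid.positions)

    means, variances = {}, {}
    for role, rows in idx.items():
        means[role], variances[role] = _cell_stats(
            fm.X[rows], fm.labels.iloc[rows], classes, n_pos
        )

    m0 = means["train"][:, 0, :]  # (C, F) neutral means, stats split
    v0 = np.maximum(variances["train"][:, 0, :], VAR_FLOOR)
    spread = means["train"].max(axis=1) - means["train"].min(axis=1)  # (C, F)
    diff_mode = np.abs(m0) < _DIFF_MODE_TOL * np.maximum(spread, VAR_FLOOR)

    neutral = NeutralStats(
        classes=classes, columns=list(fm.columns), mean=m0, variance=v0
    )

    # every split is normalised by its own neutral statistics, so the
    # neutral ratios equal 1 by construction in all three target sets and
    # no split inherits the others' neutral sampling noise
    mean_targets, var_targets = {}, {}
    for role in idx:
        m = means[role]
        m0_role = m[:, 0, :]
        v0_role = np.maximum(variances[role][:, 0, :], VAR_FLOOR)
        m0_safe = np.where(diff_mode, 1.0, m0_role)
        mean_targets[role] = np.where(
            diff_mode[:, None, :],
            m - m0_role[:, None, :],
            m / m0_safe[:, None, :],
        )
        var_targets[role] = variances[role] / v0_role[:, None, :]

    return neutral, RatioTargets(
        classes=classes,
        columns=list(fm.columns),
        angles_deg=grid.angles(),
        angle_scale=np.asarray(grid.end_range_deg, float),
        mean_targets=mean_targets,
        var_targets=var_targets,
        diff_mode=diff_mode,
        neutral=neutral,
    )


@dataclass
class RatioModelBank:
    """One 3-3-1 regressor per (class, column) x {mean, variance}."""

    classes: list[str]
    columns: list[str]
    angle_scale: np.ndarray  # (3,)
    net: MLPSpec
    # (C, F, P_weights) per target kind; NaN rows for degenerate regressors
    weights: dict[str, np.ndarray]
    constants: dict[str, np.ndarray]  # (C, F) constant for degenerate ones
    degenerate: dict[str, np.ndarray]  # (C, F) bool
    diff_mode: np.ndarray  # (C, F) bool, mean-target convention
    r2: dict[str, np.ndarray]  # (C, F) test r², NaN when undefined
    neutral: NeutralStats

    def mean_r2(self, kind: str = "mean") -> float:
        """Bank-average test r² over non-degenerate regressors."""
        vals = self.r2[kind]
        return float(np.nanmean(vals))

    def predict(self, position: WristPosition) -> dict[str, np.ndarray]:
        """Forward pass of every regressor at one wrist position.

        Returns {"mean": (C, F), "var": (C, F)} ratio (or difference)
        predictions.
        """
        x = (position.as_array() / self.angle_scale)[None, :]  # (1, 3)
        out = {}
        for kind in ("mean", "var"):
            w = self.weights[kind]
            C, F, P = w.shape
            flat = w.reshape(C * F, P)
            valid = ~np.isnan(flat[:, 0])
            pred = np.empty(C * F)
            pred[:] = self.constants[kind].reshape(-1)
            if valid.any():
                y = self.net.forward(flat[valid], x)[:, 0, 0]
                pred[valid] = y
            out[kind] = pred.reshape(C, F)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes,
            "columns": self.columns,
            "angle_scale": self.angle_scale.tolist(),
            "net": {
                "n_in": self.net.n_in,
                "n_hidden": self.net.n_hidden,
                "n_out": self.net.n_out,
                "activation": self.net.activation,
                "loss": self.net.loss,
            },
            "diff_mode": self.diff_mode.tolist(),
            "neutral_mean": self.neutral.mean.tolist(),
            "neutral_variance": self.neutral.variance.tolist(),
        }
        for kind in ("mean", "var"):
            payload[f"weights_{kind}"] = np.where(
                np.isnan(self.weights[kind]), None, self.weights[kind]
            ).tolist()
            payload[f"constants_{kind}"] = self.constants[kind].tolist()
            payload[f"degenerate_{kind}"] = self.degenerate[kind].tolist()
            payload[f"r2_{kind}"] = np.where(
                np.isnan(self.r2[kind]), None, self.r2[kind]
            ).tolist()
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def from_json(path: str | Path) -> "RatioModelBank":
        d = json.loads(Path(path).read_text())
        net = MLPSpec(**d["net"])
        classes = d["classes"]
        columns = d["columns"]
        neutral = NeutralStats(
            classes=classes,
            columns=columns,
            mean=np.asarray(d["neutral_mean"], float),
            variance=np.asarray(d["neutral_variance"], float),
        )

        def arr(v):
            return np.array(
                [[np.nan if x is None else x for x in row] for row in v], float
            )

        weights, constants, degenerate, r2 = {}, {}, {}, {}
        for kind in ("mean", "var"):
            w = d[f"weights_{kind}"]
            weights[kind] = np.array(
                [
                    [
                        [np.nan if x is None else x for x in cell]
                        for cell in row
                    ]
                    for row in w
                ],
                float,
            )
            constants[kind] = np.asarray(d[f"constants_{kind}"], float)
            degenerate[kind] = np.asarray(d[f"degenerate_{kind}"], bool)
            r2[kind] = arr(d[f"r2_{kind}"])
        return RatioModelBank(
            classes=classes,
            columns=columns,
            angle_scale=np.asarray(d["angle_scale"], float),
            net=net,
            weights=weights,
            constants=constants,
            degenerate=degenerate,
            r2=r2,
            diff_mode=np.asarray(d["diff_mode"], bool),
            neutral=neutral,
        )


def _degenerate_mask(t_train: np.ndarray, t_val: np.ndarray) -> np.ndarray:
    """Flag regressors whose targets carry no reproducible position signal.

    The training- and validation-split targets are independent estimates of
    the same 13 position values, so for a feature that truly varies with
    position they correlate strongly, while for a constant-up-to-noise
    target (amplitude-invariant features under pure amplitude modulation)
    the correlation vanishes. Exactly constant targets are degenerate too.
    """
    st = t_train.std(axis=1)
    sv = t_val.std(axis=1)
    constant = (st <= 1e-12) | (sv <= 1e-12)
    ct = t_train - t_train.mean(axis=1, keepdims=True)
    cv = t_val - t_val.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, st * sv * t_train.shape[1])
    corr = np.einsum("rn,rn->r", ct, cv) / denom
    return constant | (corr < _RELIABILITY_MIN)


def fit_bank(
    targets: RatioTargets,
    seed: int = 0,
    *,
    hidden: int = 3,
    restarts: int = 3,
    max_iter: int = 400,
    patience: int = 6,
) -> RatioModelBank:
    """Train the full regressor bank (batched across regressors)."""
    X = targets.inputs  # (13, 3)
    if X.shape[0] < 13:
        raise ValueError("need one target point per grid position")
    net = MLPSpec(n_in=3, n_hidden=hidden, n_out=1, activation="tanh", loss="mse")
    C = len(targets.classes)
    F = len(targets.columns)

    weights: dict[str, np.ndarray] = {}
    constants: dict[str, np.ndarray] = {}
    degenerate: dict[str, np.ndarray] = {}
    r2: dict[str, np.ndarray] = {}
    for kind, tgt in (("mean", targets.mean_targets), ("var", targets.var_targets)):
        # (C, 13, F) -> (C*F, 13): one row of 13 position targets per regressor
        t_train = tgt["train"].transpose(0, 2, 1).reshape(C * F, -1)
        t_val = tgt["validation"].transpose(0, 2, 1).reshape(C * F, -1)
        t_test = tgt["test"].transpose(0, 2, 1).reshape(C * F, -1)
        degen = _degenerate_mask(t_train, t_val)
        w_all = np.full((C * F, net.n_params), np.nan)
        r2_all = np.full(C * F, np.nan)
        const = t_train.mean(axis=1)
        active = np.flatnonzero(~degen)
        if active.size:
            w, _ = train_networks(
                net,
                X,
                t_train[active][:, :, None],
                seed=seed,
                n_nets=active.size,
                restarts=restarts,
                X_val=X,
                Y_val=t_val[active][:, :, None],
                max_iter=max_iter,
                patience=patience,
            )
            w_all[active] = w
            pred = net.forward(w, X)[:, :, 0]  # (R_active, 13)
            yt = t_test[active]
            ss_tot = ((yt - yt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            ss_res = ((yt - pred) ** 2).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                r2_all[active] = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
        weights[kind] = w_all.reshape(C, F, -1)
        constants[kind] = const.reshape(C, F)
        degenerate[kind] = degen.reshape(C, F)
        r2[kind] = r2_all.reshape(C, F)

    return RatioModelBank(
        classes=list(targets.classes),
        columns=list(targets.columns),
        angle_scale=np.asarray(targets.angle_scale, float),
        net=net,
        weights=weights,
        constants=constants,
        degenerate=degenerate,
        r2=r2,
        diff_mode=targets.diff_mode.copy(),
        neutral=targets.neutral,
    )


def predict_ratios(
    bank: RatioModelBank, position: WristPosition
) -> tuple[np.ndarray, np.ndarray]:
    """(mean_ratio, var_ratio) arrays of shape (n_classes, n_columns).

    For difference-mode features the first array holds a difference from
    the neutral mean instead of a ratio (see ``bank.diff_mode``).
    """
    out = bank.predict(position)
    return out["mean"], out["var"]
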