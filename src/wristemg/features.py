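"""TDAR feature set (time-domain + autoregressive) and POS features.

Per 200 ms window and EMG channel, ten features are computed: mean absolute
value (MAV), zero-crossing count (ZC), slope-sign-change count (SSC),
waveform length (WL) and the six coefficients of a 6th-order autoregressive
model. Optionally the per-window mean wrist angles (POS, three values) are
appended.

AR coefficients are estimated with Burg's method (stable at order 6 on
200-sample windows, no windowing bias) in the prediction convention
``x_t = sum_k a_k x_{t-k} + e_t``. The Burg recursion is vectorised over
windows, since a full session contains over half a million window-channel fits.

MAV and WL scale linearly with signal amplitude; ZC, SSC and the AR
coefficients are amplitude-invariant. That dichotomy is what lets the
position-ratio model describe the wrist-position effect as per-feature
scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import WindowSpec, window_views
from .synthetic_emg import EmgTrial

TD_FEATURES = ("mav", "zc", "ssc", "wl")
AR_ORDER = 6
FEATURE_NAMES = TD_FEATURES + tuple(f"ar{k}" for k in range(1, AR_ORDER + 1))
POS_NAMES = ("pos_flexion", "pos_deviation", "pos_rotation")
MUSCLE_SETS = ("extrinsic", "intrinsic", "combined")


# --------------------------------------------------------------------------- #
# single-window operations (reference surface; the extractor uses the
# batched versions below)


def mav(window: np.ndarray) -> float:
    """Mean absolute value of a window."""
    window = np.asarray(window)
    if window.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(window)))


def zero_crossings(window: np.ndarray, deadzone: float = 0.0) -> int:
    """Count sign changes between consecutive samples.

    A crossing requires strictly opposite signs and an amplitude jump
    exceeding ``deadzone`` (default 0: pure sign logic).
    """
    if deadzone < 0:
        raise ValueError("deadzone must be non-negative")
    x = np.asarray(window, float)
    if x.size == 0:
        raise ValueError("empty window")
    a, b = x[:-1], x[1:]
    return int(np.count_nonzero((a * b < 0) & (np.abs(a - b) > deadzone)))


def slope_sign_changes(window: np.ndarray, deadzone: float = 0.0) -> int:
    """Count interior samples where the slope changes sign."""
    if deadzone < 0:
        raise ValueError("deadzone must be non-negative")
    x = np.asarray(window, float)
    if x.size < 3:
        raise ValueError("window too short for slope sign changes")
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    return int(np.count_nonzero(d1 * d2 > deadzone))


def waveform_length(window: np.ndarray) -> float:
    """Sum of absolute first differences (cumulative path length)."""
    x = np.asarray(window, float)
    if x.size < 2:
        raise ValueError("window too short for waveform length")
    return float(np.sum(np.abs(np.diff(x))))


def ar_coefficients(window: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """Burg AR coefficients in the convention x_t = sum a_k x_{t-k} + e_t.

    A zero-variance window yields all-zero coefficients.
    """
    x = np.asarray(window, float)
    if x.size <= order:
        raise ValueError("window too short for the AR order")
    return _burg_batch(x[None, :], order)[0]


def pos_features(gonio_window: np.ndarray) -> np.ndarray:
    """Mean wrist angle per degree of freedom over the window: (3,)."""
    g = np.asarray(gonio_window, float)
    if g.ndim != 2 or g.shape[0] != 3:
        raise ValueError("expected a (3, n_samples) angle window")
    return g.mean(axis=1)


# --------------------------------------------------------------------------- #
# batched kernels


def _burg_batch(x: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """Burg recursion vectorised over rows; x: (B, N) -> (B, order).

    Returns prediction-convention coefficients (negated polynomial
    coefficients). Rows with zero residual energy get zero coefficients.
    """
    x = np.asarray(x, float)
    B = x.shape[0]
    f = x.copy()
    b = x.copy()
    # polynomial convention: x_t + sum_k a_k x_{t-k} = e_t
    a = np.zeros((B, 0))
    for _ in range(order):
        ff = f[:, 1:]
        bb = b[:, :-1]
        den = np.einsum("bn,bn->b", ff, ff) + np.einsum("bn,bn->b", bb, bb)
        num = -2.0 * np.einsum("bn,bn->b", ff, bb)
        k = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        a = np.concatenate(
            [a + k[:, None] * a[:, ::-1], k[:, None]], axis=1
        )
        f_new = ff + k[:, None] * bb
        b_new = bb + k[:, None] * ff
        f, b = f_new, b_new
    return -a


def _td_batch(w: np.ndarray, deadzone: float) -> np.ndarray:
    """MAV/ZC/SSC/WL for a batch of windows (B, L) -> (B, 4)."""
    amav = np.abs(w).mean(axis=1)
    a, bnext = w[:, :-1], w[:, 1:]
    zc = ((a * bnext < 0) & (np.abs(a - bnext) > deadzone)).sum(axis=1)
    d1 = w[:, 1:-1] - w[:, :-2]
    d2 = w[:, 1:-1] - w[:, 2:]
    ssc = (d1 * d2 > deadzone).sum(axis=1)
    wl = np.abs(np.diff(w, axis=1)).sum(axis=1)
    return np.column_stack([amav, zc, ssc, wl])


# --------------------------------------------------------------------------- #


@dataclass
class FeatureMatrix:
    """Windows x features with per-row labels.

    ``columns`` are strings like ``"ch05_mav"`` or ``"pos_flexion"``;
    ``labels`` carries class, position_index, rep_index and window_index
    per row.
    """

    X: np.ndarray
    columns: list[str]
    labels: pd.DataFrame
    muscle_set: str = "combined"
    provenance: str = "real"

    def __post_init__(self):
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column metadata does not match data width")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("labels do not match row count")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def emg_columns(self) -> list[str]:
        return [c for c in self.columns if not c.startswith("pos_")]

    @property
    def has_pos(self) -> bool:
        return any(c.startswith("pos_") for c in self.columns)

    def take(self, rows: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[rows],
            columns=list(self.columns),
            labels=self.labels.iloc[rows].reset_index(drop=True),
            muscle_set=self.muscle_set,
            provenance=self.provenance,
        )

    def select_columns(self, cols: list[str]) -> "FeatureMatrix":
        idx = [self.columns.index(c) for c in cols]
        return FeatureMatrix(
            X=self.X[:, idx],
            columns=list(cols),
            labels=self.labels.copy(),
            muscle_set=self.muscle_set,
            provenance=self.provenance,
        )

    def drop_pos(self) -> "FeatureMatrix":
        return self.select_columns(self.emg_columns)

    def to_csv(self, path: str | Path) -> None:
        """CSV with feature + label columns and a JSON sidecar of metadata."""
        path = Path(path)
        df = pd.DataFrame(self.X, columns=self.columns)
        out = pd.concat([self.labels.reset_index(drop=True), df], axis=1)
        out.to_csv(path, index=False, float_format="%.8g")
        meta = {
            "feature_columns": self.columns,
            "label_columns": list(self.labels.columns),
            "muscle_set": self.muscle_set,
            "provenance": self.provenance,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @staticmethod
    def from_csv(path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        df = pd.read_csv(path)
        return FeatureMatrix(
            X=df[meta["feature_columns"]].to_numpy(float),
            columns=list(meta["feature_columns"]),
            labels=df[meta["label_columns"]].copy(),
            muscle_set=meta["muscle_set"],
            provenance=meta["provenance"],
        )


def channel_indices(groups: tuple[str, ...], muscle_set: str) -> list[int]:
    if muscle_set == "combined":
        return list(range(len(groups)))
    if muscle_set not in MUSCLE_SETS:
        raise ValueError(f"unknown muscle set {muscle_set!r}")
    return [i for i, g in enumerate(groups) if g == muscle_set]


def extract(
    trials: list[EmgTrial],
    wspec: WindowSpec | None = None,
    muscle_set: str = "combined",
    include_pos: bool = False,
    deadzone: float = 0.0,
    ar_order: int = AR_ORDER,
) -> FeatureMatrix:
    """Extract the TDAR (+POS) feature matrix from conditioned trials.

    One row per analysis window; feature columns grouped by channel in the
    order MAV, ZC, SSC, WL, AR1..AR6.
    """
    if not trials:
        raise ValueError("no trials")
    wspec = wspec or WindowSpec()
    chans = channel_indices(trials[0].channel_groups, muscle_set)
    names = TD_FEATURES + tuple(f"ar{k}" for k in range(1, ar_order + 1))
    columns = [f"ch{c + 1:02d}_{f}" for c in chans for f in names]
    if include_pos:
        columns = columns + list(POS_NAMES)

    blocks = []
    label_rows = []
    for t in trials:
        emg, gon = window_views(t, wspec)  # (K, W, L), (3, W, L)
        emg = emg[chans]
        k, nw, L = emg.shape
        flat = emg.reshape(k * nw, L)
        td = _td_batch(flat, deadzone)
        ar = _burg_batch(flat, ar_order)
        feats = np.concatenate([td, ar], axis=1)  # (k*nw, 10)
        # (k, W, F) -> (W, k*F) with channel-major column order
        feats = feats.reshape(k, nw, -1).transpose(1, 0, 2).reshape(nw, -1)
        if include_pos:
            feats = np.concatenate([feats, gon.mean(axis=2).T], axis=1)
        blocks.append(feats)
        label_rows.append(
            pd.DataFrame(
                {
                    "class": t.class_label,
                    "position_index": t.position_index,
                    "rep_index": t.rep_index,
                    "window_index": np.arange(nw),
                }
            )
        )
    X = np.concatenate(blocks, axis=0)
    labels = pd.concat(label_rows, ignore_index=True)
    return FeatureMatrix(X=X, columns=columns, labels=labels, muscle_set=muscle_set)
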