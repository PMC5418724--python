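"""Motion classifiers: LDA, QDA and SCG-trained perceptrons (LNN, MLPANN).

Four classifier families are compared throughout:

* LDA — Gaussian discriminant with a pooled covariance;
* QDA — Gaussian discriminant with per-class covariances;
* LNN — one-hidden-layer perceptron (4 identity-activation hidden units),
  mathematically equivalent to a reduced linear input-output model;
* MLPANN — one-hidden-layer perceptron (7 tanh hidden units).

Networks use a softmax output with cross-entropy loss, are trained by
scaled conjugate gradient and early-stop when validation error starts to
increase (patience rule, best-validation weights restored). All models
z-score their inputs with training-set statistics so mV-scale EMG features
can be mixed with degree-scale position features.

Data are divided per (class, position) cell into training (50%),
validation (20%) and test (30%) sets; two-fold cross-validation exchanges
the train and test partitions for fold 2 (the validation rows are shared
and never tested on).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._nets import MLPSpec, train_networks
from .features import FeatureMatrix

KINDS = ("lda", "qda", "lnn", "mlpann")
_DEFAULT_HIDDEN = {"lnn": 4, "mlpann": 7}
_RIDGE_EPS = 1e-6


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "lda"
    hidden_units: int | None = None  # defaults: 7 (mlpann), 4 (lnn)
    seed: int = 0
    max_iter: int = 300
    patience: int = 6
    restarts: int = 3

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    @property
    def n_hidden(self) -> int:
        if self.hidden_units is not None:
            return self.hidden_units
        return _DEFAULT_HIDDEN.get(self.kind, 0)


@dataclass(frozen=True)
class DataSplit:
    train_fraction: float = 0.5
    test_fraction: float = 0.3
    validation_fraction: float = 0.2
    fold_id: int = 1
    seed: int = 0

    def __post_init__(self):
        s = self.train_fraction + self.test_fraction + self.validation_fraction
        if abs(s - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.fold_id not in (1, 2):
            raise ValueError("fold_id must be 1 or 2")


def split_indices(
    labels: pd.DataFrame, split: DataSplit
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified (train, validation, test) row indices per (class, position).

    Fold 2 swaps the roles of the fold-1 train and test rows; the
    validation rows are common to both folds.
    """
    rng = np.random.default_rng(split.seed)
    tr, va, te = [], [], []
    key = list(zip(labels["class"].to_numpy(), labels["position_index"].to_numpy()))
    cells: dict = {}
    for i, k in enumerate(key):
        cells.setdefault(k, []).append(i)
    for k in sorted(cells):
        idx = np.array(cells[k])
        n = len(idx)
        n_tr = int(round(split.train_fraction * n))
        n_va = int(round(split.validation_fraction * n))
        if n_tr < 1 or n - n_tr - n_va < 1:
            raise ValueError(f"cell {k} too small to stratify ({n} rows)")
        perm = idx[rng.permutation(n)]
        f1_tr, f1_va, f1_te = (
            perm[:n_tr],
            perm[n_tr : n_tr + n_va],
            perm[n_tr + n_va :],
        )
        if split.fold_id == 1:
            tr.append(f1_tr)
            va.append(f1_va)
            te.append(f1_te)
        else:
            # fold 2 exchanges the train and test partitions; the
            # validation rows never appear in either fold's test set
            tr.append(f1_te)
            va.append(f1_va)
            te.append(f1_tr)
    return (
        np.sort(np.concatenate(tr)),
        np.sort(np.concatenate(va)),
        np.sort(np.concatenate(te)),
    )


def split(
    features: FeatureMatrix, dsplit: DataSplit
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix]:
    """Return (train, validation, test) FeatureMatrix views."""
    tr, va, te = split_indices(features.labels, dsplit)
    return features.take(tr), features.take(va), features.take(te)


# --------------------------------------------------------------------------- #


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    classes: list[str]
    columns: list[str]
    norm_mean: np.ndarray
    norm_std: np.ndarray
    params: dict  # closed-form stats or network weights

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.norm_mean) / self.norm_std

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class discriminant values / network logits, shape (n, C)."""
        Z = self._normalize(np.asarray(X, float))
        kind = self.spec.kind
        if kind == "lda":
            W = self.params["coef"]  # (C, d)
            b = self.params["intercept"]  # (C,)
            return Z @ W.T + b
        if kind == "qda":
            scores = np.empty((Z.shape[0], len(self.classes)))
            for c in range(len(self.classes)):
                mu = self.params["means"][c]
                P = self.params["precisions"][c]
                d = Z - mu
                maha = np.einsum("nd,de,ne->n", d, P, d)
                scores[:, c] = (
                    -0.5 * maha
                    - 0.5 * self.params["logdets"][c]
                    + self.params["log_priors"][c]
                )
            return scores
        net: MLPSpec = self.params["net"]
        return net.forward(self.params["weights"][None, :], Z)[0]

    def to_json(self, path: str | Path) -> None:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        payload = {
            "spec": self.spec.__dict__,
            "classes": self.classes,
            "columns": self.columns,
            "norm_mean": self.norm_mean.tolist(),
            "norm_std": self.norm_std.tolist(),
            "params": {
                k: enc(v)
                for k, v in self.params.items()
                if k != "net"
            },
        }
        if "net" in self.params:
            n = self.params["net"]
            payload["net"] = {
                "n_in": n.n_in,
                "n_hidden": n.n_hidden,
                "n_out": n.n_out,
                "activation": n.activation,
                "loss": n.loss,
            }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def from_json(path: str | Path) -> "TrainedClassifier":
        d = json.loads(Path(path).read_text())
        params = {k: np.asarray(v, float) for k, v in d["params"].items()}
        if "net" in d:
            params["net"] = MLPSpec(**d["net"])
        spec = ClassifierSpec(**d["spec"])
        return TrainedClassifier(
            spec=spec,
            classes=d["classes"],
            columns=d["columns"],
            norm_mean=np.asarray(d["norm_mean"], float),
            norm_std=np.asarray(d["norm_std"], float),
            params=params,
        )


def _ridge(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    return cov + (_RIDGE_EPS * np.trace(cov) / d + 1e-12) * np.eye(d)


def fit(
    spec: ClassifierSpec,
    train: FeatureMatrix,
    validation: FeatureMatrix | None = None,
) -> TrainedClassifier:
    """Fit a classifier; networks early-stop on the validation set."""
    X = np.asarray(train.X, float)
    y = train.labels["class"].to_numpy()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    n, d = Z.shape
    yi = np.searchsorted(np.array(classes), y)

    params: dict = {}
    if spec.kind in ("lda", "qda"):
        means = np.stack([Z[yi == c].mean(axis=0) for c in range(len(classes))])
        priors = np.array([(yi == c).mean() for c in range(len(classes))])
        if spec.kind == "lda":
            pooled = np.zeros((d, d))
            for c in range(len(classes)):
                Zc = Z[yi == c] - means[c]
                pooled += Zc.T @ Zc
            pooled /= n - len(classes)
            P = np.linalg.inv(_ridge(pooled))
            coef = means @ P  # (C, d)
            intercept = -0.5 * np.einsum("cd,cd->c", coef, means) + np.log(priors)
            params = {"coef": coef, "intercept": intercept, "means": means}
        else:
            precisions, logdets = [], []
            for c in range(len(classes)):
                Zc = Z[yi == c] - means[c]
                cov = _ridge(Zc.T @ Zc / max(len(Zc) - 1, 1))
                sign, logdet = np.linalg.slogdet(cov)
                precisions.append(np.linalg.inv(cov))
                logdets.append(logdet)
            params = {
                "means": means,
                "precisions": np.stack(precisions),
                "logdets": np.array(logdets),
                "log_priors": np.log(priors),
            }
    else:
        Y = np.eye(len(classes))[yi]
        net = MLPSpec(
            n_in=d,
            n_hidden=spec.n_hidden,
            n_out=len(classes),
            activation="tanh" if spec.kind == "mlpann" else "identity",
            loss="softmax_ce",
        )
        Xv = Yv = None
        if validation is not None and validation.n_rows:
            Xv = (np.asarray(validation.X, float) - mu) / sd
            yv = validation.labels["class"].to_numpy()
            Yv = np.eye(len(classes))[np.searchsorted(np.array(classes), yv)]
        w, _ = train_networks(
            net,
            Z,
            Y,
            seed=spec.seed,
            restarts=spec.restarts,
            X_val=Xv,
            Y_val=Yv,
            max_iter=spec.max_iter,
            patience=spec.patience,
        )
        params = {"net": net, "weights": w[0]}

    return TrainedClassifier(
        spec=spec,
        classes=classes,
        columns=list(train.columns),
        norm_mean=mu,
        norm_std=sd,
        params=params,
    )


def predict(model: TrainedClassifier, rows: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Class labels by argmax of the decision scores."""
    if isinstance(rows, FeatureMatrix):
        if rows.columns != model.columns:
            raise ValueError("feature columns do not match the trained model")
        X = rows.X
    else:
        X = np.asarray(rows, float)
        if X.shape[1] != len(model.columns):
            raise ValueError("feature columns do not match the trained model")
    scores = model.decision_scores(X)
    return np.asarray(model.classes)[scores.argmax(axis=1)]


def classification_error(
    pred: np.ndarray,
    truth: np.ndarray,
    positions: np.ndarray | None = None,
) -> float:
    """Misclassification percentage.

    With ``positions`` given, the error is computed per wrist position and
    the position-wise errors are averaged with equal weight.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if positions is None:
        return 100.0 * float(np.mean(pred != truth))
    positions = np.asarray(positions)
    errs = [
        100.0 * float(np.mean(pred[positions == p] != truth[positions == p]))
        for p in np.unique(positions)
    ]
    return float(np.mean(errs))


def evaluate(
    spec: ClassifierSpec,
    features: FeatureMatrix,
    dsplit: DataSplit,
    *,
    by_position: bool = True,
) -> dict:
    """Two-fold cross-validated test error for one classifier.

    Returns the per-fold errors and their mean (the reported error).
    """
    fold_errors = []
    for fold in (1, 2):
        ds = DataSplit(
            train_fraction=dsplit.train_fraction,
            test_fraction=dsplit.test_fraction,
            validation_fraction=dsplit.validation_fraction,
            fold_id=fold,
            seed=dsplit.seed,
        )
        tr, va, te = split(features, ds)
        model = fit(spec, tr, va)
        pred = predict(model, te)
        pos = te.labels["position_index"].to_numpy() if by_position else None
        fold_errors.append(
            classification_error(pred, te.labels["class"].to_numpy(), pos)
        )
    return {
        "fold_errors": fold_errors,
        "error": float(np.mean(fold_errors)),
    }
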