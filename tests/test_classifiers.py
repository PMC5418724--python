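"""Classifier contracts: stratified splits, closed-form discriminants,
network training behaviour and the error metric."""

import numpy as np
import pandas as pd
import pytest

from wristemg import classifiers as cl


def _cells_fixture(make_fm, n_per_cell=20, n_classes=2, n_pos=3, seed=0):
    rng = np.random.default_rng(seed)
    X, y, pos = [], [], []
    for c in range(n_classes):
        for p in range(n_pos):
            X.append(rng.normal(3 * c, 1.0, size=(n_per_cell, 4)))
            y += [f"c{c}"] * n_per_cell
            pos += [p] * n_per_cell
    return make_fm(np.concatenate(X), np.array(y), positions=np.array(pos))


class TestSplit:
    def test_fractions_per_cell(self, make_fm):
        fm = _cells_fixture(make_fm, n_per_cell=100)
        tr, va, te = cl.split_indices(fm.labels, cl.DataSplit(seed=1))
        lab = fm.labels
        for (c, p), grp in lab.groupby(["class", "position_index"]):
            idx = set(grp.index)
            assert len(idx & set(tr)) == 50
            assert len(idx & set(va)) == 20
            assert len(idx & set(te)) == 30

    def test_disjoint_and_complete(self, make_fm):
        fm = _cells_fixture(make_fm)
        tr, va, te = cl.split_indices(fm.labels, cl.DataSplit(seed=2))
        all_rows = np.concatenate([tr, va, te])
        assert len(all_rows) == fm.n_rows
        assert len(set(all_rows)) == fm.n_rows

    def test_fold2_swaps_train_and_test(self, make_fm):
        fm = _cells_fixture(make_fm)
        tr1, va1, te1 = cl.split_indices(fm.labels, cl.DataSplit(seed=3, fold_id=1))
        tr2, va2, te2 = cl.split_indices(fm.labels, cl.DataSplit(seed=3, fold_id=2))
        # fold-1 test rows all train in fold 2
        assert set(te1) & set(tr2) == set(te1)
        assert set(te2) == set(tr1)
        assert set(va1) == set(va2)

    def test_small_cell_rejected(self, make_fm):
        fm = _cells_fixture(make_fm, n_per_cell=1)
        with pytest.raises(ValueError):
            cl.split_indices(fm.labels, cl.DataSplit())

    def test_split_returns_views(self, make_fm):
        fm = _cells_fixture(make_fm)
        tr, va, te = cl.split(fm, cl.DataSplit(seed=0))
        assert tr.n_rows + va.n_rows + te.n_rows == fm.n_rows
        assert tr.columns == fm.columns


class TestGaussianDiscriminants:
    def test_lda_boundary_on_symmetric_gaussians(self, make_fm):
        """Two 1-D classes at -3 and +3: the LDA boundary sits at 0."""
        rng = np.random.default_rng(0)
        n = 500
        X = np.concatenate([rng.normal(-3, 1, n), rng.normal(3, 1, n)])[:, None]
        y = np.array(["lo"] * n + ["hi"] * n)
        fm = make_fm(X, y)
        tr, va, te = cl.split(fm, cl.DataSplit(seed=0))
        model = cl.fit(cl.ClassifierSpec(kind="lda"), tr, va)
        grid = np.linspace(-1, 1, 2001)[:, None]
        scores = model.decision_scores(grid)
        flip = np.flatnonzero(np.diff(scores.argmax(axis=1)))
        assert abs(grid[flip[0], 0]) <= 0.1
        err = cl.classification_error(cl.predict(model, te), te.labels["class"].to_numpy())
        assert err <= 1.0

    def test_lda_matches_closed_form(self, make_fm):
        """Fitted parameters equal the textbook sample estimates."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(90, 3))
        y = np.array(["a", "b", "c"]).repeat(30)
        X[y == "b"] += 2.0
        fm = make_fm(X, y)
        tr, va, _ = cl.split(fm, cl.DataSplit(seed=0))
        model = cl.fit(cl.ClassifierSpec(kind="lda"), tr, va)
        Z = (tr.X - model.norm_mean) / model.norm_std
        yi = tr.labels["class"].to_numpy()
        means = np.stack([Z[yi == c].mean(axis=0) for c in model.classes])
        np.testing.assert_allclose(model.params["means"], means, atol=1e-12)
        pooled = sum(
            (Z[yi == c] - means[i]).T @ (Z[yi == c] - means[i])
            for i, c in enumerate(model.classes)
        ) / (len(Z) - 3)
        coef_ref = means @ np.linalg.inv(pooled)
        np.testing.assert_allclose(model.params["coef"], coef_ref, rtol=1e-4)

    def test_lda_qda_agree_with_sklearn(self, make_fm):
        from sklearn.discriminant_analysis import (
            LinearDiscriminantAnalysis,
            QuadraticDiscriminantAnalysis,
        )

        rng = np.random.default_rng(7)
        X = np.concatenate(
            [rng.normal(0, 1, (150, 4)), rng.normal(1.5, 2.0, (150, 4))]
        )
        y = np.array(["a"] * 150 + ["b"] * 150)
        fm = make_fm(X, y)
        tr, va, te = cl.split(fm, cl.DataSplit(seed=1))
        Z = (tr.X - tr.X.mean(0)) / tr.X.std(0)
        Zte = (te.X - tr.X.mean(0)) / tr.X.std(0)
        for kind, ref in (
            ("lda", LinearDiscriminantAnalysis()),
            ("qda", QuadraticDiscriminantAnalysis(reg_param=0.0)),
        ):
            model = cl.fit(cl.ClassifierSpec(kind=kind), tr, va)
            ref.fit(Z, tr.labels["class"].to_numpy())
            assert (cl.predict(model, te) == ref.predict(Zte)).mean() == 1.0

    def test_qda_handles_near_singular_covariance(self, make_fm):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 5))
        X[:, 4] = X[:, 3]  # exactly collinear pair
        y = np.array(["a", "b"]).repeat(100)
        X[y == "b", 0] += 5
        fm = make_fm(X, y)
        tr, va, te = cl.split(fm, cl.DataSplit(seed=0))
        model = cl.fit(cl.ClassifierSpec(kind="qda"), tr, va)
        err = cl.classification_error(cl.predict(model, te), te.labels["class"].to_numpy())
        assert err <= 5.0


class TestNetworks:
    @staticmethod
    def _xor(seed, n=150):
        rng = np.random.default_rng(seed)
        X = np.concatenate(
            [
                rng.normal([1, 1], 0.3, (n, 2)),
                rng.normal([-1, -1], 0.3, (n, 2)),
                rng.normal([1, -1], 0.3, (n, 2)),
                rng.normal([-1, 1], 0.3, (n, 2)),
            ]
        )
        y = np.array(["same"] * 2 * n + ["diff"] * 2 * n)
        perm = rng.permutation(len(y))
        return X[perm], y[perm]

    def test_mlpann_solves_xor_lda_cannot(self, make_fm):
        X, y = self._xor(0)
        fm = make_fm(X, y)
        tr, va, te = cl.split(fm, cl.DataSplit(seed=0))
        truth = te.labels["class"].to_numpy()
        mlp = cl.fit(cl.ClassifierSpec(kind="mlpann", seed=0), tr, va)
        assert cl.classification_error(cl.predict(mlp, te), truth) <= 5.0
        lda = cl.fit(cl.ClassifierSpec(kind="lda"), tr, va)
        assert cl.classification_error(cl.predict(lda, te), truth) >= 30.0

    def test_lnn_equivalent_to_linear_softmax(self, make_fm):
        """The linear-activation hidden layer collapses to an input-output
        model: trained to convergence, predictions agree >= 99%."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(600, 6))
        W = rng.normal(size=(6, 3))
        y = np.array(["c0", "c1", "c2"])[
            (X @ W + 0.3 * rng.normal(size=(600, 3))).argmax(axis=1)
        ]
        fm = make_fm(X, y)
        tr, _, te = cl.split(fm, cl.DataSplit(seed=1))
        lnn = cl.fit(cl.ClassifierSpec(kind="lnn", seed=0, max_iter=600), tr, None)
        lin = cl.fit(
            cl.ClassifierSpec(kind="lnn", hidden_units=0, seed=0, max_iter=600),
            tr,
            None,
        )
        agree = (cl.predict(lnn, te) == cl.predict(lin, te)).mean()
        assert agree >= 0.99

    def test_network_fit_deterministic(self, make_fm):
        X, y = self._xor(1, n=60)
        fm = make_fm(X, y)
        tr, va, te = cl.split(fm, cl.DataSplit(seed=0))
        a = cl.fit(cl.ClassifierSpec(kind="mlpann", seed=5, max_iter=100), tr, va)
        b = cl.fit(cl.ClassifierSpec(kind="mlpann", seed=5, max_iter=100), tr, va)
        np.testing.assert_array_equal(a.params["weights"], b.params["weights"])


class TestPredictAndError:
    def test_training_error_zero_on_separable(self, make_fm):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-5, 0.5, (50, 2)), rng.normal(5, 0.5, (50, 2))])
        y = np.array(["a"] * 50 + ["b"] * 50)
        fm = make_fm(X, y)
        tr, va, _ = cl.split(fm, cl.DataSplit(seed=0))
        model = cl.fit(cl.ClassifierSpec(kind="lda"), tr, va)
        assert cl.classification_error(cl.predict(model, tr), tr.labels["class"].to_numpy()) == 0.0

    def test_row_permutation_equivariance(self, make_fm):
        fm = _cells_fixture(make_fm)
        tr, va, te = cl.split(fm, cl.DataSplit(seed=0))
        model = cl.fit(cl.ClassifierSpec(kind="lda"), tr, va)
        pred = cl.predict(model, te)
        perm = np.random.default_rng(0).permutation(te.n_rows)
        pred_perm = cl.predict(model, te.take(perm))
        np.testing.assert_array_equal(pred[perm], pred_perm)

    def test_scores_match_hand_computed_discriminant(self, make_fm):
        """Two-point fixture: scores equal the closed-form Gaussian
        discriminant evaluated by hand."""
        X = np.array([[0.0, 0.0], [2.0, 0.0]] * 10)
        X = X + np.random.default_rng(0).normal(0, 0.1, X.shape)
        y = np.array(["a", "b"] * 10)
        fm = make_fm(X, y)
        model = cl.fit(cl.ClassifierSpec(kind="lda"), fm, None)
        q = np.array([[1.0, 0.3]])
        Z = (q - model.norm_mean) / model.norm_std
        means = model.params["means"]
        coef = model.params["coef"]
        icpt = model.params["intercept"]
        expected = Z @ coef.T + icpt
        np.testing.assert_allclose(model.decision_scores(q), expected)

    def test_column_mismatch_rejected(self, make_fm):
        fm = _cells_fixture(make_fm)
        tr, va, te = cl.split(fm, cl.DataSplit(seed=0))
        model = cl.fit(cl.ClassifierSpec(kind="lda"), tr, va)
        with pytest.raises(ValueError):
            cl.predict(model, te.select_columns(te.columns[:2]))

    def test_classification_error_arithmetic(self):
        y = np.array(list("aaabbbcccc"))
        assert cl.classification_error(y, y) == 0.0
        flip = np.where(y == "a", "b", "a")
        assert cl.classification_error(flip, y) == 100.0
        pred = y.copy()
        pred[:3] = "z"
        assert cl.classification_error(pred, y) == pytest.approx(30.0)

    def test_position_averaged_error_weights_positions_equally(self):
        truth = np.array(["a"] * 90 + ["a"] * 10)
        pred = truth.copy()
        pred[:45] = "b"  # 50% error in position 0 (90 rows), 0% in position 1
        pos = np.array([0] * 90 + [1] * 10)
        assert cl.classification_error(pred, truth, pos) == pytest.approx(25.0)
        assert cl.classification_error(pred, truth) == pytest.approx(45.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cl.classification_error(np.array(["a"]), np.array(["a", "b"]))


class TestEvaluate:
    def test_two_fold_error_is_fold_mean(self, make_fm):
        fm = _cells_fixture(make_fm, n_per_cell=40)
        res = cl.evaluate(cl.ClassifierSpec(kind="lda"), fm, cl.DataSplit(seed=0))
        assert res["error"] == pytest.approx(np.mean(res["fold_errors"]))
        assert len(res["fold_errors"]) == 2


class TestSerialization:
    def test_model_json_round_trip(self, make_fm, tmp_path):
        fm = _cells_fixture(make_fm)
        tr, va, te = cl.split(fm, cl.DataSplit(seed=0))
        for kind in ("lda", "qda", "mlpann"):
            model = cl.fit(cl.ClassifierSpec(kind=kind, seed=0, max_iter=50), tr, va)
            path = tmp_path / f"{kind}.json"
            model.to_json(path)
            back = cl.TrainedClassifier.from_json(path)
            np.testing.assert_array_equal(cl.predict(model, te), cl.predict(back, te))
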