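"""Classifier behaviour: optimizer correctness, separability, bookkeeping."""

import numpy as np
import pytest

from thzresidue.nnmodels import (
    BPNNClassifier,
    DCNNClassifier,
    evaluate,
    minimize_cg,
    minimize_rprop,
)
from thzresidue.preprocess import LabeledDataset


def make_quadratic(n, seed):
    """Convex quadratic bowl with a closed-form minimum (the oracle)."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, n))
    H = A @ A.T + n * np.eye(n)
    b = rng.normal(size=n)
    xstar = np.linalg.solve(H, b)
    fmin = 0.5 * xstar @ H @ xstar - b @ xstar

    def fun_grad(x):
        return 0.5 * x @ H @ x - b @ x - fmin, H @ x - b

    return fun_grad, xstar


def two_class_spectra(n=80, n_feat=67, seed=0):
    """Linearly separable synthetic spectra: disjoint peak channels."""
    rng = np.random.default_rng(seed)
    X = 0.05 + 0.01 * rng.normal(size=(n, n_feat))
    y = np.repeat([1, 2], n // 2)
    X[y == 1, 10] += 1.0
    X[y == 2, 40] += 1.0
    return X, y


@pytest.mark.parametrize("variant", ["cgf", "cgp", "cgb"])
def test_cg_exact_convergence_on_quadratic(variant):
    """CG with an exact (secant) line search terminates in <= n steps."""
    fun_grad, xstar = make_quadratic(6, seed=1)
    x, history = minimize_cg(fun_grad, np.zeros(6), variant=variant,
                             max_iter=6, goal=-np.inf)
    assert np.max(np.abs(x - xstar)) <= 1e-4
    assert np.all(np.diff(history) <= 1e-12)


def test_rprop_decreases_quadratic():
    fun_grad, xstar = make_quadratic(4, seed=2)
    x, history = minimize_rprop(fun_grad, np.zeros(4), max_iter=500, goal=1e-10)
    assert history[-1] < 1e-6


def test_bpnn_rp_solves_xor_within_goal():
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    y = np.array([1, 2, 2, 1])
    model = BPNNClassifier(algorithm="rp", epochs=5000, random_state=0).fit(X, y)
    assert model.history_["loss"][-1] <= model.goal
    assert np.array_equal(model.predict(X), y)


def test_bpnn_unknown_algorithm_rejected():
    with pytest.raises(ValueError, match="algorithm"):
        BPNNClassifier(algorithm="sgd").fit(np.zeros((4, 2)), [1, 1, 2, 2])


def test_bpnn_resamples_wide_spectra_to_input_width():
    X, y = two_class_spectra()
    model = BPNNClassifier(algorithm="cgf", epochs=100, random_state=0).fit(X, y)
    assert model.predict_proba(X).shape == (len(X), 2)
    assert np.mean(model.predict(X) == y) == 1.0


def test_dcnn_single_class_reaches_full_training_accuracy():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 67))
    y = np.full(30, 4)
    model = DCNNClassifier(epochs=3, batch_size=16, random_state=0).fit(X, y)
    assert model.history_["train_acc"][-1] == 1.0
    assert np.all(model.predict(X) == 4)


def test_dcnn_separable_two_class_beats_centroid_oracle():
    X, y = two_class_spectra(n=200)
    ds = LabeledDataset(
        X, y, np.arange(200) % 10 < 7, np.linspace(0.2, 2.2, 67)
    )
    Xtr, ytr = ds.train
    Xte, yte = ds.test
    # nearest-centroid oracle scores 1.0 on this construction
    c1, c2 = Xtr[ytr == 1].mean(axis=0), Xtr[ytr == 2].mean(axis=0)
    d1 = np.linalg.norm(Xte - c1, axis=1)
    d2 = np.linalg.norm(Xte - c2, axis=1)
    assert np.mean(np.where(d1 < d2, 1, 2) == yte) == 1.0
    model = DCNNClassifier(epochs=50, batch_size=32, random_state=0).fit(Xtr, ytr)
    assert np.mean(model.predict(Xte) == yte) >= 0.99


def test_dcnn_reproducible_given_seed():
    X, y = two_class_spectra(n=60, seed=3)
    a = DCNNClassifier(epochs=5, batch_size=16, random_state=7).fit(X, y)
    b = DCNNClassifier(epochs=5, batch_size=16, random_state=7).fit(X, y)
    assert np.array_equal(a.history_["train_loss"], b.history_["train_loss"])
    assert np.array_equal(a.predict(X), b.predict(X))


def test_bpnn_reproducible_given_seed():
    X, y = two_class_spectra(n=40, seed=4)
    a = BPNNClassifier(algorithm="cgp", epochs=50, random_state=5).fit(X, y)
    b = BPNNClassifier(algorithm="cgp", epochs=50, random_state=5).fit(X, y)
    assert np.array_equal(a.history_["loss"], b.history_["loss"])
    assert np.array_equal(a.coef_flat_, b.coef_flat_)


def test_training_never_sees_test_labels():
    """Permuting test-split labels leaves the training history unchanged."""
    X, y = two_class_spectra(n=60, seed=6)
    split = np.arange(60) % 10 < 7
    freqs = np.linspace(0.2, 2.2, 67)
    ds1 = LabeledDataset(X, y, split, freqs)
    y_perm = y.copy()
    rng = np.random.default_rng(0)
    y_perm[~split] = rng.permutation(y_perm[~split])
    ds2 = LabeledDataset(X, y_perm, split, freqs)
    m1 = DCNNClassifier(epochs=4, batch_size=16, random_state=1).fit(*ds1.train)
    m2 = DCNNClassifier(epochs=4, batch_size=16, random_state=1).fit(*ds2.train)
    assert np.array_equal(m1.history_["train_loss"], m2.history_["train_loss"])


class _Constant:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label)


def _balanced_dataset(n_per_class=4):
    rng = np.random.default_rng(0)
    X = rng.normal(size=(9 * n_per_class, 5))
    y = np.repeat(np.arange(1, 10), n_per_class)
    return LabeledDataset(X, y, np.ones(len(y), bool), np.arange(5, dtype=float))


def test_evaluate_perfect_predictor():
    ds = _balanced_dataset()

    class Echo:
        def predict(self, X):
            return ds.labels

    rep = evaluate(Echo(), ds, split="train")
    assert rep.overall == 1.0
    assert np.all(rep.per_class.to_numpy() == 1.0)
    cm = rep.confusion.to_numpy()
    assert np.all(cm == np.diag(np.diag(cm)))


def test_evaluate_constant_predictor_on_balanced_classes():
    ds = _balanced_dataset()
    rep = evaluate(_Constant(2), ds, split="train")
    assert rep.overall == pytest.approx(1 / 9)


def test_evaluate_overall_is_weighted_mean_of_per_class():
    ds = _balanced_dataset(n_per_class=6)
    rng = np.random.default_rng(1)

    class Noisy:
        def predict(self, X):
            flip = rng.random(len(X)) < 0.3
            out = ds.labels.copy()
            out[flip] = rng.integers(1, 10, flip.sum())
            return out

    rep = evaluate(Noisy(), ds, split="train")
    cm = rep.confusion.to_numpy()
    assert cm.sum(axis=1).tolist() == [6] * 9  # row sums = class sizes
    weighted = (rep.per_class.to_numpy() * 6).sum() / (9 * 6)
    assert rep.overall == pytest.approx(weighted)
    assert np.trace(cm) / cm.sum() == pytest.approx(rep.overall)


def test_evaluate_empty_split_rejected():
    ds = _balanced_dataset()
    with pytest.raises(ValueError, match="empty"):
        evaluate(_Constant(1), ds, split="test")
    with pytest.raises(ValueError, match="split"):
        evaluate(_Constant(1), ds, split="validation")
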