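"""Spectral classifiers: a 1-D deep CNN and four batch back-propagation nets.

The DCNN consumes the band-intercepted spectrum directly (two convolution
modules of 32 and 64 filters, kernel and max-pool spanning 3 grid points,
batch normalization after each convolution module and before each of the five
fully connected layers, ReLU activations, dropout on the hidden dense layers,
softmax cross-entropy output, Adam optimizer).

The BPNN family is a fixed 40-40-40-9 multilayer perceptron (spectra are
linearly resampled to 40 input points) trained full-batch on mean squared
error against one-hot targets with one of four classical algorithms: resilient
back-propagation (Rprop) or conjugate gradients with the Fletcher-Reeves,
Polak-Ribiere, or Powell-Beale update.  The conjugate-gradient engine uses a
secant line search, which is exact on quadratics, so the textbook
finite-termination property holds and is tested.

Both classifiers follow the scikit-learn estimator protocol (``fit`` /
``predict`` / ``predict_proba``, ``get_params``, trailing-underscore fitted
attributes) and are fully deterministic given ``random_state``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.utils.validation import check_is_fitted

from ._net import (
    Adam,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    MaxPool1D,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "DCNNSpec",
    "BPNNSpec",
    "TrainedModel",
    "DCNNClassifier",
    "BPNNClassifier",
    "minimize_cg",
    "minimize_rprop",
    "train_dcnn",
    "train_bpnn",
    "evaluate",
    "EvaluationReport",
]

BPNN_ALGORITHMS = ("rp", "cgb", "cgf", "cgp")


# --------------------------------------------------------------------------
# Batch optimizers on a flat parameter vector
# --------------------------------------------------------------------------

def _secant_line_search(fun_grad, x, d, f0, g0d, alpha0):
    """Minimize f(x + a*d) along a descent direction.

    One secant step on the directional derivative (exact for quadratics),
    with backtracking as a safeguard.  Returns ``(alpha, f, g)`` at an
    improving point, or ``None`` if no decrease was found.
    """
    alpha1 = alpha0
    f1, g1 = fun_grad(x + alpha1 * d)
    candidates = [(f1, alpha1, g1)]
    denom = g0d - g1 @ d
    if abs(denom) > 1e-300:
        alpha2 = alpha1 * g0d / denom
        if np.isfinite(alpha2) and alpha2 > 0:
            f2, g2 = fun_grad(x + alpha2 * d)
            candidates.append((f2, alpha2, g2))
    f_best, a_best, g_best = min(candidates, key=lambda t: t[0])
    if f_best < f0:
        return a_best, f_best, g_best
    alpha = alpha1
    for _ in range(30):
        alpha *= 0.5
        f, g = fun_grad(x + alpha * d)
        if f < f0:
            return alpha, f, g
    return None


def minimize_cg(
    fun_grad,
    x0: np.ndarray,
    variant: str = "cgf",
    max_iter: int = 1000,
    goal: float = 0.0,
    lr: float = 0.1,
    callback=None,
):
    """Nonlinear conjugate gradient descent.

    ``variant``: ``cgf`` uses the Fletcher-Reeves beta ``g'g / g-'g-``,
    ``cgp`` the Polak-Ribiere beta ``g'(g - g-) / g-'g-``, and ``cgb`` the
    Powell-Beale scheme (Polak-Ribiere beta with a restart to steepest
    descent whenever ``|g-'g| >= 0.2 * ||g||^2``, i.e. successive gradients
    are far from orthogonal).  Directions also restart every ``len(x0)``
    iterations and whenever a candidate direction is not a descent direction.
    Stops at ``max_iter`` iterations, when the objective reaches ``goal``, or
    when the line search stalls.
    """
    if variant not in ("cgb", "cgf", "cgp"):
        raise ValueError(f"unknown CG variant {variant!r}")
    x = np.array(x0, dtype=float)
    f, g = fun_grad(x)
    history = [f]
    d = -g
    gg = g @ g
    alpha = lr / (1.0 + np.sqrt(gg))
    n = len(x)
    since_restart = 0
    for k in range(max_iter):
        if f <= goal or gg == 0.0:
            break
        g0d = g @ d
        if g0d >= 0:  # not a descent direction: restart
            d, g0d, since_restart = -g, -gg, 0
        ls = _secant_line_search(fun_grad, x, d, f, g0d, alpha)
        if ls is None:
            break
        alpha, f, g_new = ls
        x = x + alpha * d
        ggn = g_new @ g_new
        since_restart += 1
        restart = since_restart >= n
        if variant == "cgf":
            beta = ggn / gg
        else:  # cgp and cgb share the Polak-Ribiere numerator
            beta = g_new @ (g_new - g) / gg
        if variant == "cgb" and abs(g @ g_new) >= 0.2 * ggn:
            restart = True
        if restart or not np.isfinite(beta):
            d = -g_new
            since_restart = 0
        else:
            d = -g_new + beta * d
        g, gg = g_new, ggn
        history.append(f)
        if callback is not None:
            callback(x, f)
    return x, np.asarray(history)


def minimize_rprop(
    fun_grad,
    x0: np.ndarray,
    max_iter: int = 1000,
    goal: float = 0.0,
    delta0: float = 0.1,
    eta_plus: float = 1.2,
    eta_minus: float = 0.5,
    delta_max: float = 50.0,
    delta_min: float = 1e-6,
    callback=None,
):
    """Resilient back-propagation (iRprop-): sign-based step adaptation.

    Per-weight step sizes grow by ``eta_plus`` while the partial derivative
    keeps its sign and shrink by ``eta_minus`` when it flips (the flipped
    gradient entry is zeroed for one update, the iRprop- rule).  Gradient
    magnitudes never enter the update.
    """
    x = np.array(x0, dtype=float)
    delta = np.full_like(x, delta0)
    f, g = fun_grad(x)
    history = [f]
    g_prev = np.zeros_like(x)
    for _ in range(max_iter):
        if f <= goal:
            break
        prod = g * g_prev
        delta = np.clip(
            delta * np.where(prod < 0, eta_minus, np.where(prod > 0, eta_plus, 1.0)),
            delta_min,
            delta_max,
        )
        g_eff = np.where(prod < 0, 0.0, g)
        x = x - np.sign(g_eff) * delta
        g_prev = g_eff
        f, g = fun_grad(x)
        history.append(f)
        if callback is not None:
            callback(x, f)
    return x, np.asarray(history)


# --------------------------------------------------------------------------
# BPNN: fixed-architecture MLP trained full batch
# --------------------------------------------------------------------------

def _mlp_shapes(sizes):
    return [(sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]


def _mlp_unpack(flat, shapes):
    Ws, bs, pos = [], [], 0
    for n_in, n_out in shapes:
        Ws.append(flat[pos : pos + n_in * n_out].reshape(n_in, n_out))
        pos += n_in * n_out
        bs.append(flat[pos : pos + n_out])
        pos += n_out
    return Ws, bs


def _mlp_forward(X, Ws, bs):
    a = X
    acts = [a]
    for W, b in zip(Ws[:-1], bs[:-1]):
        a = np.tanh(a @ W + b)
        acts.append(a)
    out = expit(a @ Ws[-1] + bs[-1])  # logistic output
    acts.append(out)
    return acts


def _mlp_loss_grad(flat, X, T, shapes):
    """Mean squared error over all outputs and its flat gradient."""
    Ws, bs = _mlp_unpack(flat, shapes)
    acts = _mlp_forward(X, Ws, bs)
    out = acts[-1]
    err = out - T
    loss = float(np.mean(err**2))
    if not np.isfinite(loss):
        raise ArithmeticError(
            "non-finite loss during BPNN training; the optimization diverged"
        )
    grad = np.empty_like(flat)
    delta = (2.0 / err.size) * err * out * (1.0 - out)
    pos = len(flat)
    for i in range(len(Ws) - 1, -1, -1):
        dW = acts[i].T @ delta
        db = delta.sum(axis=0)
        pos -= len(db)
        grad[pos:pos + len(db)] = db
        pos -= dW.size
        grad[pos:pos + dW.size] = dW.ravel()
        if i > 0:
            delta = (delta @ Ws[i].T) * (1.0 - acts[i] ** 2)
    return loss, grad


class BPNNClassifier(BaseEstimator, ClassifierMixin):
    """Back-propagation network with a selectable batch training algorithm.

    Parameters
    ----------
    algorithm : {"rp", "cgb", "cgf", "cgp"}
        Resilient back-propagation or a conjugate-gradient variant
        (Powell-Beale, Fletcher-Reeves, Polak-Ribiere).
    hidden : tuple of int
        Hidden layer widths (two hidden layers of 40 by default).
    input_width : int or None
        Spectra are linearly resampled to this many points before entering
        the 40-node input layer; ``None`` uses the raw feature count.
    epochs, lr, goal
        Maximum iterations, learning-rate/initial-step factor, and the mean
        squared error at which training stops.
    """

    def __init__(
        self,
        algorithm: str = "rp",
        hidden: tuple = (40, 40),
        input_width: int | None = 40,
        epochs: int = 5000,
        lr: float = 0.1,
        goal: float = 1e-4,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.hidden = hidden
        self.input_width = input_width
        self.epochs = epochs
        self.lr = lr
        self.goal = goal
        self.random_state = random_state

    def _resample(self, X: np.ndarray) -> np.ndarray:
        if self.input_width is None or X.shape[1] == self.input_width:
            return X
        old = np.linspace(0.0, 1.0, X.shape[1])
        new = np.linspace(0.0, 1.0, self.input_width)
        return np.apply_along_axis(lambda row: np.interp(new, old, row), 1, X)

    def fit(self, X, y):
        if self.algorithm not in BPNN_ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {BPNN_ALGORITHMS}"
            )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        self.n_features_in_ = X.shape[1]
        Xr = self._resample(X)
        self.classes_, codes = np.unique(y, return_inverse=True)
        T = np.eye(len(self.classes_))[codes]
        sizes = [Xr.shape[1], *self.hidden, len(self.classes_)]
        shapes = _mlp_shapes(sizes)
        rng = np.random.default_rng(self.random_state)
        flat0 = np.concatenate(
            [
                arr
                for n_in, n_out in shapes
                for arr in (
                    rng.uniform(-1, 1, n_in * n_out) * np.sqrt(6.0 / (n_in + n_out)),
                    np.zeros(n_out),
                )
            ]
        )
        self._shapes = shapes
        accs = []

        def fun_grad(flat):
            return _mlp_loss_grad(flat, Xr, T, shapes)

        def record(flat, f):
            pred = self._decision(Xr, flat).argmax(axis=1)
            accs.append(float(np.mean(pred == codes)))

        if self.algorithm == "rp":
            flat, losses = minimize_rprop(
                fun_grad, flat0, max_iter=self.epochs, goal=self.goal,
                delta0=self.lr, callback=record,
            )
        else:
            flat, losses = minimize_cg(
                fun_grad, flat0, variant=self.algorithm, max_iter=self.epochs,
                goal=self.goal, lr=self.lr, callback=record,
            )
        self.coef_flat_ = flat
        self.history_ = {"loss": losses, "accuracy": np.asarray(accs)}
        return self

    def _decision(self, Xr, flat):
        Ws, bs = _mlp_unpack(flat, self._shapes)
        return _mlp_forward(Xr, Ws, bs)[-1]

    def predict_proba(self, X):
        check_is_fitted(self, "coef_flat_")
        X = np.asarray(X, dtype=float)
        out = self._decision(self._resample(X), self.coef_flat_)
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, X):
        check_is_fitted(self, "coef_flat_")
        X = np.asarray(X, dtype=float)
        out = self._decision(self._resample(X), self.coef_flat_)
        return self.classes_[out.argmax(axis=1)]


# --------------------------------------------------------------------------
# DCNN
# --------------------------------------------------------------------------

class DCNNClassifier(BaseEstimator, ClassifierMixin):
    """1-D convolutional network for per-spectrum classification.

    Two convolution modules (conv -> ReLU -> max-pool, batch-normalized at
    the module output) followed by five fully connected layers, each preceded
    by batch normalization; hidden dense layers use ReLU and dropout, the
    last layer is a softmax over the classes.  Trained with mini-batch Adam
    on cross-entropy; a fraction of the training data is held out as a
    per-epoch validation set (never used for weight updates).
    """

    def __init__(
        self,
        conv_filters: tuple = (32, 64),
        kernel_size: int = 3,
        pool_size: int = 3,
        fc_widths: tuple = (256, 128, 64, 32),
        dropout_rate: float = 0.3,
        epochs: int = 500,
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.99,
        batch_size: int = 128,
        val_fraction: float = 0.3,
        restore_best: bool = True,
        random_state: int = 0,
    ):
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.fc_widths = fc_widths
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.restore_best = restore_best
        self.random_state = random_state

    def _build(self, n_features: int, n_classes: int, rng) -> None:
        conv, length, c_in = [], n_features, 1
        for n_filt in self.conv_filters:
            conv.append(Conv1D(c_in, n_filt, self.kernel_size, rng))
            conv.append(ReLU())
            conv.append(MaxPool1D(self.pool_size))
            conv.append(BatchNorm(n_filt, spatial=True))
            length = (length - self.kernel_size + 1) // self.pool_size
            if length < 1:
                raise ValueError(
                    f"{n_features} spectral points are too few for the "
                    "configured convolution/pooling stack"
                )
            c_in = n_filt
        width = c_in * length
        fc = []
        for w in self.fc_widths:
            fc.append(BatchNorm(width))
            fc.append(Dense(width, w, rng))
            fc.append(ReLU())
            fc.append(Dropout(self.dropout_rate, rng))
            width = w
        fc.append(BatchNorm(width))
        fc.append(Dense(width, n_classes, rng))
        self._conv, self._fc = conv, fc

    def _forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        x = X[:, None, :]
        for layer in self._conv:
            x = layer.forward(x, train)
        self._pre_flatten = x.shape
        x = x.reshape(len(X), -1)
        for layer in self._fc:
            x = layer.forward(x, train)
        return x

    def _backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self._fc):
            dout = layer.backward(dout)
        dout = dout.reshape(self._pre_flatten)
        for layer in reversed(self._conv):
            dout = layer.backward(dout)

    _STATE_ATTRS = ("W", "b", "gamma", "beta", "run_mean", "run_var")

    def _get_state(self) -> list:
        return [
            getattr(layer, attr).copy()
            for layer in [*self._conv, *self._fc]
            for attr in self._STATE_ATTRS
            if hasattr(layer, attr)
        ]

    def _set_state(self, state: list) -> None:
        i = 0
        for layer in [*self._conv, *self._fc]:
            for attr in self._STATE_ATTRS:
                if hasattr(layer, attr):
                    setattr(layer, attr, state[i].copy())
                    i += 1

    def _eval_metrics(self, X, codes):
        logits = self._forward(X, train=False)
        loss, _ = softmax_cross_entropy(logits, np.eye(logits.shape[1])[codes])
        acc = float(np.mean(logits.argmax(axis=1) == codes))
        return loss, acc

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        rng = np.random.default_rng(self.random_state)
        self.classes_, codes = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        self._build(X.shape[1], len(self.classes_), rng)
        params, grads_of = [], []
        for layer in [*self._conv, *self._fc]:
            params.extend(layer.params)
            if layer.params:
                grads_of.append(layer)
        adam = Adam(params, self.learning_rate, self.beta1, self.beta2)

        # Stratified validation carve-out from the training data only.
        val_idx = []
        for cls in range(len(self.classes_)):
            idx = np.nonzero(codes == cls)[0]
            rng.shuffle(idx)
            val_idx.extend(idx[: int(np.floor(self.val_fraction * len(idx)))])
        val_mask = np.zeros(len(X), dtype=bool)
        val_mask[val_idx] = True
        Xt, ct = X[~val_mask], codes[~val_mask]
        Xv, cv = X[val_mask], codes[val_mask]
        onehot = np.eye(len(self.classes_))

        history = {k: [] for k in ("train_loss", "train_acc", "val_loss", "val_acc")}
        best_va, best_state = -np.inf, None
        order = np.arange(len(Xt))
        for _epoch in range(self.epochs):
            rng.shuffle(order)
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                if len(batch) < 2:
                    continue  # batch statistics are undefined for one sample
                logits = self._forward(Xt[batch], train=True)
                _, dz = softmax_cross_entropy(logits, onehot[ct[batch]])
                self._backward(dz)
                adam.step([g for layer in grads_of for g in layer.grads])
            tl, ta = self._eval_metrics(Xt, ct)
            history["train_loss"].append(tl)
            history["train_acc"].append(ta)
            if len(Xv):
                vl, va = self._eval_metrics(Xv, cv)
            else:
                vl, va = float("nan"), float("nan")
            history["val_loss"].append(vl)
            history["val_acc"].append(va)
            if self.restore_best and len(Xv) and va > best_va:
                best_va, best_state = va, self._get_state()
        if best_state is not None:
            # Keep the weights of the best validation epoch (the verification
            # split exists to pick the model state; ties keep the earliest).
            self._set_state(best_state)
        self.history_ = {k: np.asarray(v) for k, v in history.items()}
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "history_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"model was fit on {self.n_features_in_} spectral points, "
                f"got {X.shape[1]}"
            )
        out = []
        for start in range(0, len(X), 4096):
            out.append(softmax(self._forward(X[start : start + 4096], train=False)))
        return np.vstack(out)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


# --------------------------------------------------------------------------
# Spec dataclasses, functional wrappers, evaluation
# --------------------------------------------------------------------------

@dataclass
class DCNNSpec:
    """Hyperparameters of the DCNN (printed study defaults)."""

    conv_filters: tuple = (32, 64)
    kernel: int = 3
    pool: int = 3
    fc_widths: tuple = (256, 128, 64, 32)
    dropout_rate: float = 0.3
    epochs: int = 500
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.99
    batch_size: int = 128
    val_fraction: float = 0.3
    seed: int = 0


@dataclass
class BPNNSpec:
    """Hyperparameters of the BPNN family (printed study defaults)."""

    algorithm: str = "rp"
    hidden: tuple = (40, 40)
    input_width: int = 40
    learning_rate: float = 0.1
    epochs: int = 5000
    goal: float = 1e-4
    seed: int = 0


@dataclass
class TrainedModel:
    """A fitted classifier plus its spec, history, and class mapping."""

    estimator: object
    spec: dict
    history: dict
    class_map: dict = field(default_factory=dict)

    def predict(self, X):
        return self.estimator.predict(X)

    def predict_proba(self, X):
        return self.estimator.predict_proba(X)


def train_dcnn(dataset, spec: DCNNSpec | None = None) -> TrainedModel:
    """Fit the DCNN on a dataset's training split (test rows never seen)."""
    spec = spec or DCNNSpec()
    est = DCNNClassifier(
        conv_filters=tuple(spec.conv_filters),
        kernel_size=spec.kernel,
        pool_size=spec.pool,
        fc_widths=tuple(spec.fc_widths),
        dropout_rate=spec.dropout_rate,
        epochs=spec.epochs,
        learning_rate=spec.learning_rate,
        beta1=spec.beta1,
        beta2=spec.beta2,
        batch_size=spec.batch_size,
        val_fraction=spec.val_fraction,
        random_state=spec.seed,
    )
    X, y = dataset.train
    if len(X) == 0:
        raise ValueError("training split is empty")
    est.fit(X, y)
    return TrainedModel(
        est, asdict(spec), est.history_,
        {i: int(c) for i, c in enumerate(est.classes_)},
    )


def train_bpnn(dataset, spec: BPNNSpec | None = None) -> TrainedModel:
    """Fit one BPNN variant on a dataset's training split."""
    spec = spec or BPNNSpec()
    est = BPNNClassifier(
        algorithm=spec.algorithm,
        hidden=tuple(spec.hidden),
        input_width=spec.input_width,
        epochs=spec.epochs,
        lr=spec.learning_rate,
        goal=spec.goal,
        random_state=spec.seed,
    )
    X, y = dataset.train
    if len(X) == 0:
        raise ValueError("training split is empty")
    est.fit(X, y)
    return TrainedModel(
        est, asdict(spec), est.history_,
        {i: int(c) for i, c in enumerate(est.classes_)},
    )


@dataclass
class EvaluationReport:
    """Per-class and overall accuracy plus the confusion matrix."""

    overall: float
    per_class: pd.Series  # indexed by class label, values in [0, 1]
    confusion: pd.DataFrame  # rows = true class, columns = predicted


def evaluate(model, dataset, split: str = "test") -> EvaluationReport:
    """Score a trained model on one split of a labeled dataset."""
    if split == "train":
        X, y = dataset.train
    elif split == "test":
        X, y = dataset.test
    else:
        raise ValueError(f"split must be 'train' or 'test', got {split!r}")
    if len(X) == 0:
        raise ValueError(f"the {split} split is empty")
    pred = np.asarray(model.predict(X))
    labels = sorted(dataset.class_names)
    cm = confusion_matrix(y, pred, labels=labels)
    names = [dataset.class_names[c] for c in labels]
    confusion = pd.DataFrame(cm, index=names, columns=names)
    present = [c for c in labels if (y == c).any()]
    per_class = pd.Series(
        {c: float(np.mean(pred[y == c] == c)) for c in present}, dtype=float
    )
    return EvaluationReport(float(np.mean(pred == y)), per_class, confusion)
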