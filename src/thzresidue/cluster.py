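"""Fuzzy c-means clustering with Sammon projection of spectral datasets.

The "fuzzy Sammon" visualization clusters spectra with fuzzy c-means (FCM,
soft memberships governed by the weighting exponent ``m``) and then projects
samples (and cluster centers) to two dimensions by minimizing Sammon's
distance-distortion stress, so that inter-pattern distances in the plane
approximate those in spectral space.

Clustering quality against known class labels is scored under the optimal
one-to-one cluster-to-class assignment, making the score invariant to
arbitrary cluster numbering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

__all__ = [
    "FCMParams",
    "ClusterResult",
    "FuzzyCMeans",
    "SammonMapping",
    "fuzzy_cmeans",
    "sammon_project",
    "fuzzy_sammon",
    "clustering_accuracy",
]


@dataclass(frozen=True)
class FCMParams:
    """Fuzzy c-means settings (defaults follow the emulated study)."""

    n_clusters: int = 9
    m: float = 2.0  # weighting exponent
    t: int = 20  # maximum iterations
    s: float = 1.0  # iteration step size (initial Sammon learning factor)
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ValueError("weighting exponent m must be > 1")
        if self.t < 1:
            raise ValueError("max iterations t must be >= 1")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")


@dataclass
class ClusterResult:
    """FCM memberships/centers plus (optionally) a Sammon projection."""

    membership: np.ndarray  # (n_clusters, n_samples), columns sum to 1
    centers: np.ndarray  # (n_clusters, n_features)
    hard_labels: np.ndarray  # argmax-membership cluster index per sample
    objective_history: np.ndarray  # non-increasing FCM objective values
    projection: np.ndarray | None = None  # (n_samples, 2)
    center_projection: np.ndarray | None = None  # (n_clusters, 2)
    stress: float | None = None


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means clustering.

    Minimizes ``J = sum_i sum_k u_ik^m ||x_k - v_i||^2`` by alternating the
    closed-form membership and center updates.  Stops after ``max_iter``
    iterations or when the largest membership change falls below ``tol``.

    Attributes (after ``fit``): ``cluster_centers_``, ``membership_``
    (clusters x samples), ``labels_``, ``objective_history_``.
    """

    def __init__(
        self,
        n_clusters: int = 9,
        m: float = 2.0,
        max_iter: int = 20,
        tol: float = 1e-6,
        random_state: int | None = 0,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _memberships(self, d2: np.ndarray) -> np.ndarray:
        """Closed-form memberships from squared distances (clusters x n)."""
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (self.m - 1.0))
            u = inv / inv.sum(axis=0, keepdims=True)
        # A sample coincident with >= 1 center: full membership there.
        coincident = zero.any(axis=0)
        if coincident.any():
            u[:, coincident] = zero[:, coincident] / zero[:, coincident].sum(axis=0)
        return u

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        n = len(X)
        if n <= self.n_clusters:
            raise ValueError(
                f"need more samples ({n}) than clusters ({self.n_clusters})"
            )
        rng = np.random.default_rng(self.random_state)
        u = rng.random((self.n_clusters, n))
        u /= u.sum(axis=0, keepdims=True)
        history = []
        for _ in range(self.max_iter):
            um = u**self.m
            centers = (um @ X) / um.sum(axis=1, keepdims=True)
            d2 = cdist(centers, X, "sqeuclidean")
            u_new = self._memberships(d2)
            history.append(float((u_new**self.m * d2).sum()))
            delta = float(np.abs(u_new - u).max())
            u = u_new
            if delta < self.tol:
                break
        self.membership_ = u
        self.cluster_centers_ = centers
        self.labels_ = u.argmax(axis=0)
        self.objective_history_ = np.asarray(history)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d2 = cdist(self.cluster_centers_, X, "sqeuclidean")
        return self._memberships(d2).argmax(axis=0)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def fuzzy_cmeans(data: np.ndarray, params: FCMParams | None = None) -> ClusterResult:
    """Functional FCM front end returning a :class:`ClusterResult`."""
    params = params or FCMParams()
    est = FuzzyCMeans(
        n_clusters=params.n_clusters,
        m=params.m,
        max_iter=params.t,
        tol=params.tol,
        random_state=params.seed,
    ).fit(np.asarray(data))
    return ClusterResult(
        membership=est.membership_,
        centers=est.cluster_centers_,
        hard_labels=est.labels_,
        objective_history=est.objective_history_,
    )


def _sammon_stress(D: np.ndarray, Y: np.ndarray, c: float) -> float:
    d = squareform(pdist(Y))
    iu = np.triu_indices(len(Y), 1)
    Du, du = D[iu], d[iu]
    mask = Du > 0  # coincident input points are excluded from the stress
    return float((((Du - du) ** 2)[mask] / Du[mask]).sum() / c)


def sammon_project(
    points: np.ndarray,
    target_dim: int = 2,
    max_iter: int = 200,
    step: float = 1.0,
    tol: float = 1e-12,
) -> tuple[np.ndarray, float]:
    """Project points to ``target_dim`` dimensions by minimizing Sammon stress.

    ``E = (1 / sum d*_ij) * sum (d*_ij - d_ij)^2 / d*_ij`` over pairs with
    nonzero input distance ``d*``.  Gradient descent with the given initial
    step factor, halved whenever a trial step would increase the stress, so
    the stress is non-increasing over accepted iterations.  Initialization is
    the identity for 2-D input (lossless case) and the two leading principal
    directions otherwise.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or len(X) < 3:
        raise ValueError("need a 2-D array of at least 3 points")
    D = squareform(pdist(X))
    if np.count_nonzero(pdist(X)) == 0:
        raise ValueError("all points coincide; nothing to project")
    c = float(D[np.triu_indices(len(X), 1)].sum())

    if X.shape[1] == target_dim:
        Y = X.copy()
    else:
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        Y = Xc @ vt[:target_dim].T

    stress = _sammon_stress(D, Y, c)
    alpha = step
    safe_D = np.where(D > 0, D, 1.0)
    for _ in range(max_iter):
        if stress <= tol:
            break
        d = squareform(pdist(Y))
        np.fill_diagonal(d, 1.0)
        w = (d - D) / (safe_D * np.maximum(d, 1e-12))
        w[D <= 0] = 0.0
        np.fill_diagonal(w, 0.0)
        grad = (2.0 / c) * (w.sum(axis=1, keepdims=True) * Y - w @ Y)
        gnorm = np.linalg.norm(grad)
        if gnorm == 0:
            break
        accepted = False
        for _half in range(40):
            trial = Y - alpha * grad
            s_new = _sammon_stress(D, trial, c)
            if s_new < stress:
                Y, stress = trial, s_new
                alpha *= 1.1
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
    return Y, stress


class SammonMapping(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`sammon_project`."""

    def __init__(self, n_components: int = 2, max_iter: int = 200, step: float = 1.0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.step = step

    def fit_transform(self, X, y=None):
        Y, stress = sammon_project(
            X, target_dim=self.n_components, max_iter=self.max_iter, step=self.step
        )
        self.embedding_ = Y
        self.stress_ = stress
        return Y

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self


def fuzzy_sammon(
    data: np.ndarray,
    params: FCMParams | None = None,
    sammon_iter: int = 200,
) -> ClusterResult:
    """FCM followed by a joint Sammon projection of samples and centers."""
    params = params or FCMParams()
    result = fuzzy_cmeans(data, params)
    stacked = np.vstack([np.asarray(data, dtype=float), result.centers])
    Y, stress = sammon_project(stacked, max_iter=sammon_iter, step=params.s)
    n = len(data)
    result.projection = Y[:n]
    result.center_projection = Y[n:]
    result.stress = stress
    return result


def clustering_accuracy(hard_labels, truth) -> float:
    """Accuracy under the optimal one-to-one cluster-to-class assignment.

    Builds the cluster x class agreement matrix and solves the maximum-
    agreement assignment; classes left without a cluster (or vice versa)
    count as errors.  Invariant to relabeling of clusters.
    """
    hard_labels = np.asarray(hard_labels)
    truth = np.asarray(truth)
    if hard_labels.shape != truth.shape:
        raise ValueError("hard_labels and truth must have equal length")
    clusters, cl_inv = np.unique(hard_labels, return_inverse=True)
    classes, tr_inv = np.unique(truth, return_inverse=True)
    agreement = np.zeros((len(clusters), len(classes)), dtype=int)
    np.add.at(agreement, (cl_inv, tr_inv), 1)
    rows, cols = linear_sum_assignment(agreement, maximize=True)
    return float(agreement[rows, cols].sum() / len(truth))
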