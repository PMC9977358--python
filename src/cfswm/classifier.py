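"""Deterministic linear max-margin classifier for the decoding engine.

A primal L2-regularized squared-hinge support-vector classifier with unit
cost, solved by accelerated (FISTA-style) full-batch gradient descent with a
fixed step from the spectral norm of the design.  The objective is smooth and
strongly convex, so the solver is exactly repeatable — the same data and
labels always give the same hyperplane — which the balanced-resampling and
permutation procedures rely on.

The same solver trains *many* label vectors against one feature matrix in a
single batched call (`fit_batch`), which is what makes label-shuffling
permutation nulls with literal classifier refits affordable.
"""

from __future__ import annotations

import numpy as np


def _as_signed(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary binary labels to -1/+1; returns (signed, classes)."""
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    return np.where(y == classes[1], 1.0, -1.0), classes


def _spectral_norm_sq(Xa: np.ndarray, n_power_iter: int = 30) -> float:
    """Squared spectral norm by power iteration on Xa^T Xa (deterministic)."""
    n, d = Xa.shape
    if n <= d:
        G = Xa @ Xa.T
    else:
        G = Xa.T @ Xa
    v = np.ones(G.shape[0]) / np.sqrt(G.shape[0])
    for _ in range(n_power_iter):
        w = G @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 0.0
        v = w / nrm
    return float(v @ (G @ v))


def fit_linear_svm_batch(
    X: np.ndarray,
    Y_signed: np.ndarray,
    C: float = 1.0,
    n_iter: int = 400,
    tol: float = 1e-4,
    include: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Train one squared-hinge linear SVM per row of ``Y_signed``.

    X is (n_samples, n_features); Y_signed is (n_problems, n_samples) with
    entries in {-1, +1}.  Returns weights (n_problems, n_features) and
    intercepts (n_problems,).  ``include`` (n_problems, n_samples, boolean)
    optionally restricts each problem to a subset of the samples — this is
    how balanced-resampling iterations share one batched call.

    The objective is 1-strongly convex (unit L2 penalty) with
    L = 1 + 2C ||Xa||^2 Lipschitz gradient, so constant-momentum Nesterov
    descent converges linearly; iteration stops early once the largest
    gradient entry across problems falls below ``tol`` (checked
    periodically), capped at ``n_iter``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y_signed, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != X.shape[0]:
        raise ValueError("Y_signed must be (n_problems, n_samples)")
    mask = None
    if include is not None:
        mask = np.asarray(include, dtype=float)
        if mask.shape != Y.shape:
            raise ValueError("include must match Y_signed's shape")
    n, d = X.shape
    # With more voxels than trials the optimum lies in the row space of X
    # (representer property of the L2 penalty), so train on the rotated
    # n-dimensional features U S and map the weights back through V^T.
    basis = None
    if d > n:
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        X = U * S
        basis = Vt
        d = X.shape[1]
    Xa = np.hstack([X, np.ones((n, 1))])
    L = 1.0 + 2.0 * C * _spectral_norm_sq(Xa)
    step = 1.0 / L
    sqrt_kappa = np.sqrt(L)  # strong convexity constant is 1
    beta = (sqrt_kappa - 1.0) / (sqrt_kappa + 1.0)
    m = Y.shape[0]
    W = np.zeros((m, d + 1))
    V = W.copy()
    for it in range(n_iter):
        margins = Y * (V @ Xa.T)
        slack = np.minimum(margins - 1.0, 0.0)
        if mask is not None:
            slack *= mask
        grad = V.copy()
        grad[:, -1] = 0.0  # intercept is unregularized
        grad += 2.0 * C * ((slack * Y) @ Xa)
        W_new = V - step * grad
        V = W_new + beta * (W_new - W)
        W = W_new
        if it % 25 == 24 and np.max(np.abs(grad)) < tol:
            break
    weights, intercept = W[:, :-1], W[:, -1]
    if basis is not None:
        weights = weights @ basis
    return weights, intercept


class LinearMaxMargin:
    """Scikit-learn-style facade over the batched primal solver."""

    def __init__(self, C: float = 1.0, n_iter: int = 400):
        self.C = C
        self.n_iter = n_iter

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearMaxMargin":
        y = np.asarray(y)
        signed, classes = _as_signed(y)
        W, b = fit_linear_svm_batch(X, signed[None, :], C=self.C, n_iter=self.n_iter)
        self.coef_ = W[0]
        self.intercept_ = float(b[0])
        self.classes_ = classes
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    fold_of: np.ndarray,
    C: float = 1.0,
    n_iter: int = 400,
) -> float:
    """Pooled cross-validated accuracy over the folds in ``fold_of``.

    ``fold_of`` assigns each row of X to a fold id (>= 0); rows with fold -1
    are ignored.  Each fold is scored by a classifier trained on all other
    folds; accuracy is the pooled fraction of correct test predictions.
    """
    return float(cv_accuracy_batch(X, np.asarray(y)[None, :], fold_of, C=C, n_iter=n_iter)[0])


def cv_accuracy_batch(
    X: np.ndarray,
    Y: np.ndarray,
    fold_of: np.ndarray,
    C: float = 1.0,
    n_iter: int = 400,
    include: np.ndarray | None = None,
) -> np.ndarray:
    """Pooled CV accuracy for many label vectors on one feature matrix.

    Y is (n_problems, n_samples) of binary labels (any two values; the
    class coding is per problem row).  Per fold, all problems are trained
    in one batched call.  ``include`` (n_problems, n_samples) restricts
    each problem to a trial subset for both training and scoring.
    Returns (n_problems,) accuracies.
    """
    Y = np.asarray(Y)
    m, n = Y.shape
    signed = np.empty((m, n))
    for i in range(m):
        signed[i], _ = _as_signed(Y[i])
    inc = None if include is None else np.asarray(include, dtype=bool)
    correct = np.zeros(m)
    total = np.zeros(m)
    for f in np.unique(fold_of[fold_of >= 0]):
        train = (fold_of >= 0) & (fold_of != f)
        test = fold_of == f
        train_mask = None if inc is None else inc[:, train]
        W, b = fit_linear_svm_batch(
            X[train], signed[:, train], C=C, n_iter=n_iter, include=train_mask
        )
        scores = W @ X[test].T + b[:, None]
        hits = (scores > 0) == (signed[:, test] > 0)
        if inc is None:
            correct += hits.sum(axis=1)
            total += int(test.sum())
        else:
            correct += (hits & inc[:, test]).sum(axis=1)
            total += inc[:, test].sum(axis=1)
    return correct / total
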