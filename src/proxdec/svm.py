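"""Hard-working-set SMO solver for the linear soft-margin SVM.

The decoding analyses train tens of thousands of linear SVMs on very small
samples (4-60 patterns), so the trainer is implemented directly as a
numba-compiled SMO (sequential minimal optimization) on the dual problem

    min  1/2 a' Q a - 1' a     s.t.  0 <= a_i <= C,  sum_i y_i a_i = 0,

with ``Q_ij = y_i y_j <x_i, x_j>`` -- the same quadratic program solved by
libsvm's C-SVC, with hinge loss and fixed regularization constant ``C``
(default 1).  Working-set selection is the maximal-violating-pair rule and
updates are the exact two-variable analytic solution, so for a fixed input
the result is deterministic.  Agreement with an off-the-shelf SVM
implementation is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["LinearModel", "train_svm", "svm_weights"]


@dataclass
class LinearModel:
    """A trained linear decision function ``f(x) = w . x + b``.

    The class ordering is fixed by the caller: label +1 maps to "wide"
    (shape decoding) or to orientation A (background-matched decoding).
    """

    weights: np.ndarray
    bias: float
    training_meta: dict = field(default_factory=dict)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias


@njit(cache=True)
def _smo(K, y, C, tol, max_iter):  # pragma: no cover - exercised via train_svm
    n = K.shape[0]
    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of the dual objective at alpha = 0
    for _ in range(max_iter):
        # maximal violating pair over I_up / I_low
        i, j = -1, -1
        gmax, gmin = -1e300, 1e300
        for t in range(n):
            yg = -y[t] * grad[t]
            if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
                if yg > gmax:
                    gmax, i = yg, t
            if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C):
                if yg < gmin:
                    gmin, j = yg, t
        if i < 0 or j < 0 or gmax - gmin < tol:
            break
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if quad <= 1e-12:
            quad = 1e-12
        step = (gmax - gmin) / quad  # unclipped step along (y_i, -y_j)
        # box constraints on both coordinates
        if y[i] > 0:
            step = min(step, C - alpha[i])
        else:
            step = min(step, alpha[i])
        if y[j] > 0:
            step = min(step, alpha[j])
        else:
            step = min(step, C - alpha[j])
        if step <= 0.0:
            break
        alpha[i] += y[i] * step
        alpha[j] -= y[j] * step
        for t in range(n):
            grad[t] += y[t] * step * (K[t, i] - K[t, j])
    # intercept from the KKT conditions
    nf = 0
    bsum = 0.0
    ub, lb = 1e300, -1e300
    for t in range(n):
        g = y[t] - (grad[t] + 1.0) * y[t]  # y_t - sum_j a_j y_j K_tj
        if 0.0 < alpha[t] < C:
            bsum += g
            nf += 1
        elif (y[t] > 0 and alpha[t] == 0.0) or (y[t] < 0 and alpha[t] == C):
            ub = min(ub, g)
        else:
            lb = max(lb, g)
    if nf > 0:
        b = bsum / nf
    else:
        b = 0.5 * (ub + lb)
    return alpha, b


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    meta: dict | None = None,
) -> LinearModel:
    """Train a maximum-margin linear classifier with hinge loss.

    ``y`` must contain both labels -1 and +1.  Deterministic for fixed inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be samples x features with one label per sample")
    present = set(np.unique(y).tolist())
    if present != {-1.0, 1.0}:
        missing = {-1.0, 1.0} - present
        extra = present - {-1.0, 1.0}
        if extra:
            raise ValueError(f"labels must be -1/+1, got {sorted(present)}")
        raise ValueError(f"missing class {sorted(missing)} in training labels")
    K = X @ X.T
    alpha, b = _smo(np.ascontiguousarray(K), y, float(C), float(tol), int(max_iter))
    w = X.T @ (alpha * y)
    if not (np.all(np.isfinite(w)) and np.isfinite(b)):
        raise FloatingPointError("SVM training produced non-finite parameters")
    m = {"C": C}
    if meta:
        m.update(meta)
    return LinearModel(weights=w, bias=float(b), training_meta=m)


def svm_weights(X: np.ndarray, y: np.ndarray, C: float = 1.0):
    """Convenience wrapper returning ``(weights, bias)``."""
    model = train_svm(X, y, C=C)
    return model.weights, model.bias
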