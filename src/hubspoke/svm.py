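"""Linear soft-margin SVM (LIBSVM backend) for tiny searchlight problems.

A searchlight analysis fits the classifier hundreds of thousands of times on
problems with ~6 samples and ~10^2 features, where the input-validation
overhead of the high-level scikit-learn estimator dominates runtime by two
orders of magnitude. This module therefore calls scikit-learn's bundled
LIBSVM binding directly (the same C-SVC solver, fixed C) and exposes a
minimal linear decision model. Equality with ``sklearn.svm.SVC`` and with a
brute-force dual quadratic program is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import _libsvm

_libsvm.set_verbosity_wrap(0)


@dataclass
class LinearSVM:
    """Linear decision model: predict classes[1] if w.x + b > 0, classes[0]
    if < 0; a decision value of exactly 0 resolves to classes[0] (the first
    class in sorted label order) and is flagged."""

    weights: np.ndarray
    bias: float
    classes: tuple
    n_tie_predictions: int = 0

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights + self.bias

    def predict(self, X):
        d = self.decision_function(X)
        self.n_tie_predictions += int(np.sum(d == 0.0))
        return np.where(d > 0, self.classes[1], self.classes[0])


def train_linear_svm(features, classes, C: float = 1.0) -> LinearSVM:
    """Train a binary linear C-SVM (LIBSVM C-SVC, kernel='linear').

    Parameters
    ----------
    features : (n_samples, n_features) array
    classes : length-n_samples label sequence with exactly two distinct values
    C : soft-margin regularization constant (> 0), fixed at 1 in the analyses.
    """
    X = np.ascontiguousarray(np.asarray(features, dtype=np.float64))
    if X.ndim != 2:
        raise ValueError("features must be 2D (samples x voxels)")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if C <= 0:
        raise ValueError("C must be > 0")
    y = np.asarray(classes)
    if y.shape[0] != X.shape[0]:
        raise ValueError("classes length does not match sample count")
    uniq = sorted(set(y.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"exactly two classes required, got {uniq}")
    y_enc = np.asarray([uniq.index(v) for v in y], dtype=np.float64)

    # tight stopping tolerance: the searchlight problems are tiny, and a
    # loosely converged hyperplane would make label-swap symmetry only
    # approximate
    out = _libsvm.fit(X, y_enc, svm_type=0, kernel="linear", C=float(C), tol=1e-8)
    support_vectors, dual_coef, intercept = out[1], out[3], out[4]
    # The binding groups classes in sorted label order and returns a decision
    # function positive toward the first class; negate so positive values
    # point at uniq[1] (the sklearn convention).
    w = -(dual_coef @ support_vectors).ravel()
    b = -float(intercept[0])
    return LinearSVM(weights=w, bias=b, classes=tuple(uniq))
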