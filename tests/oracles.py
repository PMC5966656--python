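"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
brute-force enumeration for pattern extraction, a box-constrained dual
quadratic program for the SVM, and plain counting for accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from adrcause.patterns import WILDCARD


def ngrams_bruteforce(tokens, n):
    """Every contiguous window of length n, as a set."""
    toks = tuple(tokens)
    return {toks[i : i + n] for i in range(len(toks) - n + 1)}


def skipgrams_bruteforce(tokens, n, max_wildcards=1):
    """Windows plus all single-position wildcard substitutions, deduplicated."""
    out = set()
    for window in ngrams_bruteforce(tokens, n):
        out.add(window)
        if max_wildcards >= 1 and n >= 2:
            for j in range(n):
                out.add(window[:j] + (WILDCARD,) + window[j + 1 :])
    return out


def svm_dual_qp(X, y, C):
    """Solve the no-intercept soft-margin SVM via its dual box QP.

    min_a  ½ aᵀQa − Σa   s.t. 0 ≤ a ≤ C,   Q_ij = y_i y_j x_i·x_j;
    then w = Σ a_i y_i x_i. Returns (w, primal objective at w).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    Q = (y[:, None] * X) @ (y[:, None] * X).T

    def fun(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    res = minimize(
        fun,
        x0=np.zeros(n),
        jac=grad,
        method="L-BFGS-B",
        bounds=[(0.0, C)] * n,
        options={"maxiter": 10000, "ftol": 1e-16, "gtol": 1e-12},
    )
    a = res.x
    w = (a * y) @ X
    slack = np.maximum(0.0, 1.0 - y * (X @ w))
    primal = 0.5 * w @ w + C * slack.sum()
    return w, float(primal)


def counting_accuracy(preds, labels):
    """Accuracy (%) by explicit counting."""
    correct = sum(1 for p, l in zip(preds, labels) if p == l)
    return 100.0 * correct / len(labels)
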