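"""Independent naive reference implementations used as test oracles.

Everything here is written with explicit Python loops, independent of the
vectorised library code it is used to check.
"""

from __future__ import annotations

import numpy as np


def naive_squared_distance(omega, w, x):
    """(x−w)ᵀ ΩᵀΩ (x−w) via explicit triple loop."""
    d = len(x)
    lam = [[0.0] * d for _ in range(d)]
    for i in range(d):
        for j in range(d):
            for k in range(d):
                lam[i][j] += omega[k][i] * omega[k][j]
    total = 0.0
    for i in range(d):
        for j in range(d):
            total += (x[i] - w[i]) * lam[i][j] * (x[j] - w[j])
    return total


def naive_mu(prototypes, proto_labels, omega, x, label):
    """Relative distance μ = (d_J − d_K)/(d_J + d_K) by exhaustive scan."""
    dj = min(
        naive_squared_distance(omega, w, x)
        for w, l in zip(prototypes, proto_labels)
        if l == label
    )
    dk = min(
        naive_squared_distance(omega, w, x)
        for w, l in zip(prototypes, proto_labels)
        if l != label
    )
    if dj + dk == 0:
        return 0.0
    return (dj - dk) / (dj + dk)


def naive_cost(prototypes, proto_labels, omega, X, y):
    return sum(
        naive_mu(prototypes, proto_labels, omega, x, label)
        for x, label in zip(X, y)
    )


def naive_predict(prototypes, proto_labels, omega, x):
    """Nearest prototype by exhaustive scan; ties to lowest label."""
    dists = [naive_squared_distance(omega, w, x) for w in prototypes]
    best = min(dists)
    return min(l for d, l in zip(dists, proto_labels) if d == best)


def pairwise_concordance_auc(scores, labels):
    """AUC as the probability a positive outscores a negative, half credit
    for ties, by exhaustive pair enumeration."""
    scores = list(scores)
    labels = [bool(l) for l in labels]
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    if not pos or not neg:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def finite_difference_gradients(cost_fn, model, eps=1e-5):
    """Central finite differences of ``cost_fn(prototypes, omega)`` w.r.t.
    every prototype coordinate and every Ω entry."""
    W = model.prototypes.copy()
    O = model.omega.copy()
    grad_w = np.zeros_like(W)
    for p in range(W.shape[0]):
        for j in range(W.shape[1]):
            Wp, Wm = W.copy(), W.copy()
            Wp[p, j] += eps
            Wm[p, j] -= eps
            grad_w[p, j] = (cost_fn(Wp, O) - cost_fn(Wm, O)) / (2 * eps)
    grad_o = np.zeros_like(O)
    for i in range(O.shape[0]):
        for j in range(O.shape[1]):
            Op, Om = O.copy(), O.copy()
            Op[i, j] += eps
            Om[i, j] -= eps
            grad_o[i, j] = (cost_fn(W, Op) - cost_fn(W, Om)) / (2 * eps)
    return grad_w, grad_o
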