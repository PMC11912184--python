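"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written against the *definitions* (scalar loops, pairwise
counts, step-up formulas, finite differences), not against the vectorized
code paths it validates.
"""

from __future__ import annotations

import math

import numpy as np


def loop_forward(params, x_values: np.ndarray) -> dict[str, np.ndarray]:
    """Scalar triple-loop forward pass through the full network."""
    n, G, _ = x_values.shape
    P = params.mask_gp.shape[1]
    C = params.mask_pc.shape[1]
    act = math.tanh if params.activation == "tanh" else (lambda v: v)
    h1 = np.zeros((n, G)); h2 = np.zeros((n, P)); h3 = np.zeros((n, C))
    p1 = np.zeros(n); p2 = np.zeros(n); p3 = np.zeros(n)
    for s in range(n):
        for i in range(G):
            z = params.b_gene[i]
            for j in range(4):
                z += params.w_gene[i, j] * x_values[s, i, j]
            h1[s, i] = act(z)
        for p in range(P):
            z = params.b_p[p]
            for i in range(G):
                z += params.mask_gp[i, p] * params.w_gp[i, p] * h1[s, i]
            h2[s, p] = act(z)
        for c in range(C):
            z = params.b_c[c]
            for p in range(P):
                z += params.mask_pc[p, c] * params.w_pc[p, c] * h2[s, p]
            h3[s, c] = act(z)
        for h, w, b, out in ((h1, params.head_gene_w, params.head_gene_b, p1),
                             (h2, params.head_pathway_w, params.head_pathway_b, p2),
                             (h3, params.head_out_w, params.head_out_b, p3)):
            z = b
            for i in range(h.shape[1]):
                z += w[i] * h[s, i]
            out[s] = 1.0 / (1.0 + math.exp(-z))
    return {"h1": h1, "h2": h2, "h3": h3, "p1": p1, "p2": p2, "p3": p3}


def plain_mlp_forward(x_values, w_gene, b_gene, w2, b2, w3, b3, head_w, head_b):
    """Dense (unmasked) MLP with the combiner front end: the dense-equivalence
    oracle for all-ones masks."""
    z1 = np.einsum("ngj,gj->ng", x_values, w_gene) + b_gene
    h1 = np.tanh(z1)
    h2 = np.tanh(h1 @ w2 + b2)
    h3 = np.tanh(h2 @ w3 + b3)
    return 1.0 / (1.0 + np.exp(-(h3 @ head_w + head_b)))


def fd_gradient(f, x0: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x0."""
    x0 = np.asarray(x0, dtype=float)
    grad = np.zeros_like(x0)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x0.copy(); xp[idx] += eps
        xm = x0.copy(); xm[idx] -= eps
        grad[idx] = (f(xp) - f(xm)) / (2 * eps)
    return grad


def auc_pairwise(y, scores) -> float:
    """Fraction of correctly ordered (positive, negative) pairs, ties half."""
    y = np.asarray(y); scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]; neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def delong_components_bruteforce(scores, y):
    """Structural components by O(m*n) pairwise psi sums."""
    scores = np.asarray(scores, dtype=float); y = np.asarray(y)
    pos = scores[y == 1]; neg = scores[y == 0]
    m, n = len(pos), len(neg)
    psi = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            psi[i, j] = 1.0 if pos[i] > neg[j] else (0.5 if pos[i] == neg[j] else 0.0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return psi.mean(), v10, v01


def delong_variance_bruteforce(scores_a, scores_b, y) -> tuple[float, float]:
    """(AUC difference, variance) straight from the structural components."""
    auc_a, v10_a, v01_a = delong_components_bruteforce(scores_a, y)
    auc_b, v10_b, v01_b = delong_components_bruteforce(scores_b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    return auc_a - auc_b, var


def bh_stepup(pvals) -> np.ndarray:
    """Literal step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = min(running_min, 1.0)
    return q
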