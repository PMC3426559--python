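"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the Procrustes oracle
searches rotation space on a dense grid instead of using the SVD closed
form, the PCA oracle goes through the SVD of the standardized matrix
instead of the eigendecomposition of Y Y^T, and the FST oracle is a plain
scalar-loop transcription of the published variance-component formulas.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


def brute_force_t0(X, Y, allow_reflection=True, n_grid=7200):
    """Max Procrustes similarity over a dense rotation grid with closed-form
    optimal scale/translation at each fixed orthogonal map, plus a local
    refinement around the best grid angle."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    trX = (Xc ** 2).sum()
    trY = (Yc ** 2).sum()
    A = Yc.T @ Xc
    denom = math.sqrt(trX * trY)

    def t0_at(theta, reflect):
        c, s = math.cos(theta), math.sin(theta)
        Q = np.array([[c, s], [-s, c]])
        if reflect:
            Q = np.diag([1.0, -1.0]) @ Q
        # for fixed Q the optimal positive scale gives t0 = max(tr, 0)/denom
        return max(np.trace(Q.T @ A), 0.0) / denom

    families = (False, True) if allow_reflection else (False,)
    best = 0.0
    thetas = np.linspace(-math.pi, math.pi, n_grid, endpoint=False)
    for reflect in families:
        vals = [t0_at(t, reflect) for t in thetas]
        i = int(np.argmax(vals))
        step = 2 * math.pi / n_grid
        res = minimize_scalar(lambda t: -t0_at(t, reflect),
                              bounds=(thetas[i] - step, thetas[i] + step),
                              method="bounded",
                              options={"xatol": 1e-12})
        best = max(best, vals[i], -res.fun)
    return best


def svd_pca(Y):
    """Row-space coordinates and eigenvalues from the SVD of the
    standardized matrix (top n-1 components)."""
    n = Y.shape[0]
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    k = min(n - 1, len(s))
    scores = U[:, :k] * s[:k]
    lam = s[:k] ** 2
    pad = (n - 1) - k
    if pad > 0:
        scores = np.hstack([scores, np.zeros((n, pad))])
        lam = np.concatenate([lam, np.zeros(pad)])
    return scores, lam


def wc_theta_loops(values, missing, populations):
    """Scalar-loop Weir-Cockerham theta: ratio of summed components.

    values/missing are (n, L); populations a length-n label list.
    Returns (theta, a_sum, abc_sum, loci_used).
    """
    pops = sorted(set(populations))
    n, L = values.shape
    a_sum = abc_sum = 0.0
    used = 0
    for l in range(L):
        ns, ps, hs = [], [], []
        for pop in pops:
            idx = [i for i in range(n) if populations[i] == pop and not missing[i, l]]
            if not idx:
                continue
            ni = len(idx)
            ns.append(ni)
            ps.append(sum(values[i, l] for i in idx) / (2 * ni))
            hs.append(sum(1 for i in idx if values[i, l] == 1) / ni)
        r = len(ns)
        if r < 2:
            continue
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        ntot = sum(ns)
        nc = (ntot - sum(x * x for x in ns) / ntot) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(ns, ps)) / ntot
        if pbar <= 0 or pbar >= 1:
            continue
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(ns, hs)) / ntot
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        abc_sum += a + b + c
        used += 1
    return a_sum / abc_sum, a_sum, abc_sum, used


def random_similarity(rng, allow_reflection=True):
    """A random 2-D similarity transform as (matrix, translation)."""
    theta = rng.uniform(-math.pi, math.pi)
    c, s = math.cos(theta), math.sin(theta)
    Q = np.array([[c, s], [-s, c]])
    if allow_reflection and rng.random() < 0.5:
        Q = Q @ np.diag([1.0, -1.0])
    scale = rng.uniform(0.2, 5.0)
    t = rng.uniform(-10, 10, size=2)
    return scale * Q, t
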