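"""Independent reference implementations used only to check the package.

Everything here is written as directly as possible from the defining
formulas (explicit loops, exhaustive enumeration, straight-line
transcription) and never calls into the code paths it checks.
"""

import itertools

import numpy as np


def enum_corruption_expect(M, q, func):
    """Exact E[func(Mtilde)] by summing over all 2^(n*m) corruption patterns.

    Each entry of M is independently kept (prob q) or zeroed (prob 1-q).
    """
    M = np.asarray(M, dtype=float)
    idx = list(np.ndindex(M.shape))
    total = None
    for keep in itertools.product((0, 1), repeat=len(idx)):
        Mt = M.copy()
        w = 1.0
        for pos, k in zip(idx, keep):
            if k:
                w *= q
            else:
                Mt[pos] = 0.0
                w *= 1.0 - q
    # accumulate probability-weighted values
        val = np.asarray(func(Mt), dtype=float) * w
        total = val if total is None else total + val
    return total


def mc_corruption_expect(M, q, func, n_samples, seed):
    """Monte-Carlo estimate of E[func(Mtilde)] with a seeded generator.

    Uses antithetic uniforms (u and 1-u) in pairs: both masks are exact
    Bernoulli(q) keep-masks, so the estimator stays unbiased while the
    negative correlation between the paired masks lowers its variance.
    """
    M = np.asarray(M, dtype=float)
    rng = np.random.default_rng(seed)
    total = None
    for _ in range(n_samples // 2):
        u = rng.random(M.shape)
        for mask in (u < q, (1.0 - u) < q):
            val = np.asarray(func(M * mask), dtype=float)
            total = val if total is None else total + val
    return total / (2 * (n_samples // 2))


def brute_force_auc(labels, scores):
    """O(P*N) pairwise Mann-Whitney statistic with half-credit for ties."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def step_rule_aupr(labels, scores):
    """Independent transcription of the average-precision step rule."""
    labels = np.asarray(labels).astype(float)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    area = 0.0
    recall_prev = 0.0
    for thr in sorted(set(scores), reverse=True):
        sel = scores >= thr
        tp = labels[sel].sum()
        precision = tp / sel.sum()
        recall = tp / n_pos
        area += (recall - recall_prev) * precision
        recall_prev = recall
    return area


def transcribed_fusion(K1, K2, K3, k_nn, n_iters):
    """Straight-line loop transcription of the normalize/localize/diffuse
    recurrences, independent of the package's vectorized implementation."""
    Ks = [np.asarray(K, dtype=float) for K in (K1, K2, K3)]
    n = Ks[0].shape[0]

    def normalize(K):
        P = np.zeros((n, n))
        for i in range(n):
            denom = sum(K[i, k] for k in range(n) if k != i)
            for j in range(n):
                if j == i:
                    P[i, j] = 0.5
                elif denom > 0:
                    P[i, j] = K[i, j] / (2.0 * denom)
                else:
                    P[i, j] = 1.0 / (2.0 * (n - 1))
        return P

    def localize(P, k_nn):
        L = np.zeros((n, n))
        for i in range(n):
            order = sorted((j for j in range(n) if j != i),
                           key=lambda j: (-P[i, j], j))
            neigh = [i] + order[: k_nn - 1]
            denom = sum(P[i, j] for j in neigh)
            for j in neigh:
                L[i, j] = P[i, j] / denom
        return L

    Ps = [normalize(K) for K in Ks]
    Ls = [localize(P, k_nn) for P in Ps]
    I = np.eye(n)
    for _ in range(n_iters):
        new = []
        for a in range(3):
            others = [Ps[b] for b in range(3) if b != a]
            Q = Ls[a] @ ((others[0] + others[1]) / 2.0) @ Ls[a].T
            new.append(Q)
        Ps = [0.5 * (Q + Q.T) + I for Q in new]
    return (Ps[0] + Ps[1] + Ps[2]) / 3.0


def transcribed_reconstruction(U, V, b, M):
    """Entry-wise transcription of M* = U U' M + M V V' M' + b (row offset)."""
    d = M.shape[0]
    L = U @ U.T
    G = V @ V.T
    out = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            s = sum(L[i, l] * M[l, j] for l in range(d))
            s += sum(M[i, l] * G[l, k] * M[j, k]
                     for l in range(d) for k in range(d))
            out[i, j] = s + b[i]
    return out
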