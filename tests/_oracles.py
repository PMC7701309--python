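"""Independent slow reference implementations used only by the tests."""

from __future__ import annotations

import numpy as np


def objective(omegas, covs, lam):
    """Penalized objective computed entry-by-entry, no shared code paths."""
    m = len(covs)
    val = 0.0
    for om, s in zip(omegas, covs):
        val += np.trace(om @ s) - np.log(np.linalg.det(om))
    val /= m
    p = covs[0].shape[0]
    for u in range(p):
        for v in range(p):
            if u != v:
                val += lam * np.sqrt(sum(om[u, v] ** 2 for om in omegas))
    return val


def prox_gradient_minimize(covs, lam, n_iter=20000, tol=1e-12):
    """Proximal-gradient minimizer of the neighborhood objective.

    Brute-force reference: gradient step on the smooth part with
    backtracking (rejecting non-PD iterates), groupwise soft-threshold on
    the off-diagonals. Slow but independent of the ADMM implementation.
    """
    covs = [np.asarray(s, float) for s in covs]
    m = len(covs)
    p = covs[0].shape[0]
    X = np.stack([np.diag(1.0 / np.diag(s)) for s in covs])
    t = 1.0

    def smooth(Xs):
        val = 0.0
        for i in range(m):
            sign, logdet = np.linalg.slogdet(Xs[i])
            if sign <= 0:
                return np.inf
            val += np.trace(Xs[i] @ covs[i]) - logdet
        return val / m

    def prox(A, step):
        norms = np.sqrt((A**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            fac = np.maximum(0.0, 1.0 - lam * step / norms)
        fac[~np.isfinite(fac)] = 0.0
        Z = A * fac[None]
        for i in range(m):
            np.fill_diagonal(Z[i], np.diag(A[i]))
        return Z

    f_old = smooth(X)
    for _ in range(n_iter):
        grad = np.stack([(covs[i] - np.linalg.inv(X[i])) / m for i in range(m)])
        grad = 0.5 * (grad + grad.transpose(0, 2, 1))
        while True:
            Xn = prox(X - t * grad, t)
            fs = smooth(Xn)
            if np.isfinite(fs):
                diff = Xn - X
                bound = (
                    smooth(X)
                    + (grad * diff).sum()
                    + (diff**2).sum() / (2 * t)
                )
                if fs <= bound + 1e-15:
                    break
            t *= 0.5
            if t < 1e-12:
                break
        move = np.abs(Xn - X).max()
        X = Xn
        t = min(t * 1.5, 10.0)
        if move < tol:
            break
    return [X[i] for i in range(m)]


def weighted_covariance_loop(values, weights):
    """Entrywise weighted sum of outer products (independent of einsum path)."""
    p, n = values.shape
    out = np.zeros((p, p))
    for j in range(n):
        x = values[:, j]
        for a in range(p):
            for b in range(p):
                out[a, b] += weights[j] * x[a] * x[b]
    return out


def bfs_diameter(edges):
    """Max shortest-path length over connected pairs, by explicit BFS."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    best = 0
    for src in adj:
        dist = {src: 0}
        queue = [src]
        while queue:
            node = queue.pop(0)
            for nb in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    queue.append(nb)
        best = max(best, max(dist.values()))
    return best


def f1_score(est, true):
    tp = len(est & true)
    fp = len(est - true)
    fn = len(true - est)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0


def as_partition(labels):
    """Canonical form of a flat clustering for label-free comparison."""
    labels = np.asarray(labels)
    return frozenset(
        frozenset(np.nonzero(labels == lab)[0].tolist()) for lab in np.unique(labels)
    )
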