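"""Independent brute-force oracles, written as plain loops over the weight
update and distance definitions. They share no code with the package."""

import numpy as np


def brute_force_relieff(X, y, k, targets):
    """Direct per-target, per-feature evaluation of the Relieff update."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    frange = X.max(axis=0) - X.min(axis=0)

    def d(f, i, j):
        if frange[f] <= 0:
            return 0.0
        return abs(X[i, f] - X[j, f]) / frange[f]

    def dist(i, j):
        return sum(d(f, i, j) for f in range(p))

    classes = sorted(set(y.tolist()))
    prior = {c: float(np.sum(y == c)) / n for c in classes}
    m = len(targets)
    W = np.zeros(p)
    for t in targets:
        for c in classes:
            pool = [i for i in range(n) if y[i] == c and i != t]
            pool.sort(key=lambda i: (dist(t, i), i))
            nearest = pool[:k]
            for f in range(p):
                s = sum(d(f, t, j) for j in nearest)
                if c == y[t]:
                    W[f] -= s / (m * k)
                else:
                    W[f] += prior[c] / (1.0 - prior[y[t]]) * s / (m * k)
    return W


def brute_force_neighbors(target, pool, k):
    """Exhaustive sort by range-normalized Manhattan distance, ties by index."""
    target = np.asarray(target, dtype=float)
    pool = np.asarray(pool, dtype=float)
    stacked = np.vstack([target[None, :], pool])
    frange = stacked.max(axis=0) - stacked.min(axis=0)
    safe = np.where(frange > 0, frange, np.inf)
    dists = [
        (float(np.sum(np.abs(pool[i] - target) / safe)), i)
        for i in range(pool.shape[0])
    ]
    dists.sort()
    return np.array([i for _, i in dists[:k]])


def brute_force_center_order(X, y, cls):
    """Order class members by Manhattan distance (on range-scaled values) to
    the per-feature class mean."""
    X = np.asarray(X, dtype=float)
    frange = X.max(axis=0) - X.min(axis=0)
    safe = np.where(frange > 0, frange, 1.0)
    Xs = X / safe
    Xs[:, frange <= 0] = 0.0
    members = [i for i in range(X.shape[0]) if y[i] == cls]
    center = Xs[members].mean(axis=0)
    members.sort(key=lambda i: (float(np.sum(np.abs(Xs[i] - center))), i))
    return np.array(members)
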