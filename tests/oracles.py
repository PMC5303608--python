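"""Independent oracles used by the test suite.

Each oracle re-derives a quantity by a different route than the package:
explicit Gaussian elimination for the normal equations, an exhaustive
ordered-triple scan for shortcut enumeration, all-pairs comparison for the
Mann-Whitney AUROC, an eigendecomposition of the scaled cross-product for
the Belsley variance decomposition, Kahn's algorithm for acyclicity, and
union-find for weak connectivity.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import t as t_dist


def gaussian_solve(A, b):
    """Solve A x = b by explicit Gaussian elimination with partial pivoting."""
    A = [list(map(float, row)) for row in np.asarray(A)]
    b = list(map(float, np.asarray(b).ravel()))
    m = len(A)
    for col in range(m):
        pivot = max(range(col, m), key=lambda r: abs(A[r][col]))
        if abs(A[pivot][col]) == 0.0:
            raise ZeroDivisionError("singular system")
        A[col], A[pivot] = A[pivot], A[col]
        b[col], b[pivot] = b[pivot], b[col]
        for r in range(col + 1, m):
            f = A[r][col] / A[col][col]
            for c in range(col, m):
                A[r][c] -= f * A[col][c]
            b[r] -= f * b[col]
    x = [0.0] * m
    for r in range(m - 1, -1, -1):
        s = b[r] - sum(A[r][c] * x[c] for c in range(r + 1, m))
        x[r] = s / A[r][r]
    return np.array(x)


def ols_normal_equations(y, X):
    """Full OLS oracle from the normal equations (X'X) beta = X'y.

    Returns (params, standard_errors, t_stats, p_values, residual_df) for the
    intercept-augmented design, all computed without statsmodels.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xc = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    n, p = Xc.shape
    XtX = Xc.T @ Xc
    params = gaussian_solve(XtX, Xc.T @ y)
    resid = y - Xc @ params
    df = n - p
    sigma2 = float(resid @ resid) / df
    # diag of (X'X)^-1 column by column, again via elimination
    inv_diag = np.array(
        [gaussian_solve(XtX, np.eye(p)[:, j])[j] for j in range(p)]
    )
    se = np.sqrt(sigma2 * inv_diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = np.where(se > 0, params / se, 0.0)
    p_values = 2.0 * t_dist.sf(np.abs(t_stats), df)
    return params, se, t_stats, p_values, df


def shortcuts_by_triple_scan(nodes, edges):
    """All (A, C) with a witness B, by exhaustive scan over ordered triples."""
    edges = set(edges)
    nodes = sorted(nodes)
    found = {}
    for a in nodes:
        for b in nodes:
            for c in nodes:
                if a == b or b == c or a == c:
                    continue
                if (a, b) in edges and (b, c) in edges:
                    found.setdefault((a, c), set()).add(b)
    return found


def auroc_all_pairs(scores, labels):
    """AUROC by explicit comparison of every positive-negative pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def belsley_by_eigensystem(X):
    """Condition indices and VDPs from the eigendecomposition of (Xs' Xs).

    Eigenvalues of the scaled cross-product equal squared singular values;
    eigenvectors give the variance decomposition directly.
    """
    X = np.asarray(X, dtype=float)
    Xs = X / np.linalg.norm(X, axis=0)
    evals, evecs = np.linalg.eigh(Xs.T @ Xs)
    order = np.argsort(evals)[::-1]  # descending, matching singular-value order
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    d = np.sqrt(evals)
    ci = d[0] / d
    phi = (evecs ** 2) / evals  # (variable j, component k)
    vdp = (phi / phi.sum(axis=1, keepdims=True)).T  # (component, variable)
    return ci, vdp


def kahn_is_acyclic(nodes, edges):
    """Kahn's algorithm: repeatedly strip in-degree-0 nodes."""
    indeg = {v: 0 for v in nodes}
    succ = {v: [] for v in nodes}
    for a, b in edges:
        indeg[b] += 1
        succ[a].append(b)
    queue = [v for v in nodes if indeg[v] == 0]
    seen = 0
    while queue:
        v = queue.pop()
        seen += 1
        for w in succ[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return seen == len(list(nodes))


def is_weakly_connected(nodes, edges):
    """Union-find weak connectivity check."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    roots = {find(v) for v in nodes}
    return len(roots) <= 1


def random_directed_network(rng, max_nodes=60):
    """A random directed self-loop-free edge set for oracle comparisons."""
    n = int(rng.integers(4, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    density = float(rng.uniform(0.02, 0.25))
    edges = {
        (names[i], names[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < density
    }
    return names, edges
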