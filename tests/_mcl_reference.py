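"""Minimal independent Markov-clustering reference used as a test oracle.

Written directly from the algorithm's published description — alternate
matrix expansion with entrywise inflation on a column-stochastic matrix
until idempotence, then read clusters as the attractor basins — with no
pruning and none of the package implementation's machinery, so it can serve
as an independent cross-check on small graphs.
"""

import numpy as np


def reference_mcl(adjacency: np.ndarray, inflation: float, expansion: int = 2,
                  self_loops: str = "max", max_iter: int = 500,
                  tol: float = 1e-10) -> list[frozenset[int]]:
    a = np.array(adjacency, dtype=float)
    n = a.shape[0]
    if self_loops == "max":
        diag = a.max(axis=0)
        diag[diag == 0] = 1.0
    else:
        diag = np.full(n, float(self_loops))
    np.fill_diagonal(a, diag)
    m = a / a.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m = m / m.sum(axis=0, keepdims=True)
        if np.abs(m - prev).max() < tol:
            break
    # attractor basins: node j joins the attractor row holding most of its
    # column mass; attractors sharing any basin member are merged
    attractors = [i for i in range(n) if m[i, i] > 1e-8]
    parent = {i: i for i in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    assign = {}
    for j in range(n):
        rows = [i for i in attractors if m[i, j] > 1e-8]
        for i in rows[1:]:
            ra, rb = find(rows[0]), find(i)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    for j in range(n):
        masses = {}
        for i in attractors:
            if m[i, j] > 1e-8:
                r = find(i)
                masses[r] = masses.get(r, 0.0) + m[i, j]
        if masses:
            assign[j] = max(masses, key=lambda r: (masses[r], -r))
        else:
            assign[j] = -1 - j  # unattracted: its own singleton
    clusters: dict[int, set[int]] = {}
    for j, r in assign.items():
        clusters.setdefault(r, set()).add(j)
    return [frozenset(c) for c in clusters.values()]
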