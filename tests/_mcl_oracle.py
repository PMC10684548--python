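"""Independent naive Markov-clustering oracle for tests.

Dense full-graph implementation with no pruning and no per-component
decomposition; written straight from the algorithm definition so it shares
no code path with the package implementation.
"""

import numpy as np


def mcl_oracle(nodes, weighted_edges, inflation=2.0, expansion=2, max_iter=100,
               tol=1e-8):
    """Return the partition as a set of frozensets of node names."""
    nodes = sorted(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for (a, b), w in weighted_edges.items():
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    for i in range(n):
        mx = m[i].max()
        m[i, i] = mx if mx > 0 else 1.0
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        m = m / m.sum(axis=0, keepdims=True)
        if np.abs(m - prev).max() < tol:
            break
    attractors = [i for i in range(n) if m[i, i] > 1e-12]
    clusters = {i: set() for i in attractors}
    orphans = []
    for j in range(n):
        col = m[attractors, :][:, j]
        best = int(np.argmax(col))
        if col[best] > 0:
            clusters[attractors[best]].add(nodes[j])
        else:
            orphans.append({nodes[j]})
    groups = [c for c in clusters.values() if c] + orphans
    return {frozenset(g) for g in groups}


def random_weighted_graph(rng, max_nodes=40):
    """Random sparse weighted graph for oracle comparisons."""
    n = int(rng.integers(5, max_nodes + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = {}
    p_edge = float(rng.uniform(0.05, 0.25))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges[(nodes[i], nodes[j])] = float(rng.uniform(0.1, 1.0))
    return nodes, edges
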