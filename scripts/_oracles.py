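"""Self-contained independent oracles used by the acceptance script.

Each is a naive straight-line recomputation of the quantity it checks:
exact hypergeometric enumeration for Fisher, a dense unpruned MCL, and a
per-residue brute force for pair aggregation.  None shares a code path with
the package implementation.
"""

from __future__ import annotations

from math import comb

import numpy as np

from phagemosaic.io import AlignmentHit


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    r1, r2, c1 = a + b, c + d, a + c
    hi = min(r1, c1)
    denom = comb(r1 + r2, c1)
    return sum(comb(r1, k) * comb(r2, c1 - k) for k in range(a, hi + 1)) / denom


def mcl_oracle(nodes, weighted_edges, inflation=2.0, expansion=2, max_iter=100,
               tol=1e-8):
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
    return {frozenset(g) for g in list(clusters.values()) + orphans if g}


def random_weighted_graph(rng, max_nodes=40):
    n = int(rng.integers(5, max_nodes + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = {}
    p_edge = float(rng.uniform(0.05, 0.25))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges[(nodes[i], nodes[j])] = float(rng.uniform(0.1, 1.0))
    return nodes, edges


def random_pair_instance(rng):
    len_a = int(rng.integers(80, 401))
    len_b = int(rng.integers(80, 401))
    n_ab = int(rng.integers(0, 5))
    n_ba = int(rng.integers(0, 5))
    if n_ab == 0 and n_ba == 0:
        n_ab = 1

    def rand_hits(n, qlen, slen, q, s):
        out = []
        for _ in range(n):
            qs = int(rng.integers(1, qlen))
            qe = int(rng.integers(qs, qlen + 1))
            ss = int(rng.integers(1, slen))
            se = int(rng.integers(ss, slen + 1))
            out.append(
                AlignmentHit(
                    query_id=q, subject_id=s,
                    probability=float(rng.uniform(0.5, 1.0)),
                    percent_identity=float(rng.uniform(0.0, 1.0)),
                    q_start=qs, q_end=qe, s_start=ss, s_end=se,
                    q_len=qlen, s_len=slen, search_tag="self",
                )
            )
        return out

    return (
        rand_hits(n_ab, len_a, len_b, "A", "B"),
        rand_hits(n_ba, len_b, len_a, "B", "A"),
        len_a,
        len_b,
    )


def brute_force_pair(dir_ab, dir_ba, len_a, len_b):
    def dir_stats(hits):
        arr = {}
        for h in hits:
            for i in range(h.q_start, h.q_end + 1):
                arr[i] = max(arr.get(i, 0.0), h.probability)
        prob = sum(arr.values()) / len(arr)
        wsum = sum((h.q_end - h.q_start + 1) * h.percent_identity for h in hits)
        lsum = sum(h.q_end - h.q_start + 1 for h in hits)
        return prob, wsum / lsum

    probs, idents = [], []
    for hits in (dir_ab, dir_ba):
        if hits:
            pr, pid = dir_stats(hits)
            probs.append(pr)
            idents.append(pid)

    res_a, res_b = set(), set()
    for h in dir_ab:
        res_a.update(range(h.q_start, h.q_end + 1))
        res_b.update(range(h.s_start, h.s_end + 1))
    for h in dir_ba:
        res_b.update(range(h.q_start, h.q_end + 1))
        res_a.update(range(h.s_start, h.s_end + 1))
    return (
        min(probs), min(idents),
        len(res_a) / len_a, len(res_b) / len_b,
        len(res_a), len(res_b),
    )
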