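"""Protein families by Markov clustering of the rHMM similarity network.

Edges connect rHMM pairs with probability >= 0.95 and pairwise coverage
min(qcov, scov) >= 0.8, weighted by p x cov.  Markov clustering (MCL)
alternates expansion (matrix squaring) and inflation (entrywise power with
column renormalisation) on the column-stochastic transition matrix until
convergence; clusters are read off the attractor rows.  Connected components
are clustered independently — MCL can split but never merge them — which
also keeps the dense per-component matrices small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .pairs import PairComparison

__all__ = [
    "FamilyPartition",
    "build_family_graph",
    "mcl",
    "family_mosaic_status",
]


@dataclass
class FamilyPartition:
    """A partition of rHMM ids into families.

    Family ids are consecutive integers assigned in order of each family's
    lexicographically smallest member, so the labelling is deterministic
    and independent of input node order.
    """

    families: dict[int, frozenset[str]]
    member_to_family: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.member_to_family:
            self.member_to_family = {
                m: fid for fid, members in self.families.items() for m in members
            }
        n_members = sum(len(m) for m in self.families.values())
        if n_members != len(self.member_to_family):
            raise ValueError("families overlap: not a partition")

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[str]]) -> "FamilyPartition":
        canon = sorted((frozenset(g) for g in groups), key=lambda s: min(s))
        return cls(families={i: g for i, g in enumerate(canon)})

    @property
    def n_families(self) -> int:
        return len(self.families)

    def labels(self, order: Sequence[str]) -> list[int]:
        """Family labels for the given member order (e.g. for ARI)."""
        return [self.member_to_family[m] for m in order]


def build_family_graph(
    pairs: Iterable[PairComparison],
    nodes: Optional[Iterable[str]] = None,
    min_p: float = 0.95,
    min_cov: float = 0.8,
) -> nx.Graph:
    """Weighted, undirected rHMM similarity graph for family clustering.

    An edge exists iff p >= ``min_p`` and cov_min >= ``min_cov``; its weight
    is p x cov_min.  ``nodes`` may add edgeless rHMMs so that singletons end
    up as their own families.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for pc in pairs:
        if pc.id_a == pc.id_b:
            continue
        if pc.p >= min_p and pc.cov_min >= min_cov:
            g.add_edge(pc.id_a, pc.id_b, weight=pc.p * pc.cov_min)
    return g


def _mcl_component(
    sub: nx.Graph,
    order: list[str],
    inflation: float,
    expansion: int,
    max_iter: int,
    prune_eps: float,
    tol: float,
) -> list[set[str]]:
    n = len(order)
    idx = {node: i for i, node in enumerate(order)}
    m = np.zeros((n, n), dtype=float)
    for a, b, data in sub.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    # self-loops: each node loops with its maximum incident weight
    for i in range(n):
        inc = m[i].max()
        m[i, i] = inc if inc > 0 else 1.0
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        if prune_eps > 0:
            m[m < prune_eps] = 0.0
        colsums = m.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        m /= colsums
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {max_iter} iterations on a "
            f"{n}-node component; clustering current state",
            RuntimeWarning,
            stacklevel=3,
        )

    # attractors are rows with non-negligible diagonal mass
    attractors = [i for i in range(n) if m[i, i] > max(prune_eps, 1e-12)]
    if not attractors:
        return [set(order)]
    clusters: dict[int, set[str]] = {i: set() for i in attractors}
    orphans: list[set[str]] = []
    attr_rows = m[attractors, :]
    for j in range(n):
        col = attr_rows[:, j]
        best = int(np.argmax(col))  # ties: first index = lowest attractor id
        if col[best] > 0:
            clusters[attractors[best]].add(order[j])
        else:  # numerically unreachable node: its own family
            orphans.append({order[j]})
    return [c for c in clusters.values() if c] + orphans


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    prune_eps: float = 1e-6,
    tol: float = 1e-8,
) -> FamilyPartition:
    """Markov clustering of a weighted similarity graph.

    Each connected component is clustered with dense arithmetic; entries
    below ``prune_eps`` are zeroed after every inflation for tractability.
    Every node — including isolated ones — ends up in exactly one family.
    Nodes covered by several attractors are assigned to the attractor
    holding the most mass for them, ties going to the lowest-indexed
    attractor in sorted node order.
    """
    groups: list[set[str]] = []
    for comp in nx.connected_components(graph):
        order = sorted(comp)
        if len(order) == 1:
            groups.append(set(order))
            continue
        sub = graph.subgraph(comp)
        groups.extend(
            _mcl_component(sub, order, inflation, expansion, max_iter, prune_eps, tol)
        )
    return FamilyPartition.from_groups(groups)


def family_mosaic_status(
    partition: FamilyPartition, signals: Mapping[str, set[str]]
) -> dict[int, set[str]]:
    """Per-family mosaic flags: a family carries a basis if any member does."""
    for rid in signals:
        if rid not in partition.member_to_family:
            raise KeyError(f"mosaic signal on {rid!r}, which is absent from the partition")
    flags: dict[int, set[str]] = {fid: set() for fid in partition.families}
    for rid, bases in signals.items():
        flags[partition.member_to_family[rid]] |= set(bases)
    return flags
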