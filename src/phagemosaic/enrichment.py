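"""Enrichment statistics and the mosaic functional-class networks.

Two enrichment designs are computed, both with one-tailed Fisher exact tests
("greater", i.e. over-representation) and Bonferroni correction:

* per-domain: units are unique domain architectures; for each T-group the
  2x2 table counts mosaic/non-mosaic architectures with/without the group,
  and the odds ratio is OR = (m_t / m_nt) / (n_t / n_nt);
* per-class: units are rHMM families; for each functional class the table
  counts mosaic/non-mosaic families containing/not containing the class
  (restricted to families holding at least one eligible-class rHMM).

The class networks summarise mosaic calls: nodes are functional classes,
edges link classes whose architectures share mosaic evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
from scipy import stats

from .annotation import DomainArchitecture, FunctionalAnnotation, STATUS_ASSIGNED
from .families import FamilyPartition
from .io import GENERIC_CLASSES
from .mosaicism import BASIS_ECOD, MosaicCall, Tier

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "odds_ratio",
    "fisher_one_tailed",
    "domain_enrichment",
    "class_family_enrichment",
    "mosaic_network",
    "recent_network",
    "write_enrichment_table",
    "write_edge_list",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table laid out as (a, b, c, d) = (with-feature among cases,
    without-feature among cases, with-feature among controls,
    without-feature among controls)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def odds_ratio(t: ContingencyTable) -> float:
    """OR = (a/b) / (c/d), without continuity correction.

    Zero cells follow the natural limits: a == 0 gives 0, a > 0 with c == 0
    (or b == 0) gives +infinity; a zero-margin table where both ratios
    degenerate gives NaN.
    """
    if t.a == 0:
        return math.nan if t.c == 0 else 0.0
    if t.c == 0 or t.b == 0:
        return math.inf
    if t.d == 0:
        return 0.0
    return (t.a / t.b) / (t.c / t.d)


def fisher_one_tailed(t: ContingencyTable) -> float:
    """One-tailed (over-representation) Fisher exact p for the table."""
    _, p = stats.fisher_exact(t.as_array(), alternative="greater")
    return float(p)


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    table: ContingencyTable
    odds_ratio: float
    p_raw: float
    p_bonferroni: float
    n_tests: int

    def __post_init__(self) -> None:
        expected = min(1.0, self.p_raw * self.n_tests)
        if abs(self.p_bonferroni - expected) > 1e-12:
            raise ValueError("p_bonferroni inconsistent with p_raw and n_tests")

    @property
    def significant(self) -> bool:
        return self.p_bonferroni < 0.05


def _finish(results: list[tuple[str, ContingencyTable]]) -> list[EnrichmentResult]:
    n = len(results)
    out = []
    for feature, table in results:
        p = fisher_one_tailed(table)
        out.append(
            EnrichmentResult(
                feature=feature,
                table=table,
                odds_ratio=odds_ratio(table),
                p_raw=p,
                p_bonferroni=min(1.0, p * n),
                n_tests=n,
            )
        )
    return out


def _group_of(t_id: str, level: str) -> str:
    parts = t_id.split(".")
    if level == "T":
        return t_id
    if level == "H":
        return ".".join(parts[:2])
    if level == "X":
        return parts[0]
    raise ValueError(f"unknown level {level!r}")


def domain_enrichment(
    architectures: Iterable[DomainArchitecture],
    mosaic_architecture_keys: set[str],
    level: str = "T",
) -> list[EnrichmentResult]:
    """Per-domain over-representation in mosaic domain architectures.

    Units are unique architectures (deduplicated by T-group set); an
    architecture counts as mosaic when its key is in
    ``mosaic_architecture_keys`` — typically the keys borne by any rHMM
    involved in an ECOD-basis call (optionally restricted to contemporary
    calls).  One test per domain group occurring in >= 1 architecture;
    Bonferroni multiplicity is the number of groups tested.
    """
    uniq: dict[str, frozenset[str]] = {}
    for arch in architectures:
        if arch.t_groups:
            uniq[arch.architecture_key] = arch.t_groups
    domains = sorted(
        {_group_of(t, level) for t_groups in uniq.values() for t in t_groups}
    )
    n_mosaic = sum(1 for key in uniq if key in mosaic_architecture_keys)
    n_total = len(uniq)
    tables = []
    for dom in domains:
        m_t = sum(
            1
            for key, t_groups in uniq.items()
            if key in mosaic_architecture_keys
            and any(_group_of(t, level) == dom for t in t_groups)
        )
        n_t = sum(
            1
            for key, t_groups in uniq.items()
            if key not in mosaic_architecture_keys
            and any(_group_of(t, level) == dom for t in t_groups)
        )
        m_nt = n_mosaic - m_t
        n_nt = (n_total - n_mosaic) - n_t
        tables.append((dom, ContingencyTable(m_t, m_nt, n_t, n_nt)))
    return _finish(tables)


def class_family_enrichment(
    family_flags: Mapping[int, set[str]],
    partition: FamilyPartition,
    annotations: Mapping[str, FunctionalAnnotation],
    eligible: set[str],
    bases: frozenset[str] = frozenset({BASIS_ECOD}),
) -> list[EnrichmentResult]:
    """Per-class over-representation in mosaic rHMM families.

    A family is mosaic when its flag set intersects ``bases`` (pass the
    ECOD basis alone, or both bases, for the two published designs).  The
    family universe is restricted to families containing at least one rHMM
    of an eligible class, so each table's margin counts families assigned
    to this class vs families assigned to any of the remaining classes.
    """
    fam_classes: dict[int, set[str]] = {}
    for fid, members in partition.families.items():
        classes = set()
        for rid in members:
            ann = annotations.get(rid)
            if ann is not None and ann.status == STATUS_ASSIGNED:
                if ann.simplified_class in eligible:
                    classes.add(ann.simplified_class)
        if classes:
            fam_classes[fid] = classes

    tables = []
    for cls in sorted(eligible):
        a = b = c = d = 0
        for fid, classes in fam_classes.items():
            is_mosaic = bool(set(family_flags.get(fid, ())) & bases)
            has_cls = cls in classes
            if is_mosaic and has_cls:
                a += 1
            elif is_mosaic:
                b += 1
            elif has_cls:
                c += 1
            else:
                d += 1
        tables.append((cls, ContingencyTable(a, b, c, d)))
    return _finish(tables)


def _class_of(
    rid: str, annotations: Mapping[str, FunctionalAnnotation]
) -> Optional[str]:
    ann = annotations.get(rid)
    if ann is None or ann.status != STATUS_ASSIGNED:
        return None
    return ann.simplified_class


def mosaic_network(
    calls: Iterable[MosaicCall],
    architectures: Mapping[str, DomainArchitecture],
    annotations: Mapping[str, FunctionalAnnotation],
    min_arch_pairs: int = 4,
    generic_classes: frozenset[str] = GENERIC_CLASSES,
) -> nx.Graph:
    """Mosaic network of functional classes from ECOD-basis calls.

    Classes are linked (self-loops allowed: within-class mosaicism) when
    mosaic evidence connects at least ``min_arch_pairs`` distinct unordered
    pairs of domain architectures between them.  An edge is flagged
    contemporary when at least one supporting rHMM pair has fragment
    identity >= 50%.  Node size is the class's distinct-architecture count.
    Generic classes and unannotated rHMMs are excluded.
    """
    arch_pairs: dict[tuple[str, str], set[tuple[str, str]]] = {}
    contemporary: dict[tuple[str, str], bool] = {}
    for call in calls:
        if call.basis != BASIS_ECOD:
            continue
        ca, cb = _class_of(call.id_a, annotations), _class_of(call.id_b, annotations)
        if ca is None or cb is None or ca in generic_classes or cb in generic_classes:
            continue
        key_a = architectures[call.id_a].architecture_key
        key_b = architectures[call.id_b].architecture_key
        cls_key = tuple(sorted((ca, cb)))
        arch_key = tuple(sorted((key_a, key_b)))
        arch_pairs.setdefault(cls_key, set()).add(arch_key)
        if call.tier >= Tier.CONTEMPORARY:
            contemporary[cls_key] = True

    class_arch: dict[str, set[str]] = {}
    for rid, arch in architectures.items():
        cls = _class_of(rid, annotations)
        if cls is None or cls in generic_classes or not arch.t_groups:
            continue
        class_arch.setdefault(cls, set()).add(arch.architecture_key)

    g = nx.Graph()
    for cls, keys in class_arch.items():
        g.add_node(cls, n_architectures=len(keys))
    for (ca, cb), pairs_set in arch_pairs.items():
        if len(pairs_set) >= min_arch_pairs:
            for cls in (ca, cb):
                if cls not in g:
                    g.add_node(cls, n_architectures=len(class_arch.get(cls, ())))
            g.add_edge(
                ca, cb,
                n_arch_pairs=len(pairs_set),
                contemporary=contemporary.get((ca, cb), False),
            )
    return g


def recent_network(
    calls: Iterable[MosaicCall],
    annotations: Mapping[str, FunctionalAnnotation],
    min_tier: Tier = Tier.RECENT_HIGH,
    generic_classes: frozenset[str] = GENERIC_CLASSES,
) -> nx.Graph:
    """Network of classes linked by recently emerged sequence mosaicism.

    Edges come from individual sequence-basis rHMM pairs at or above
    ``min_tier``; rHMMs without an assigned class map to the node
    ``"unknown"``.  Edge attribute ``n_pairs`` counts the supporting pairs.
    """
    g = nx.Graph()
    for call in calls:
        if call.basis != "sequence" or call.tier < min_tier:
            continue
        ca = _class_of(call.id_a, annotations) or "unknown"
        cb = _class_of(call.id_b, annotations) or "unknown"
        if ca in generic_classes or cb in generic_classes:
            continue
        key = tuple(sorted((ca, cb)))
        if g.has_edge(*key):
            g.edges[key]["n_pairs"] += 1
        else:
            g.add_edge(*key, n_pairs=1)
    return g


def write_enrichment_table(
    results: Sequence[EnrichmentResult], stream: Union[str, Path, IO[str]]
) -> None:
    if isinstance(stream, (str, Path)):
        handle: IO[str] = open(stream, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = stream, False
    try:
        handle.write("feature\ta\tb\tc\td\todds_ratio\tp_raw\tp_bonferroni\n")
        for r in results:
            t = r.table
            handle.write(
                f"{r.feature}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                f"{r.odds_ratio!r}\t{r.p_raw!r}\t{r.p_bonferroni!r}\n"
            )
    finally:
        if close:
            handle.close()


def write_edge_list(graph: nx.Graph, stream: Union[str, Path, IO[str]]) -> None:
    if isinstance(stream, (str, Path)):
        handle: IO[str] = open(stream, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = stream, False
    try:
        attrs = sorted({k for _, _, d in graph.edges(data=True) for k in d})
        handle.write("\t".join(["class_a", "class_b", *attrs]) + "\n")
        for a, b, d in sorted(graph.edges(data=True)):
            handle.write(
                "\t".join([a, b, *[str(d.get(k, "")) for k in attrs]]) + "\n"
            )
    finally:
        if close:
            handle.close()
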