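"""End-to-end wiring: from raw hit tables to mosaic calls and families.

This is glue over the per-stage modules, in the order the analysis runs:
pair aggregation (permissive and strict contexts), functional annotation,
domain architectures, both mosaic detectors, Markov-clustered families and
per-family mosaic flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .annotation import (
    DomainArchitecture,
    FunctionalAnnotation,
    architecture,
    assign_domains,
    assign_function,
)
from .families import FamilyPartition, build_family_graph, family_mosaic_status, mcl
from .io import AlignmentHit, EcodId, FunctionMap
from .mosaicism import MosaicCall, detect_ecod_calls, detect_sequence_calls, mosaic_signals
from .pairs import PERMISSIVE_P50, STRICT_P95, PairComparison, aggregate_pair

__all__ = ["PipelineResult", "aggregate_all_pairs", "run_pipeline"]


@dataclass
class PipelineResult:
    permissive_pairs: list[PairComparison]
    strict_pairs: list[PairComparison]
    annotations: dict[str, FunctionalAnnotation]
    architectures: dict[str, DomainArchitecture]
    ecod_calls: list[MosaicCall]
    sequence_calls: list[MosaicCall]
    family_graph: nx.Graph
    partition: FamilyPartition
    signals: dict[str, set[str]] = field(default_factory=dict)
    family_flags: dict[int, set[str]] = field(default_factory=dict)

    @property
    def calls(self) -> list[MosaicCall]:
        return self.ecod_calls + self.sequence_calls


def _group_directions(
    hits: Iterable[AlignmentHit],
) -> dict[tuple[str, str], tuple[list[AlignmentHit], list[AlignmentHit]]]:
    """Group hits by unordered pair into (low->high, high->low) directions."""
    grouped: dict[tuple[str, str], tuple[list[AlignmentHit], list[AlignmentHit]]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        fwd, rev = grouped.setdefault(key, ([], []))
        (fwd if h.query_id == key[0] else rev).append(h)
    return grouped


def aggregate_all_pairs(
    hits: Sequence[AlignmentHit],
    min_hit_p: float = 0.5,
    threshold_context: str = PERMISSIVE_P50,
) -> list[PairComparison]:
    """Aggregate a directional self-search hit table into pair comparisons,
    keeping only hits at or above ``min_hit_p`` before aggregation."""
    kept = [h for h in hits if h.probability >= min_hit_p]
    grouped = _group_directions(kept)
    return [
        aggregate_pair(*grouped[key], threshold_context=threshold_context)
        for key in sorted(grouped)
    ]


def run_pipeline(
    self_hits: Sequence[AlignmentHit],
    ecod_hits: Sequence[AlignmentHit],
    phrog_hits: Sequence[AlignmentHit],
    antidefence_hits: Sequence[AlignmentHit],
    ecod_map: Mapping[str, EcodId],
    function_map: FunctionMap,
    rhmm_ids: Optional[Iterable[str]] = None,
    mcl_inflation: float = 2.0,
) -> PipelineResult:
    """Run the whole analysis on one input bundle.

    ``rhmm_ids`` fixes the rHMM universe (needed so edgeless rHMMs become
    singleton families); by default it is the union of query ids seen in
    the self, ECOD and PHROG tables.
    """
    if rhmm_ids is None:
        ids = {h.query_id for h in self_hits} | {h.subject_id for h in self_hits}
        ids |= {h.query_id for h in ecod_hits} | {h.query_id for h in phrog_hits}
        rhmm_ids = sorted(ids)
    else:
        rhmm_ids = sorted(set(rhmm_ids))

    grouped = _group_directions(self_hits)
    permissive: list[PairComparison] = []
    strict: list[PairComparison] = []
    for key in sorted(grouped):
        fwd, rev = grouped[key]
        permissive.append(aggregate_pair(fwd, rev, threshold_context=PERMISSIVE_P50))
        fwd95 = [h for h in fwd if h.probability >= 0.95]
        rev95 = [h for h in rev if h.probability >= 0.95]
        if fwd95 or rev95:
            strict.append(aggregate_pair(fwd95, rev95, threshold_context=STRICT_P95))

    # annotation: aggregate PHROG/antidefence hits per (rHMM, target profile)
    def per_target(hits: Sequence[AlignmentHit], rid: str) -> list[PairComparison]:
        by_target: dict[str, list[AlignmentHit]] = {}
        for h in hits:
            if h.query_id == rid:
                by_target.setdefault(h.subject_id, []).append(h)
        return [aggregate_pair(hs, []) for _, hs in sorted(by_target.items())]

    phrog_by_rhmm: dict[str, list[AlignmentHit]] = {}
    for h in phrog_hits:
        phrog_by_rhmm.setdefault(h.query_id, []).append(h)
    anti_by_rhmm: dict[str, list[AlignmentHit]] = {}
    for h in antidefence_hits:
        anti_by_rhmm.setdefault(h.query_id, []).append(h)

    annotations: dict[str, FunctionalAnnotation] = {}
    for rid in rhmm_ids:
        annotations[rid] = assign_function(
            rid,
            per_target(phrog_by_rhmm.get(rid, []), rid),
            per_target(anti_by_rhmm.get(rid, []), rid),
            function_map,
        )

    ecod_by_rhmm: dict[str, list[AlignmentHit]] = {}
    for h in ecod_hits:
        ecod_by_rhmm.setdefault(h.query_id, []).append(h)
    architectures: dict[str, DomainArchitecture] = {}
    for rid in rhmm_ids:
        hits = assign_domains(ecod_by_rhmm.get(rid, []), ecod_map)
        architectures[rid] = architecture(rid, hits)

    pair_p_ids = {pc.pair: pc.p_id for pc in strict}
    ecod_calls = detect_ecod_calls(architectures, pair_p_ids)
    sequence_calls = detect_sequence_calls(permissive, strict)

    graph = build_family_graph(strict, nodes=rhmm_ids)
    partition = mcl(graph, inflation=mcl_inflation)

    signals = mosaic_signals(ecod_calls + sequence_calls)
    flags = family_mosaic_status(
        partition, {r: s for r, s in signals.items() if r in partition.member_to_family}
    )
    return PipelineResult(
        permissive_pairs=permissive,
        strict_pairs=strict,
        annotations=annotations,
        architectures=architectures,
        ecod_calls=ecod_calls,
        sequence_calls=sequence_calls,
        family_graph=graph,
        partition=partition,
        signals=signals,
        family_flags=flags,
    )
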