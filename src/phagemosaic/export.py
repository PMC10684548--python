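"""Flat-file exports for every pipeline product.

One writer per table, all UTF-8 TSV with a header row.  These are thin and
schema-stable; anything richer (GraphML, plots) goes through networkx or
:mod:`phagemosaic.viz` directly.
"""

from __future__ import annotations

from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Union

import networkx as nx

from .annotation import DomainArchitecture, FunctionalAnnotation
from .ecology import GroupAssignment
from .families import FamilyPartition
from .mosaicism import MosaicCall

Stream = Union[str, Path, IO[str]]


def _writer(stream: Stream):
    if isinstance(stream, (str, Path)):
        return open(stream, "w", encoding="utf-8", newline=""), True
    return stream, False


def write_annotations(
    annotations: Iterable[FunctionalAnnotation], stream: Stream
) -> None:
    handle, close = _writer(stream)
    try:
        handle.write("rhmm_id\tstatus\tsimplified_class\tcategory\tantidefence_class\n")
        for a in annotations:
            handle.write(
                "\t".join([
                    a.rhmm_id, a.status, a.simplified_class or "",
                    a.category or "", a.antidefence_class or "",
                ]) + "\n"
            )
    finally:
        if close:
            handle.close()


def write_architectures(
    architectures: Iterable[DomainArchitecture], stream: Stream
) -> None:
    """One row per rHMM: its architecture key plus the display layout."""
    handle, close = _writer(stream)
    try:
        handle.write("rhmm_id\tarchitecture_key\tlayout\n")
        for arch in architectures:
            layout = ";".join(
                f"{d.ecod.t_id}:{d.q_start}-{d.q_end}" for d in arch.layout
            )
            handle.write(f"{arch.rhmm_id}\t{arch.architecture_key}\t{layout}\n")
    finally:
        if close:
            handle.close()


def write_families(partition: FamilyPartition, stream: Stream) -> None:
    handle, close = _writer(stream)
    try:
        handle.write("rhmm_id\tfamily_id\n")
        for rid in sorted(partition.member_to_family):
            handle.write(f"{rid}\t{partition.member_to_family[rid]}\n")
    finally:
        if close:
            handle.close()


def write_mosaic_calls(calls: Iterable[MosaicCall], stream: Stream) -> None:
    handle, close = _writer(stream)
    try:
        handle.write(
            "id_a\tid_b\tbasis\ttier\tshared_t_groups\t"
            "fragment_p\tfragment_p_id\tfragment_len_a\tfragment_len_b\n"
        )
        for c in calls:
            handle.write(
                "\t".join([
                    c.id_a, c.id_b, c.basis, c.tier.name,
                    "|".join(sorted(c.shared_t_groups)),
                    "" if c.fragment_p is None else repr(c.fragment_p),
                    "" if c.fragment_p_id is None else repr(c.fragment_p_id),
                    "" if c.fragment_len_a is None else str(c.fragment_len_a),
                    "" if c.fragment_len_b is None else str(c.fragment_len_b),
                ]) + "\n"
            )
    finally:
        if close:
            handle.close()


def write_group_assignments(
    assignments: Iterable[GroupAssignment], stream: Stream
) -> None:
    handle, close = _writer(stream)
    try:
        handle.write("rhmm_id\taxis\tvalue\n")
        for g in assignments:
            handle.write(f"{g.rhmm_id}\t{g.axis}\t{g.value}\n")
    finally:
        if close:
            handle.close()


def write_genome_fractions(
    fractions: Mapping[str, Optional[float]], stream: Stream
) -> None:
    """Undefined fractions (genomes without rHMM-mapped proteins) stay blank."""
    handle, close = _writer(stream)
    try:
        handle.write("genome_id\tmosaic_fraction\n")
        for genome in sorted(fractions):
            f = fractions[genome]
            handle.write(f"{genome}\t{'' if f is None else repr(f)}\n")
    finally:
        if close:
            handle.close()


def write_graphml(graph: nx.Graph, path: Union[str, Path]) -> None:
    """GraphML dump of a weighted similarity or class network."""
    nx.write_graphml(graph, str(path))
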