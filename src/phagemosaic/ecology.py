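"""Lifestyle, taxonomy and ecology of mosaic proteins.

Lifestyle is predicted from a temperate probability (temperate at >= 0.90,
virulent at <= 0.10, unclassified between).  rHMMs are assigned to a host
genus, ICTV family/genus or lifestyle group only when all their classified
member proteins agree; disagreement marks them as conserved across groups.
Per-genome mosaic fractions and cross-boundary labels for mosaic pairs are
derived on top.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .io import GenomeMetadata, ProteinRecord
from .mosaicism import MosaicCall

__all__ = [
    "GroupAssignment",
    "classify_lifestyle",
    "assign_group",
    "genome_mosaic_fraction",
    "genome_mosaic_fractions",
    "cross_boundary",
    "LIFESTYLE_TEMPERATE",
    "LIFESTYLE_VIRULENT",
    "LIFESTYLE_UNCLASSIFIED",
    "CONSERVED",
    "UNASSIGNED",
]

AXES = ("host_genus", "ictv_family", "ictv_genus", "lifestyle")

LIFESTYLE_TEMPERATE = "temperate"
LIFESTYLE_VIRULENT = "virulent"
LIFESTYLE_UNCLASSIFIED = "unclassified"

CONSERVED = "conserved_across_groups"
UNASSIGNED = "unassigned"

LABEL_SAME = "same_group"
LABEL_CROSS = "cross_group"
LABEL_CONSERVED = "involves_conserved"
LABEL_UNASSIGNED = "involves_unassigned"


@dataclass(frozen=True)
class GroupAssignment:
    rhmm_id: str
    axis: str
    value: str

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")

    @property
    def is_concrete(self) -> bool:
        return self.value not in (CONSERVED, UNASSIGNED)


def classify_lifestyle(temperate_probability: Optional[float]) -> str:
    """Temperate at probability >= 0.90, virulent at <= 0.10 (inclusive)."""
    if temperate_probability is None:
        return LIFESTYLE_UNCLASSIFIED
    if temperate_probability >= 0.90:
        return LIFESTYLE_TEMPERATE
    if temperate_probability <= 0.10:
        return LIFESTYLE_VIRULENT
    return LIFESTYLE_UNCLASSIFIED


def _member_value(rec: ProteinRecord, axis: str) -> Optional[str]:
    if axis == "lifestyle":
        ls = classify_lifestyle(rec.temperate_probability)
        return None if ls == LIFESTYLE_UNCLASSIFIED else ls
    return getattr(rec, axis)


def assign_group(
    rhmm_id: str, metadata: GenomeMetadata, axis: str
) -> GroupAssignment:
    """Assign an rHMM to a group along one axis.

    Null/unknown member values are ignored; if all remaining members agree
    the rHMM takes that group, if they disagree it is conserved across
    groups, and with no classified member it stays unassigned.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}")
    values = {
        v
        for rec in metadata.rhmm_members(rhmm_id)
        if (v := _member_value(rec, axis)) is not None
    }
    if not values:
        return GroupAssignment(rhmm_id, axis, UNASSIGNED)
    if len(values) == 1:
        return GroupAssignment(rhmm_id, axis, next(iter(values)))
    return GroupAssignment(rhmm_id, axis, CONSERVED)


def genome_mosaic_fraction(
    genome_id: str,
    metadata: GenomeMetadata,
    signals: Mapping[str, set[str]],
) -> Optional[float]:
    """Proportion of a genome's rHMM-mapped proteins with a mosaic signal.

    A protein counts when its rHMM carries either basis of mosaic signal.
    Genomes with no rHMM-mapped proteins have an undefined fraction,
    reported as None rather than 0.
    """
    records = [r for r in metadata.genome_records(genome_id) if r.rhmm_id is not None]
    if not records:
        return None
    mosaic = sum(1 for r in records if signals.get(r.rhmm_id))
    return mosaic / len(records)


def genome_mosaic_fractions(
    metadata: GenomeMetadata, signals: Mapping[str, set[str]]
) -> dict[str, Optional[float]]:
    return {
        g: genome_mosaic_fraction(g, metadata, signals) for g in metadata.genomes()
    }


def cross_boundary(
    calls: Iterable[MosaicCall],
    assignments: Mapping[str, GroupAssignment],
    tier_split: float = 0.7,
) -> list[tuple[MosaicCall, str, str]]:
    """Label mosaic pairs as within- or cross-group along one axis.

    Returns (call, label, stratum) triples, where the stratum splits calls
    by fragment identity below/at-or-above ``tier_split`` ("older" vs
    "recent") — recently emerged mosaicism tends to stay within groups
    while older mosaicism frequently crosses them.
    """
    out: list[tuple[MosaicCall, str, str]] = []
    for call in calls:
        ga = assignments.get(call.id_a)
        gb = assignments.get(call.id_b)
        if ga is None or gb is None:
            raise KeyError(f"missing group assignment for pair {call.pair}")
        if UNASSIGNED in (ga.value, gb.value):
            label = LABEL_UNASSIGNED
        elif CONSERVED in (ga.value, gb.value):
            label = LABEL_CONSERVED
        elif ga.value == gb.value:
            label = LABEL_SAME
        else:
            label = LABEL_CROSS
        p_id = call.fragment_p_id
        stratum = "recent" if (p_id is not None and p_id >= tier_split) else "older"
        out.append((call, label, stratum))
    return out
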