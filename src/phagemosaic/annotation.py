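"""Functional-class and domain-architecture assignment for rHMMs.

Function comes from PHROG hits (simplified classes, with generic catch-all
labels tolerated and an antidefence override); structure comes from ECOD
hits filtered at probability >= 0.95 and subject coverage >= 0.7, collapsed
to the set of T-groups — the domain architecture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import GENERIC_CLASSES, AlignmentHit, EcodId, FunctionMap
from .pairs import PairComparison

__all__ = [
    "FunctionalAnnotation",
    "DomainHit",
    "DomainArchitecture",
    "assign_function",
    "eligible_classes",
    "assign_domains",
    "architecture",
    "class_domain_presence",
]

STATUS_ASSIGNED = "assigned"
STATUS_UNKNOWN = "unknown"
STATUS_AMBIGUOUS = "ambiguous_discarded"


@dataclass(frozen=True)
class FunctionalAnnotation:
    rhmm_id: str
    status: str
    simplified_class: Optional[str] = None
    category: Optional[str] = None
    antidefence_class: Optional[str] = None
    supporting_hits: tuple = ()

    def __post_init__(self) -> None:
        if self.status == STATUS_ASSIGNED and self.simplified_class is None:
            raise ValueError(f"assigned annotation for {self.rhmm_id} lacks a class")


@dataclass(frozen=True)
class DomainHit:
    """One retained ECOD domain hit on an rHMM (already threshold-filtered)."""

    rhmm_id: str
    ecod: EcodId
    probability: float
    scov: float
    q_start: int
    q_end: int


@dataclass(frozen=True)
class DomainArchitecture:
    """The set of ECOD T-groups detected in one rHMM.

    Architecture identity is the T-group set alone — multiplicity and layout
    are ignored; ``layout`` (hits ordered along the sequence) is kept for
    display only.
    """

    rhmm_id: str
    t_groups: frozenset[str]
    layout: tuple[DomainHit, ...] = ()

    @property
    def x_groups(self) -> frozenset[int]:
        return frozenset(int(t.split(".")[0]) for t in self.t_groups)

    @property
    def architecture_key(self) -> str:
        return "|".join(sorted(self.t_groups))

    def __bool__(self) -> bool:
        return bool(self.t_groups)


def _other_id(pc: PairComparison, rhmm_id: str) -> str:
    if pc.id_a == rhmm_id:
        return pc.id_b
    if pc.id_b == rhmm_id:
        return pc.id_a
    raise ValueError(f"pair ({pc.id_a},{pc.id_b}) does not involve {rhmm_id}")


def assign_function(
    rhmm_id: str,
    phrog_hits: Sequence[PairComparison],
    antidefence_hits: Sequence[PairComparison],
    fmap: FunctionMap,
    min_p: float = 0.95,
    min_cov: float = 0.8,
) -> FunctionalAnnotation:
    """Assign one rHMM a simplified functional class.

    A hit qualifies at probability >= ``min_p`` and pairwise coverage
    min(qcov, scov) >= ``min_cov``.  Qualifying PHROG hits vote with their
    simplified classes: exactly one non-generic class wins (generic labels
    like "tail"/"structural protein" are tolerated alongside); more than one
    non-generic class is discarded as ambiguous; generic-only evidence
    assigns the generic class; no qualifying hits leaves the rHMM unknown.
    A qualifying antidefence hit, in the presence of any qualifying PHROG
    hit, overrides the class with the specific antidefence function.
    """
    qual = [pc for pc in phrog_hits if pc.p >= min_p and pc.cov_min >= min_cov]
    classes: dict[str, float] = {}
    for pc in qual:
        cls = fmap.simplified(_other_id(pc, rhmm_id))
        classes[cls] = max(classes.get(cls, 0.0), pc.p)

    qual_anti = [
        pc for pc in antidefence_hits if pc.p >= min_p and pc.cov_min >= min_cov
    ]
    if qual and qual_anti:
        best = max(qual_anti, key=lambda pc: (pc.p, _other_id(pc, rhmm_id)))
        anti_cls = _other_id(best, rhmm_id)
        return FunctionalAnnotation(
            rhmm_id=rhmm_id,
            status=STATUS_ASSIGNED,
            simplified_class=anti_cls,
            category="other",
            antidefence_class=anti_cls,
            supporting_hits=tuple(qual) + tuple(qual_anti),
        )

    non_generic = set(classes) - fmap.generic_classes
    generic = set(classes) & fmap.generic_classes
    if len(non_generic) > 1:
        return FunctionalAnnotation(
            rhmm_id=rhmm_id, status=STATUS_AMBIGUOUS, supporting_hits=tuple(qual)
        )
    if len(non_generic) == 1:
        cls = next(iter(non_generic))
        return FunctionalAnnotation(
            rhmm_id=rhmm_id,
            status=STATUS_ASSIGNED,
            simplified_class=cls,
            category=_class_category(fmap, cls),
            supporting_hits=tuple(qual),
        )
    if generic:
        # highest-probability generic hit wins; ties break lexicographically
        cls = max(sorted(generic), key=lambda c: classes[c])
        return FunctionalAnnotation(
            rhmm_id=rhmm_id,
            status=STATUS_ASSIGNED,
            simplified_class=cls,
            category=_class_category(fmap, cls),
            supporting_hits=tuple(qual),
        )
    return FunctionalAnnotation(rhmm_id=rhmm_id, status=STATUS_UNKNOWN)


def _class_category(fmap: FunctionMap, simplified_class: str) -> Optional[str]:
    for entry in fmap.entries.values():
        if entry.simplified_class == simplified_class:
            return entry.category
    return None


def eligible_classes(
    annotations: Iterable[FunctionalAnnotation],
    fmap: FunctionMap,
    min_phrog_seqs: int = 500,
    min_rhmms: int = 20,
) -> set[str]:
    """Classes retained for class-level statistics.

    A simplified class is eligible if its PHROGs together hold at least
    ``min_phrog_seqs`` sequences and it was assigned to at least
    ``min_rhmms`` rHMMs.
    """
    totals = fmap.class_total_seqs()
    counts: dict[str, int] = {}
    for ann in annotations:
        if ann.status == STATUS_ASSIGNED and ann.simplified_class is not None:
            counts[ann.simplified_class] = counts.get(ann.simplified_class, 0) + 1
    return {
        cls
        for cls, n in counts.items()
        if n >= min_rhmms and totals.get(cls, 0) >= min_phrog_seqs
    }


def assign_domains(
    ecod_hits: Sequence[AlignmentHit],
    ecod_map: Mapping[str, EcodId],
    min_p: float = 0.95,
    min_scov: float = 0.7,
) -> list[DomainHit]:
    """Filter raw rHMM-vs-ECOD hits into retained domain hits.

    Subject coverage is the aligned fraction of the ECOD domain profile.
    Output is sorted by query start position.
    """
    out: list[DomainHit] = []
    for h in ecod_hits:
        if h.subject_id not in ecod_map:
            raise KeyError(f"ECOD domain {h.subject_id!r} missing from id table")
        if h.probability >= min_p and h.scov >= min_scov:
            out.append(
                DomainHit(
                    rhmm_id=h.query_id,
                    ecod=ecod_map[h.subject_id],
                    probability=h.probability,
                    scov=h.scov,
                    q_start=h.q_start,
                    q_end=h.q_end,
                )
            )
    out.sort(key=lambda d: (d.q_start, d.q_end, d.ecod.t_id))
    return out


def architecture(rhmm_id: str, domain_hits: Sequence[DomainHit]) -> DomainArchitecture:
    """Collapse retained domain hits into the rHMM's architecture.

    Empty hit lists give an empty (falsy) architecture; such rHMMs are
    excluded from domain-based analyses downstream.
    """
    for d in domain_hits:
        if d.rhmm_id != rhmm_id:
            raise ValueError(f"hit on {d.rhmm_id} passed to architecture of {rhmm_id}")
    layout = tuple(sorted(domain_hits, key=lambda d: (d.q_start, d.q_end, d.ecod.t_id)))
    return DomainArchitecture(
        rhmm_id=rhmm_id,
        t_groups=frozenset(d.ecod.t_id for d in domain_hits),
        layout=layout,
    )


def class_domain_presence(
    architectures: Iterable[DomainArchitecture],
    annotations: Mapping[str, FunctionalAnnotation],
    level: str = "H",
    min_rhmms: int = 5,
    min_classes: Optional[int] = 3,
    generic_classes: frozenset[str] = GENERIC_CLASSES,
) -> pd.DataFrame:
    """Class x domain presence-count matrix.

    A cell counts the rHMMs of a functional class in which a domain (H- or
    T-group per ``level``) was detected; counts below ``min_rhmms`` are
    zeroed.  When ``min_classes`` is set, only domains present (after
    zeroing) in at least that many classes are kept.  Generic classes are
    excluded.
    """
    if level not in ("H", "T"):
        raise ValueError(f"level must be 'H' or 'T', got {level!r}")
    counts: dict[tuple[str, str], int] = {}
    for arch in architectures:
        ann = annotations.get(arch.rhmm_id)
        if ann is None or ann.status != STATUS_ASSIGNED:
            continue
        cls = ann.simplified_class
        if cls in generic_classes:
            continue
        groups = (
            {".".join(t.split(".")[:2]) for t in arch.t_groups}
            if level == "H"
            else set(arch.t_groups)
        )
        for g in groups:
            counts[(cls, g)] = counts.get((cls, g), 0) + 1
    classes = sorted({c for c, _ in counts})
    domains = sorted({g for _, g in counts})
    mat = pd.DataFrame(0, index=classes, columns=domains, dtype=int)
    for (cls, g), n in counts.items():
        mat.loc[cls, g] = n
    mat = mat.where(mat >= min_rhmms, 0)
    if min_classes is not None:
        keep = (mat > 0).sum(axis=0) >= min_classes
        mat = mat.loc[:, keep]
    mat = mat.loc[(mat > 0).any(axis=1), :]
    return mat
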