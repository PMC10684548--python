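"""Mosaic-pair detection: shared fragments between otherwise unrelated proteins.

Two complementary detectors are provided.  The ECOD-based detector calls a
pair mosaic when both proteins carry at least two domains from different
X-groups, share a domain of the same T-group, and each additionally carries
an X-group absent from the other.  The sequence-based detector calls a pair
mosaic when a high-probability (p >= 0.95), >= 30%-identity fragment of at
least 50 aa is shared while the pair aligns over at most half of either
sequence in the permissive (p >= 0.5) background search.  Fragment identity
further stratifies calls into recency tiers: contemporary (>= 50%),
high-confidence recent (>= 70%) and very-high-confidence recent (>= 90%).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Optional

from .annotation import DomainArchitecture
from .pairs import PERMISSIVE_P50, PairComparison

__all__ = [
    "Tier",
    "MosaicCall",
    "recency_tier",
    "ecod_mosaic",
    "sequence_mosaic",
    "mosaic_signal",
    "mosaic_signals",
    "detect_ecod_calls",
    "detect_sequence_calls",
]

BASIS_ECOD = "ecod"
BASIS_SEQUENCE = "sequence"


class Tier(IntEnum):
    """Recency tier of a mosaic call, ordered by fragment identity."""

    BASELINE = 0
    CONTEMPORARY = 1
    RECENT_HIGH = 2
    RECENT_VERY_HIGH = 3


def recency_tier(p_id: Optional[float]) -> Tier:
    """Map a fragment percent identity (fraction) to its recency tier."""
    if p_id is None:
        return Tier.BASELINE
    if p_id >= 0.9:
        return Tier.RECENT_VERY_HIGH
    if p_id >= 0.7:
        return Tier.RECENT_HIGH
    if p_id >= 0.5:
        return Tier.CONTEMPORARY
    return Tier.BASELINE


@dataclass(frozen=True)
class MosaicCall:
    """One rHMM pair flagged as mosaic."""

    id_a: str
    id_b: str
    basis: str
    tier: Tier = Tier.BASELINE
    shared_t_groups: frozenset[str] = frozenset()
    unique_x_a: frozenset[int] = frozenset()
    unique_x_b: frozenset[int] = frozenset()
    fragment_p: Optional[float] = None
    fragment_p_id: Optional[float] = None
    fragment_len_a: Optional[int] = None
    fragment_len_b: Optional[int] = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


def ecod_mosaic(
    arch_a: DomainArchitecture,
    arch_b: DomainArchitecture,
    p_id: Optional[float] = None,
) -> Optional[MosaicCall]:
    """ECOD-based mosaicism predicate on a pair of domain architectures.

    Requires: each side has domains from at least two different X-groups,
    the sides share a T-group, and each side has an X-group the other lacks.
    ``p_id`` (the pair's strict-search fragment identity, if known) sets the
    recency tier; without it the call is baseline.
    """
    xa, xb = arch_a.x_groups, arch_b.x_groups
    if len(xa) < 2 or len(xb) < 2:
        return None
    shared_t = arch_a.t_groups & arch_b.t_groups
    if not shared_t:
        return None
    ua, ub = xa - xb, xb - xa
    if not ua or not ub:
        return None
    id_a, id_b = sorted((arch_a.rhmm_id, arch_b.rhmm_id))
    if id_a == arch_b.rhmm_id:
        ua, ub = ub, ua
    return MosaicCall(
        id_a=id_a,
        id_b=id_b,
        basis=BASIS_ECOD,
        tier=recency_tier(p_id),
        shared_t_groups=frozenset(shared_t),
        unique_x_a=frozenset(ua),
        unique_x_b=frozenset(ub),
        fragment_p_id=p_id,
    )


def sequence_mosaic(
    permissive: PairComparison,
    strict: Optional[PairComparison],
    max_cov: float = 0.5,
    min_fragment_p: float = 0.95,
    min_p_id: float = 0.30,
    min_len: int = 50,
) -> Optional[MosaicCall]:
    """Sequence-based mosaicism predicate.

    ``permissive`` must carry the pair's coverage computed from all p >= 0.5
    hits (the homology background test); ``strict`` carries the fragment
    statistics computed from p >= 0.95 hits only, or None when no such
    fragment exists.  A call requires max(qcov, scov) <= ``max_cov`` in the
    background, fragment probability >= ``min_fragment_p``, fragment
    identity >= ``min_p_id``, and an aligned fragment of at least
    ``min_len`` residues on both sequences.
    """
    if permissive is None:
        raise ValueError("permissive-background comparison is mandatory")
    if permissive.threshold_context != PERMISSIVE_P50:
        raise ValueError(
            "background comparison must be computed at the permissive "
            f"threshold context, got {permissive.threshold_context!r}"
        )
    if strict is None:
        return None
    if (permissive.id_a, permissive.id_b) != (strict.id_a, strict.id_b):
        raise ValueError("permissive and strict comparisons refer to different pairs")
    if permissive.cov_max > max_cov:
        return None
    if strict.p < min_fragment_p:
        return None
    if strict.p_id < min_p_id:
        return None
    if min(strict.aligned_len_a, strict.aligned_len_b) < min_len:
        return None
    return MosaicCall(
        id_a=strict.id_a,
        id_b=strict.id_b,
        basis=BASIS_SEQUENCE,
        tier=recency_tier(strict.p_id),
        fragment_p=strict.p,
        fragment_p_id=strict.p_id,
        fragment_len_a=strict.aligned_len_a,
        fragment_len_b=strict.aligned_len_b,
    )


def mosaic_signal(rhmm_id: str, calls: Iterable[MosaicCall]) -> set[str]:
    """Bases ('ecod'/'sequence') for which an rHMM appears in >= 1 call."""
    return {c.basis for c in calls if rhmm_id in (c.id_a, c.id_b)}


def mosaic_signals(calls: Iterable[MosaicCall]) -> dict[str, set[str]]:
    """Per-rHMM mosaic signal sets over a collection of calls."""
    out: dict[str, set[str]] = {}
    for c in calls:
        for rid in (c.id_a, c.id_b):
            out.setdefault(rid, set()).add(c.basis)
    return out


def detect_ecod_calls(
    architectures: Mapping[str, DomainArchitecture],
    pair_p_ids: Optional[Mapping[tuple[str, str], float]] = None,
) -> list[MosaicCall]:
    """Run the ECOD-based detector over all candidate rHMM pairs.

    Candidates are generated by indexing multi-X architectures on their
    T-groups (a call requires a shared T-group), so unrelated pairs are
    never enumerated.  ``pair_p_ids`` optionally supplies strict-search
    fragment identities keyed by sorted pair for recency tiers.
    """
    by_t: dict[str, list[str]] = {}
    eligible = {
        rid: arch for rid, arch in architectures.items() if len(arch.x_groups) >= 2
    }
    for rid in sorted(eligible):
        for t in eligible[rid].t_groups:
            by_t.setdefault(t, []).append(rid)
    seen: set[tuple[str, str]] = set()
    calls: list[MosaicCall] = []
    for members in by_t.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                key = (a, b) if a <= b else (b, a)
                if key in seen:
                    continue
                seen.add(key)
                p_id = pair_p_ids.get(key) if pair_p_ids else None
                call = ecod_mosaic(eligible[a], eligible[b], p_id=p_id)
                if call is not None:
                    calls.append(call)
    calls.sort(key=lambda c: c.pair)
    return calls


def detect_sequence_calls(
    permissive_pairs: Iterable[PairComparison],
    strict_pairs: Iterable[PairComparison],
    **thresholds,
) -> list[MosaicCall]:
    """Run the sequence-based detector over matching pair comparisons."""
    strict_by_pair = {pc.pair: pc for pc in strict_pairs}
    calls: list[MosaicCall] = []
    for perm in permissive_pairs:
        call = sequence_mosaic(perm, strict_by_pair.get(perm.pair), **thresholds)
        if call is not None:
            calls.append(call)
    calls.sort(key=lambda c: c.pair)
    return calls
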