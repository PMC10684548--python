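"""Collapse directional, multi-HSP profile-profile hits into symmetric
pairwise comparisons.

Profile-profile alignments are non-commutative, so each rHMM pair is searched
both ways (query-to-subject and subject-to-query).  The aggregation here is
deliberately conservative: the final pairwise probability and percent
identity are the minima over the two directions, and coverage counts the
union of aligned residues from both directions so it is symmetric and
direction-order-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import numpy as np

from .io import AlignmentHit

__all__ = [
    "PairComparison",
    "NoHitsError",
    "residue_coverage",
    "per_residue_probability",
    "aggregate_pair",
    "filter_pairs",
    "write_pair_table",
    "read_pair_table",
]

PERMISSIVE_P50 = "permissive_p50"
STRICT_P95 = "strict_p95"


class NoHitsError(ValueError):
    """Raised when a per-residue statistic is requested with no hits;
    distinct from a legitimate value of zero."""


@dataclass(frozen=True)
class PairComparison:
    """Symmetric aggregate of all hits between two rHMMs.

    ``id_a`` < ``id_b`` lexicographically.  ``qcov``/``scov`` are the
    coverages of ``id_a`` and ``id_b`` respectively, merged over both search
    directions; ``cov_min``/``cov_max`` are their min and max.
    ``threshold_context`` records which probability floor the input hits were
    gathered at (permissive 0.5 background vs strict 0.95).
    """

    id_a: str
    id_b: str
    p: float
    p_id: float
    qcov: float
    scov: float
    cov_min: float
    cov_max: float
    aligned_len_a: int
    aligned_len_b: int
    threshold_context: str = STRICT_P95

    def __post_init__(self) -> None:
        for name in ("p", "p_id", "qcov", "scov", "cov_min", "cov_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} out of [0,1] for pair "
                                 f"({self.id_a},{self.id_b})")
        if self.cov_min > self.cov_max + 1e-12:
            raise ValueError("cov_min exceeds cov_max")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1] + 1:
            last = merged[-1]
            merged[-1] = (last[0], max(last[1], end))
        else:
            merged.append((start, end))
    return merged


def _intervals(hits: Sequence[AlignmentHit], role: str) -> list[tuple[int, int]]:
    if role == "query":
        return [h.q_interval for h in hits]
    if role == "subject":
        return [h.s_interval for h in hits]
    raise ValueError(f"unknown role {role!r}")


def residue_coverage(
    hits: Sequence[AlignmentHit], seq_len: int, role: str = "query"
) -> tuple[float, int]:
    """Coverage of one sequence by a set of hits.

    Returns (fraction, residue count) where the count is the size of the
    union of hit intervals on that sequence — overlapping stretches are
    counted once.
    """
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    intervals = _intervals(hits, role)
    for start, end in intervals:
        if start < 1 or end > seq_len:
            raise ValueError(
                f"interval [{start},{end}] outside [1,{seq_len}]"
            )
    count = sum(end - start + 1 for start, end in _merge_intervals(intervals))
    return count / seq_len, count


def per_residue_probability(
    hits: Sequence[AlignmentHit], seq_len: int, role: str = "query"
) -> float:
    """Mean hit probability over covered residues.

    Each covered residue carries the maximum probability among the hits
    covering it; the mean runs over covered residues only (uncovered
    positions do not dilute it).
    """
    if not hits:
        raise NoHitsError("per-residue probability undefined with no hits")
    arr = np.zeros(seq_len, dtype=float)
    covered = np.zeros(seq_len, dtype=bool)
    for h in hits:
        start, end = (h.q_interval if role == "query" else h.s_interval)
        if start < 1 or end > seq_len:
            raise ValueError(f"interval [{start},{end}] outside [1,{seq_len}]")
        sl = slice(start - 1, end)
        arr[sl] = np.maximum(arr[sl], h.probability)
        covered[sl] = True
    return float(arr[covered].mean())


def _direction_identity(hits: Sequence[AlignmentHit]) -> float:
    """Alignment-length-weighted mean of per-HSP identities."""
    lengths = np.array([h.q_end - h.q_start + 1 for h in hits], dtype=float)
    idents = np.array([h.percent_identity for h in hits], dtype=float)
    return float((lengths * idents).sum() / lengths.sum())


def aggregate_pair(
    dir_ab: Sequence[AlignmentHit],
    dir_ba: Sequence[AlignmentHit],
    threshold_context: str = STRICT_P95,
) -> PairComparison:
    """Aggregate the two search directions of one rHMM pair.

    ``dir_ab`` holds hits with the first sequence as query, ``dir_ba`` the
    reverse direction.  Per direction, the probability is the per-residue
    mean over that direction's query, and the identity the
    alignment-length-weighted mean over its HSPs; the pair-level ``p`` and
    ``p_id`` are the minima over the non-empty directions.  Coverage of each
    sequence merges its intervals from both directions.
    """
    if not dir_ab and not dir_ba:
        raise NoHitsError("both directions empty for pair aggregation")

    if dir_ab:
        first, second = dir_ab[0].query_id, dir_ab[0].subject_id
        len_first, len_second = dir_ab[0].q_len, dir_ab[0].s_len
    else:
        first, second = dir_ba[0].subject_id, dir_ba[0].query_id
        len_first, len_second = dir_ba[0].s_len, dir_ba[0].q_len
    for h in dir_ab:
        if (h.query_id, h.subject_id) != (first, second):
            raise ValueError("dir_ab hits refer to different pairs")
    for h in dir_ba:
        if (h.query_id, h.subject_id) != (second, first):
            raise ValueError("dir_ba hits do not mirror dir_ab")

    probs: list[float] = []
    idents: list[float] = []
    if dir_ab:
        probs.append(per_residue_probability(dir_ab, len_first, role="query"))
        idents.append(_direction_identity(dir_ab))
    if dir_ba:
        probs.append(per_residue_probability(dir_ba, len_second, role="query"))
        idents.append(_direction_identity(dir_ba))
    p = min(probs)
    p_id = min(idents)

    # union of intervals on each sequence across both directions
    first_ivs = _intervals(dir_ab, "query") + _intervals(dir_ba, "subject")
    second_ivs = _intervals(dir_ab, "subject") + _intervals(dir_ba, "query")
    cov_first, n_first = _coverage_from_intervals(first_ivs, len_first)
    cov_second, n_second = _coverage_from_intervals(second_ivs, len_second)

    if first <= second:
        id_a, id_b = first, second
        qcov, scov = cov_first, cov_second
        len_a_al, len_b_al = n_first, n_second
    else:
        id_a, id_b = second, first
        qcov, scov = cov_second, cov_first
        len_a_al, len_b_al = n_second, n_first

    return PairComparison(
        id_a=id_a,
        id_b=id_b,
        p=p,
        p_id=p_id,
        qcov=qcov,
        scov=scov,
        cov_min=min(qcov, scov),
        cov_max=max(qcov, scov),
        aligned_len_a=len_a_al,
        aligned_len_b=len_b_al,
        threshold_context=threshold_context,
    )


def _coverage_from_intervals(
    intervals: Sequence[tuple[int, int]], seq_len: int
) -> tuple[float, int]:
    for start, end in intervals:
        if start < 1 or end > seq_len:
            raise ValueError(f"interval [{start},{end}] outside [1,{seq_len}]")
    count = sum(e - s + 1 for s, e in _merge_intervals(intervals))
    return count / seq_len, count


def filter_pairs(
    pairs: Iterable[PairComparison],
    min_p: float,
    min_cov_mode: str = "min",
    min_cov: float = 0.0,
) -> list[PairComparison]:
    """Pure probability/coverage filter.

    ``min_cov_mode`` selects which coverage the threshold applies to:
    ``"min"`` uses cov_min, ``"max"`` uses cov_max, ``"none"`` skips the
    coverage test entirely.
    """
    if min_cov_mode not in ("min", "max", "none"):
        raise ValueError(f"unknown min_cov_mode {min_cov_mode!r}")
    out = []
    for pc in pairs:
        if pc.p < min_p:
            continue
        if min_cov_mode == "min" and pc.cov_min < min_cov:
            continue
        if min_cov_mode == "max" and pc.cov_max < min_cov:
            continue
        out.append(pc)
    return out


PAIR_COLUMNS = (
    "id_a", "id_b", "p", "p_id", "qcov", "scov", "cov_min", "cov_max",
    "aligned_len_a", "aligned_len_b", "threshold_context",
)


def write_pair_table(
    pairs: Iterable[PairComparison], stream: Union[str, Path, IO[str]]
) -> None:
    if isinstance(stream, (str, Path)):
        handle: IO[str] = open(stream, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = stream, False
    try:
        handle.write("\t".join(PAIR_COLUMNS) + "\n")
        for pc in pairs:
            handle.write(
                "\t".join(
                    [
                        pc.id_a, pc.id_b, repr(pc.p), repr(pc.p_id),
                        repr(pc.qcov), repr(pc.scov), repr(pc.cov_min),
                        repr(pc.cov_max), str(pc.aligned_len_a),
                        str(pc.aligned_len_b), pc.threshold_context,
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


def read_pair_table(stream: Union[str, Path, IO[str]]) -> list[PairComparison]:
    import csv

    if isinstance(stream, (str, Path)):
        handle: IO[str] = open(stream, "r", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = stream, False
    try:
        out: list[PairComparison] = []
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "id_a":
                continue
            out.append(
                PairComparison(
                    id_a=row[0], id_b=row[1], p=float(row[2]), p_id=float(row[3]),
                    qcov=float(row[4]), scov=float(row[5]), cov_min=float(row[6]),
                    cov_max=float(row[7]), aligned_len_a=int(row[8]),
                    aligned_len_b=int(row[9]), threshold_context=row[10],
                )
            )
        return out
    finally:
        if close:
            handle.close()
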