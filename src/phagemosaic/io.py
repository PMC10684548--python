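"""Readers and writers for every table the pipeline touches.

All tables are UTF-8, tab-delimited text; lines starting with ``#`` are
comments.  Alignment coordinates are 1-based inclusive (hhsuite convention)
and are never converted anywhere else in the codebase.  Probabilities and
identities are stored as fractions in [0, 1]; hhsuite-style percent input is
normalised at parse time via the ``prob_scale`` flag.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Optional, Union

__all__ = [
    "AlignmentHit",
    "EcodId",
    "FunctionMap",
    "PhrogEntry",
    "ProteinRecord",
    "GenomeMetadata",
    "GENERIC_CLASSES",
    "HitTableError",
    "read_hit_table",
    "write_hit_table",
    "read_lengths_table",
    "parse_ecod_id",
    "format_ecod_id",
    "read_ecod_map",
    "write_ecod_map",
    "read_function_map",
    "write_function_map",
    "read_metadata",
    "write_metadata",
]

SEARCH_TAGS = ("self", "ecod", "phrog", "antidefence")

#: Functional classes treated as generic ("catch-all") labels that may
#: co-occur with one specific class without making the annotation ambiguous.
GENERIC_CLASSES = frozenset({"tail", "structural protein"})


class HitTableError(ValueError):
    """Malformed row or invariant violation in a tabular input."""


@dataclass(frozen=True)
class AlignmentHit:
    """One directional local profile-profile hit.

    Coordinates are 1-based inclusive residue positions; ``q_len`` and
    ``s_len`` are the full lengths of the query and subject sequences.
    """

    query_id: str
    subject_id: str
    probability: float
    percent_identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_len: int
    s_len: int
    search_tag: str = "self"

    def __post_init__(self) -> None:
        if self.search_tag not in SEARCH_TAGS:
            raise HitTableError(
                f"unknown search_tag {self.search_tag!r} for hit "
                f"{self.query_id}->{self.subject_id}"
            )
        if not (0.0 <= self.probability <= 1.0):
            raise HitTableError(
                f"probability {self.probability} out of [0,1] for hit "
                f"{self.query_id}->{self.subject_id}"
            )
        if not (0.0 <= self.percent_identity <= 1.0):
            raise HitTableError(
                f"percent identity {self.percent_identity} out of [0,1] for hit "
                f"{self.query_id}->{self.subject_id}"
            )
        if not (1 <= self.q_start <= self.q_end <= self.q_len):
            raise HitTableError(
                f"query coordinates [{self.q_start},{self.q_end}] invalid for "
                f"length {self.q_len} in hit {self.query_id}->{self.subject_id}"
            )
        if not (1 <= self.s_start <= self.s_end <= self.s_len):
            raise HitTableError(
                f"subject coordinates [{self.s_start},{self.s_end}] invalid for "
                f"length {self.s_len} in hit {self.query_id}->{self.subject_id}"
            )

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    @property
    def scov(self) -> float:
        """Subject coverage of this single hit."""
        return (self.s_end - self.s_start + 1) / self.s_len

    @property
    def qcov(self) -> float:
        """Query coverage of this single hit."""
        return (self.q_end - self.q_start + 1) / self.q_len


@dataclass(frozen=True)
class EcodId:
    """ECOD lineage identifier at the X/H/T (optionally F) levels.

    X-groups collect possibly homologous domains, H-groups homologous ones,
    T-groups domains of the same topology; same X is assumed related,
    different X unrelated.
    """

    x_id: int
    h_id: str
    t_id: str
    f_id: Optional[str] = None
    names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.h_id.startswith(f"{self.x_id}."):
            raise ValueError(f"h_id {self.h_id!r} inconsistent with x_id {self.x_id}")
        if not self.t_id.startswith(self.h_id + "."):
            raise ValueError(f"t_id {self.t_id!r} inconsistent with h_id {self.h_id!r}")
        if self.f_id is not None and not self.f_id.startswith(self.t_id + "."):
            raise ValueError(f"f_id {self.f_id!r} inconsistent with t_id {self.t_id!r}")


def parse_ecod_id(text: str) -> EcodId:
    """Parse a dotted ECOD identifier such as ``"219.1.1"``.

    Three levels give X.H.T; a fourth gives the F-group.  Anything else is
    an error.
    """
    parts = text.strip().split(".")
    if len(parts) < 3 or len(parts) > 4:
        raise ValueError(f"ECOD id {text!r} must have 3 or 4 dot-separated levels")
    for part in parts:
        if not part.isdigit():
            raise ValueError(f"ECOD id {text!r} has non-integer component {part!r}")
    x_id = int(parts[0])
    h_id = ".".join(parts[:2])
    t_id = ".".join(parts[:3])
    f_id = ".".join(parts[:4]) if len(parts) == 4 else None
    return EcodId(x_id=x_id, h_id=h_id, t_id=t_id, f_id=f_id)


def format_ecod_id(ecod: EcodId) -> str:
    """Inverse of :func:`parse_ecod_id` (deepest known level)."""
    return ecod.f_id if ecod.f_id is not None else ecod.t_id


@dataclass(frozen=True)
class PhrogEntry:
    phrog_class: str
    simplified_class: str
    category: str
    total_seqs: int


@dataclass
class FunctionMap:
    """Mapping from PHROG functional classes to simplified classes.

    PHROG labels that name closely related biological functions are merged
    into one simplified class (e.g. two Holliday-junction-resolvase variants
    into "Holliday junction resolvase").  ``generic_classes`` holds the
    catch-all labels tolerated alongside a specific class.
    """

    entries: dict[str, PhrogEntry]
    generic_classes: frozenset[str] = GENERIC_CLASSES

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("function map is empty; pipeline cannot annotate")
        self.generic_classes = frozenset(self.generic_classes)

    def simplified(self, phrog_class: str) -> str:
        try:
            return self.entries[phrog_class].simplified_class
        except KeyError:
            raise KeyError(f"PHROG class {phrog_class!r} missing from function map")

    def category(self, phrog_class: str) -> str:
        return self.entries[phrog_class].category

    def simplified_classes(self) -> set[str]:
        return {e.simplified_class for e in self.entries.values()}

    def class_total_seqs(self) -> dict[str, int]:
        """Total PHROG sequence counts summed per simplified class."""
        totals: dict[str, int] = {}
        for e in self.entries.values():
            totals[e.simplified_class] = totals.get(e.simplified_class, 0) + e.total_seqs
        return totals


@dataclass(frozen=True)
class ProteinRecord:
    genome_id: str
    protein_id: str
    rhmm_id: Optional[str]
    host_genus: Optional[str] = None
    ictv_family: Optional[str] = None
    ictv_genus: Optional[str] = None
    temperate_probability: Optional[float] = None

    def __post_init__(self) -> None:
        tp = self.temperate_probability
        if tp is not None and not (0.0 <= tp <= 1.0):
            raise ValueError(
                f"temperate probability {tp} out of [0,1] for {self.protein_id}"
            )


@dataclass
class GenomeMetadata:
    """Per-protein genome membership plus genome-level taxonomy/lifestyle."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        seen: dict[str, Optional[str]] = {}
        for rec in self.records:
            prev = seen.get(rec.protein_id, rec.rhmm_id)
            if rec.protein_id in seen and prev != rec.rhmm_id:
                raise ValueError(
                    f"protein {rec.protein_id} mapped to two rHMMs "
                    f"({prev} and {rec.rhmm_id})"
                )
            seen[rec.protein_id] = rec.rhmm_id

    def rhmm_members(self, rhmm_id: str) -> list[ProteinRecord]:
        return [r for r in self.records if r.rhmm_id == rhmm_id]

    def genomes(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.genome_id not in out:
                out.append(rec.genome_id)
        return out

    def genome_records(self, genome_id: str) -> list[ProteinRecord]:
        return [r for r in self.records if r.genome_id == genome_id]


# ---------------------------------------------------------------------------
# tabular parsing helpers

Stream = Union[str, Path, IO[str]]


def _open_rows(stream: Stream) -> Iterator[tuple[int, list[str]]]:
    if isinstance(stream, (str, Path)):
        handle: IO[str] = open(stream, "r", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = stream, False
    try:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            yield lineno, row
    finally:
        if close:
            handle.close()


def _scale(value: float, prob_scale: str, lineno: int) -> float:
    if prob_scale == "percent":
        return value / 100.0
    if prob_scale == "fraction":
        return value
    raise ValueError(f"unknown prob_scale {prob_scale!r} (line {lineno})")


BLASTTAB_COLUMNS = (
    "query", "subject", "pid", "aln_len", "qstart", "qend",
    "sstart", "send", "evalue", "prob",
)
NATIVE_COLUMNS = (
    "query", "subject", "prob", "pid", "qstart", "qend", "sstart", "send",
    "q_len", "s_len", "search_tag",
)


def read_lengths_table(stream: Stream) -> dict[str, int]:
    """Sidecar table mapping sequence id to full length (two TSV columns)."""
    lengths: dict[str, int] = {}
    for lineno, row in _open_rows(stream):
        if len(row) < 2:
            raise HitTableError(f"lengths table line {lineno}: expected 2 columns")
        try:
            lengths[row[0]] = int(row[1])
        except ValueError as exc:
            raise HitTableError(f"lengths table line {lineno}: {exc}") from exc
    return lengths


def read_hit_table(
    stream: Stream,
    dialect: str = "native_tsv",
    prob_scale: str = "fraction",
    lengths: Optional[Mapping[str, int]] = None,
    search_tag: str = "self",
) -> list[AlignmentHit]:
    """Read a pairwise hit table into :class:`AlignmentHit` records.

    ``blasttab_plus_prob`` is the hhsuite blasttab layout plus a trailing
    probability column; sequence lengths must then come from a sidecar
    ``lengths`` mapping and all hits take the supplied ``search_tag``.  The
    ``native_tsv`` dialect carries lengths and tag in-row and expects a
    header line.  Row order is preserved.
    """
    hits: list[AlignmentHit] = []
    header_skipped = False
    for lineno, row in _open_rows(stream):
        if dialect == "native_tsv" and not header_skipped:
            header_skipped = True
            if row[0] == "query":  # header row
                continue
        try:
            if dialect == "blasttab_plus_prob":
                if len(row) < 10:
                    raise HitTableError("expected 10 columns")
                if lengths is None:
                    raise HitTableError(
                        "blasttab dialect requires a sidecar lengths table"
                    )
                q, s = row[0], row[1]
                if q not in lengths:
                    raise HitTableError(f"no length for query {q!r}")
                if s not in lengths:
                    raise HitTableError(f"no length for subject {s!r}")
                hit = AlignmentHit(
                    query_id=q,
                    subject_id=s,
                    probability=_scale(float(row[9]), prob_scale, lineno),
                    percent_identity=_scale(float(row[2]), prob_scale, lineno),
                    q_start=int(row[4]),
                    q_end=int(row[5]),
                    s_start=int(row[6]),
                    s_end=int(row[7]),
                    q_len=lengths[q],
                    s_len=lengths[s],
                    search_tag=search_tag,
                )
            elif dialect == "native_tsv":
                if len(row) < 11:
                    raise HitTableError("expected 11 columns")
                hit = AlignmentHit(
                    query_id=row[0],
                    subject_id=row[1],
                    probability=_scale(float(row[2]), prob_scale, lineno),
                    percent_identity=_scale(float(row[3]), prob_scale, lineno),
                    q_start=int(row[4]),
                    q_end=int(row[5]),
                    s_start=int(row[6]),
                    s_end=int(row[7]),
                    q_len=int(row[8]),
                    s_len=int(row[9]),
                    search_tag=row[10],
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
        except (ValueError, HitTableError) as exc:
            raise HitTableError(f"hit table line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], stream: Stream) -> None:
    """Write hits in the native dialect (fractions, lengths in-row)."""
    if isinstance(stream, (str, Path)):
        handle: IO[str] = open(stream, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = stream, False
    try:
        handle.write("\t".join(NATIVE_COLUMNS) + "\n")
        for h in hits:
            handle.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id,
                        repr(h.probability), repr(h.percent_identity),
                        str(h.q_start), str(h.q_end),
                        str(h.s_start), str(h.s_end),
                        str(h.q_len), str(h.s_len), h.search_tag,
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


def read_ecod_map(stream: Stream) -> dict[str, EcodId]:
    """ECOD id table: (ecod_domain_id, dotted lineage, optional names...)."""
    out: dict[str, EcodId] = {}
    for lineno, row in _open_rows(stream):
        if row[0] == "ecod_domain_id":
            continue
        if len(row) < 2:
            raise HitTableError(f"ECOD map line {lineno}: expected >= 2 columns")
        try:
            ecod = parse_ecod_id(row[1])
        except ValueError as exc:
            raise HitTableError(f"ECOD map line {lineno}: {exc}") from exc
        if len(row) > 2 and row[2]:
            ecod = EcodId(ecod.x_id, ecod.h_id, ecod.t_id, ecod.f_id, {"t": row[2]})
        out[row[0]] = ecod
    return out


def write_ecod_map(mapping: Mapping[str, EcodId], stream: Stream) -> None:
    if isinstance(stream, (str, Path)):
        handle: IO[str] = open(stream, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = stream, False
    try:
        handle.write("ecod_domain_id\tt_id\tname\n")
        for domain_id in sorted(mapping):
            ecod = mapping[domain_id]
            name = ecod.names.get("t", "") if ecod.names else ""
            handle.write(f"{domain_id}\t{format_ecod_id(ecod)}\t{name}\n")
    finally:
        if close:
            handle.close()


def read_function_map(stream: Stream) -> FunctionMap:
    """PHROG simplification table: phrog_class, simplified_class, category,
    total_seqs."""
    entries: dict[str, PhrogEntry] = {}
    for lineno, row in _open_rows(stream):
        if row[0] == "phrog_class":
            continue
        if len(row) < 4:
            raise HitTableError(f"function map line {lineno}: expected 4 columns")
        try:
            entry = PhrogEntry(row[0], row[1], row[2], int(row[3]))
        except ValueError as exc:
            raise HitTableError(f"function map line {lineno}: {exc}") from exc
        if row[0] in entries and entries[row[0]].simplified_class != entry.simplified_class:
            raise HitTableError(
                f"function map line {lineno}: PHROG class {row[0]!r} mapped to "
                f"both {entries[row[0]].simplified_class!r} and "
                f"{entry.simplified_class!r}"
            )
        entries[row[0]] = entry
    return FunctionMap(entries=entries)


def write_function_map(fmap: FunctionMap, stream: Stream) -> None:
    if isinstance(stream, (str, Path)):
        handle: IO[str] = open(stream, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = stream, False
    try:
        handle.write("phrog_class\tsimplified_class\tcategory\ttotal_seqs\n")
        for name in sorted(fmap.entries):
            e = fmap.entries[name]
            handle.write(
                f"{e.phrog_class}\t{e.simplified_class}\t{e.category}\t{e.total_seqs}\n"
            )
    finally:
        if close:
            handle.close()


_NA = ""


def read_metadata(stream: Stream) -> GenomeMetadata:
    """Genome metadata table; empty fields are nulls."""
    records: list[ProteinRecord] = []
    for lineno, row in _open_rows(stream):
        if row[0] == "genome_id":
            continue
        if len(row) < 7:
            raise HitTableError(f"metadata line {lineno}: expected 7 columns")
        try:
            records.append(
                ProteinRecord(
                    genome_id=row[0],
                    protein_id=row[1],
                    rhmm_id=row[2] or None,
                    host_genus=row[3] or None,
                    ictv_family=row[4] or None,
                    ictv_genus=row[5] or None,
                    temperate_probability=float(row[6]) if row[6] else None,
                )
            )
        except ValueError as exc:
            raise HitTableError(f"metadata line {lineno}: {exc}") from exc
    return GenomeMetadata(records=records)


def write_metadata(meta: GenomeMetadata, stream: Stream) -> None:
    if isinstance(stream, (str, Path)):
        handle: IO[str] = open(stream, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = stream, False
    try:
        handle.write(
            "genome_id\tprotein_id\trhmm_id\thost_genus\tictv_family\t"
            "ictv_genus\ttemperate_probability\n"
        )
        for r in meta.records:
            tp = repr(r.temperate_probability) if r.temperate_probability is not None else _NA
            handle.write(
                "\t".join(
                    [
                        r.genome_id, r.protein_id, r.rhmm_id or _NA,
                        r.host_genus or _NA, r.ictv_family or _NA,
                        r.ictv_genus or _NA, tp,
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()
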