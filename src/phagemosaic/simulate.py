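"""Synthetic input bundles with planted ground truth.

The generator emulates the pipeline's upstream searches — rHMM-vs-rHMM,
rHMM-vs-ECOD and rHMM-vs-PHROG hit tables plus the ECOD id table, PHROG
simplification map and genome metadata — with known mosaic structure planted
in, so every stage can be tested end to end without any external database.

Planted structure, by construction:

* ECOD-mosaic pairs satisfy the domain predicate on their true
  architectures: each side has two domains from different X-groups, one
  T-group is shared, and each side carries an X-group the other lacks.
  Every planted pair draws its three X-groups from a reserved block, so no
  two planted pairs can cross-call each other and detection precision is
  structurally 1 on noiseless output.
* Sequence-mosaic pairs share a fragment (>= 50 aa, probability 0.99,
  identity drawn per planted "age" class) covering at most half of either
  protein; they carry no ECOD domains.
* Planted families are cliques of full-length reciprocal hits
  (coverage 1.0, probability 0.99); all remaining rHMMs are singletons.
* Unrelated pairs emit no hits at all (clean null); an optional spurious-hit
  rate adds low-probability background fragments to exercise the permissive
  filter.

Noise knobs: independent per-domain dropout of ECOD hits and Gaussian
downward jitter of hit probabilities.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from .families import FamilyPartition
from .io import (
    AlignmentHit,
    EcodId,
    FunctionMap,
    GenomeMetadata,
    PhrogEntry,
    ProteinRecord,
    parse_ecod_id,
    write_ecod_map,
    write_function_map,
    write_hit_table,
    write_metadata,
)
from .mosaicism import MosaicCall, Tier, recency_tier

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "Bundle",
    "simulate",
    "write_bundle",
    "score_recovery",
    "RecoveryReport",
]

DEFAULT_CLASSES: tuple[tuple[str, str], ...] = (
    ("DNA polymerase", "DNA, RNA and nucleotide metabolism"),
    ("endonuclease", "DNA, RNA and nucleotide metabolism"),
    ("Holliday junction resolvase", "DNA, RNA and nucleotide metabolism"),
    ("replication initiation", "DNA, RNA and nucleotide metabolism"),
    ("endolysin", "lysis"),
    ("tail fibre", "tail"),
    ("tail spike", "tail"),
    ("adaptor", "head and packaging"),
    ("tail", "tail"),
    ("structural protein", "other"),
)

#: identity centres of the planted "age" classes; each sequence-mosaic pair
#: cycles through these, exercising every recency tier.
DEFAULT_IDENTITY_BY_AGE: tuple[float, ...] = (0.35, 0.55, 0.75, 0.95)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults are sized for a desk-scale benchmark: 200 rHMMs with 20 planted
    ECOD-mosaic pairs, 20 sequence-mosaic pairs and 15 multi-member
    families, noiseless.  Noise enters only through ``domain_dropout_rate``
    (independent loss of true ECOD hits) and ``probability_jitter_sd``.
    """

    seed: int = 0
    n_rhmms: int = 200
    n_ecod_mosaic_pairs: int = 20
    n_sequence_mosaic_pairs: int = 20
    n_families: int = 15
    family_size_range: tuple[int, int] = (2, 5)
    architecture_size_probs: tuple[float, ...] = (0.45, 0.3, 0.15, 0.07, 0.03)
    domain_dropout_rate: float = 0.0
    probability_jitter_sd: float = 0.0
    spurious_hit_rate: float = 0.0
    identity_by_age: tuple[float, ...] = DEFAULT_IDENTITY_BY_AGE
    class_labels: tuple[tuple[str, str], ...] = DEFAULT_CLASSES
    n_antidefence_rhmms: int = 2
    n_genomes: int = 40
    domain_length_range: tuple[int, int] = (80, 160)
    fragment_length_range: tuple[int, int] = (60, 120)

    def validate(self) -> None:
        reserved = 2 * (self.n_ecod_mosaic_pairs + self.n_sequence_mosaic_pairs)
        min_family = self.n_families * self.family_size_range[0]
        if reserved + min_family > self.n_rhmms:
            raise ValueError(
                f"config infeasible: {reserved} pair members plus >= "
                f"{min_family} family members exceed n_rhmms={self.n_rhmms}"
            )
        if not (0.0 <= self.domain_dropout_rate <= 1.0):
            raise ValueError("domain_dropout_rate out of [0,1]")
        if not (0.0 <= self.spurious_hit_rate <= 1.0):
            raise ValueError("spurious_hit_rate out of [0,1]")
        if abs(sum(self.architecture_size_probs) - 1.0) > 1e-9:
            raise ValueError("architecture_size_probs must sum to 1")


@dataclass(frozen=True)
class SequencePairTruth:
    id_a: str
    id_b: str
    p_id: float
    tier: Tier
    fragment_len: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass
class TruthSet:
    """Ground truth planted by the generator."""

    architectures: dict[str, frozenset[str]]
    classes: dict[str, str]
    family_partition: FamilyPartition
    ecod_pairs: list[tuple[str, str]]
    sequence_pairs: list[SequencePairTruth]
    groups: dict[str, dict[str, str]] = field(default_factory=dict)


@dataclass
class Bundle:
    """One complete synthetic input set plus its truth."""

    config: SimulationConfig
    self_hits: list[AlignmentHit]
    ecod_hits: list[AlignmentHit]
    phrog_hits: list[AlignmentHit]
    antidefence_hits: list[AlignmentHit]
    ecod_map: dict[str, EcodId]
    function_map: FunctionMap
    metadata: GenomeMetadata
    truth: TruthSet
    protein_lengths: dict[str, int] = field(default_factory=dict)


def _clip_prob(p: float) -> float:
    return float(min(0.99, max(0.5, p)))


class _EcodUniverse:
    """Allocates fresh T-groups (one per fresh X-group) on demand."""

    def __init__(self, rng: np.random.Generator, length_range: tuple[int, int]):
        self.rng = rng
        self.length_range = length_range
        self.next_x = 101
        self.lengths: dict[str, int] = {}
        self.map: dict[str, EcodId] = {}

    def new_t(self) -> str:
        t_id = f"{self.next_x}.1.1"
        self.next_x += 1
        lo, hi = self.length_range
        self.lengths[t_id] = int(self.rng.integers(lo, hi + 1))
        self.map[f"d{t_id}"] = parse_ecod_id(t_id)
        return t_id


def _place_domains(
    rng: np.random.Generator, t_groups: Sequence[str], lengths: Mapping[str, int]
) -> tuple[int, list[tuple[str, int, int]]]:
    """Lay domains along a protein with random linkers; return (protein
    length, [(t_id, q_start, q_end)])."""
    pos = int(rng.integers(5, 21))
    layout = []
    for t in t_groups:
        dlen = lengths[t]
        layout.append((t, pos + 1, pos + dlen))
        pos += dlen + int(rng.integers(10, 31))
    return pos + int(rng.integers(5, 21)), layout


def simulate(config: SimulationConfig) -> Bundle:
    """Generate one synthetic bundle; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_rhmms
    rhmms = [f"rhmm{i:06d}" for i in range(n)]

    universe = _EcodUniverse(rng, config.domain_length_range)
    true_arch: dict[str, list[str]] = {r: [] for r in rhmms}
    ecod_pairs: list[tuple[str, str]] = []
    sequence_pairs: list[SequencePairTruth] = []

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = rhmms[cursor:cursor + k]
        cursor += k
        return out

    # --- planted ECOD-mosaic pairs: {shared, unique_a} vs {shared, unique_b}
    for _ in range(config.n_ecod_mosaic_pairs):
        a, b = take(2)
        t_shared, t_a, t_b = universe.new_t(), universe.new_t(), universe.new_t()
        true_arch[a] = [t_shared, t_a]
        true_arch[b] = [t_b, t_shared]
        ecod_pairs.append((a, b) if a <= b else (b, a))

    # --- planted sequence-mosaic pairs (no ECOD domains)
    seq_members: list[tuple[str, str, int, float]] = []
    for i in range(config.n_sequence_mosaic_pairs):
        a, b = take(2)
        lo, hi = config.fragment_length_range
        frag = int(rng.integers(lo, hi + 1))
        centre = config.identity_by_age[i % len(config.identity_by_age)]
        p_id = float(np.clip(centre + rng.normal(0, 0.01), 0.30, 0.99))
        seq_members.append((a, b, frag, p_id))
        key = (a, b) if a <= b else (b, a)
        sequence_pairs.append(
            SequencePairTruth(key[0], key[1], p_id, recency_tier(p_id), frag)
        )

    # --- planted families (cliques); members share one fresh architecture
    family_groups: list[set[str]] = []
    fam_arch: list[list[str]] = []
    for _ in range(config.n_families):
        lo, hi = config.family_size_range
        size = int(rng.integers(lo, hi + 1))
        members = take(size)
        family_groups.append(set(members))
        n_dom = 1 + int(rng.integers(0, 2))
        arch = [universe.new_t() for _ in range(n_dom)]
        fam_arch.append(arch)
        for m in members:
            true_arch[m] = list(arch)

    # --- background rHMMs: each distinct background architecture draws its
    # own fresh T-groups so no two distinct architectures share a T-group
    # (identical architectures may recur — they can never form mosaic pairs)
    background = rhmms[cursor:]
    bg_archs: list[list[str]] = []
    sizes = 1 + rng.choice(
        len(config.architecture_size_probs),
        size=len(background),
        p=config.architecture_size_probs,
    )
    for r, size in zip(background, sizes):
        if bg_archs and rng.random() < 0.3:
            arch = bg_archs[int(rng.integers(0, len(bg_archs)))]
        else:
            arch = [universe.new_t() for _ in range(int(size))]
            bg_archs.append(arch)
        true_arch[r] = list(arch)

    # --- protein lengths and ECOD hit table
    lengths: dict[str, int] = {}
    layouts: dict[str, list[tuple[str, int, int]]] = {}
    seq_pair_ids = {x for a, b, _, _ in seq_members for x in (a, b)}
    for fam_members, arch in zip(family_groups, fam_arch):
        # family members share a length so full-length hits have coverage 1
        plen, layout = _place_domains(rng, arch, universe.lengths)
        for m in sorted(fam_members):
            lengths[m] = plen
            layouts[m] = layout
    for r in rhmms:
        if r in lengths:
            continue
        if r in seq_pair_ids:
            continue  # assigned below, driven by fragment length
        plen, layout = _place_domains(rng, true_arch[r], universe.lengths)
        lengths[r] = plen
        layouts[r] = layout
    for a, b, frag, _ in seq_members:
        for x in (a, b):
            # fragment must cover <= 50%: pad beyond twice the fragment
            lengths[x] = 2 * frag + int(rng.integers(20, 61))
            layouts[x] = []

    ecod_hits: list[AlignmentHit] = []
    for r in rhmms:
        for t_id, q_start, q_end in layouts[r]:
            if config.domain_dropout_rate > 0 and rng.random() < config.domain_dropout_rate:
                continue
            jitter = (
                abs(rng.normal(0, config.probability_jitter_sd))
                if config.probability_jitter_sd > 0
                else 0.0
            )
            dlen = universe.lengths[t_id]
            ecod_hits.append(
                AlignmentHit(
                    query_id=r,
                    subject_id=f"d{t_id}",
                    probability=_clip_prob(0.99 - jitter),
                    percent_identity=0.30,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=1,
                    s_end=dlen,
                    q_len=lengths[r],
                    s_len=dlen,
                    search_tag="ecod",
                )
            )

    # --- self-search hit table
    self_hits: list[AlignmentHit] = []

    def reciprocal(a: str, b: str, qa: tuple[int, int], qb: tuple[int, int],
                   p: float, p_id: float) -> None:
        self_hits.append(
            AlignmentHit(a, b, p, p_id, qa[0], qa[1], qb[0], qb[1],
                         lengths[a], lengths[b], "self")
        )
        self_hits.append(
            AlignmentHit(b, a, p, p_id, qb[0], qb[1], qa[0], qa[1],
                         lengths[b], lengths[a], "self")
        )

    for members in family_groups:
        ordered = sorted(members)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                reciprocal(a, b, (1, lengths[a]), (1, lengths[b]), 0.99, 0.90)

    for a, b, frag, p_id in seq_members:
        qa_start = int(rng.integers(1, lengths[a] - frag + 2))
        qb_start = int(rng.integers(1, lengths[b] - frag + 2))
        reciprocal(
            a, b,
            (qa_start, qa_start + frag - 1),
            (qb_start, qb_start + frag - 1),
            0.99, p_id,
        )

    if config.spurious_hit_rate > 0:
        n_spurious = rng.binomial(n, config.spurious_hit_rate)
        for _ in range(int(n_spurious)):
            a, b = (rhmms[int(i)] for i in rng.choice(n, size=2, replace=False))
            frag = int(rng.integers(20, 40))
            qa = int(rng.integers(1, max(2, lengths[a] - frag)))
            qb = int(rng.integers(1, max(2, lengths[b] - frag)))
            # low-probability background noise, below the strict threshold
            reciprocal(a, b, (qa, qa + frag - 1), (qb, qb + frag - 1), 0.60, 0.20)

    # --- functional classes, PHROG map and hit table
    entries: dict[str, PhrogEntry] = {}
    for cls, category in config.class_labels:
        for v in (1, 2):
            name = f"{cls} variant {v}"
            entries[name] = PhrogEntry(name, cls, category, 400)
    fmap = FunctionMap(entries=entries)

    class_names = [c for c, _ in config.class_labels]
    classes: dict[str, str] = {}
    phrog_hits: list[AlignmentHit] = []
    for r in rhmms:
        cls = class_names[int(rng.integers(0, len(class_names)))]
        classes[r] = cls
        variant = f"{cls} variant {1 + int(rng.integers(0, 2))}"
        phrog_hits.append(
            AlignmentHit(
                query_id=r,
                subject_id=variant,
                probability=0.99,
                percent_identity=0.50,
                q_start=1,
                q_end=lengths[r],
                s_start=1,
                s_end=lengths[r],
                q_len=lengths[r],
                s_len=lengths[r],
                search_tag="phrog",
            )
        )

    antidefence_hits: list[AlignmentHit] = []
    anti_ids = rhmms[: config.n_antidefence_rhmms]
    for r in anti_ids:
        classes[r] = "anti-restriction"
        antidefence_hits.append(
            AlignmentHit(
                query_id=r,
                subject_id="anti-restriction",
                probability=0.98,
                percent_identity=0.40,
                q_start=1,
                q_end=lengths[r],
                s_start=1,
                s_end=lengths[r],
                q_len=lengths[r],
                s_len=lengths[r],
                search_tag="antidefence",
            )
        )

    # --- genome metadata
    host_pool = ["Klebsiella", "Escherichia", "Bacillus", "Lactococcus", "Gordonia", None]
    family_pool = ["Straboviridae", "Autographiviridae", "Drexlerviridae", None]
    genus_pool = [f"genus{i}" for i in range(6)] + [None]
    genome_ids = [f"g{i:04d}" for i in range(config.n_genomes)]
    genome_attrs = {}
    for g in genome_ids:
        tp_kind = rng.random()
        if tp_kind < 0.35:
            tp: Optional[float] = float(rng.uniform(0.90, 1.0))
        elif tp_kind < 0.70:
            tp = float(rng.uniform(0.0, 0.10))
        elif tp_kind < 0.9:
            tp = float(rng.uniform(0.2, 0.8))
        else:
            tp = None
        genome_attrs[g] = (
            host_pool[int(rng.integers(0, len(host_pool)))],
            family_pool[int(rng.integers(0, len(family_pool)))],
            genus_pool[int(rng.integers(0, len(genus_pool)))],
            tp,
        )
    records: list[ProteinRecord] = []
    counter = 0
    for r in rhmms:
        for _ in range(1 + int(rng.integers(0, 3))):
            g = genome_ids[int(rng.integers(0, len(genome_ids)))]
            host, fam, genus, tp = genome_attrs[g]
            records.append(
                ProteinRecord(
                    genome_id=g,
                    protein_id=f"p{counter:06d}",
                    rhmm_id=r,
                    host_genus=host,
                    ictv_family=fam,
                    ictv_genus=genus,
                    temperate_probability=tp,
                )
            )
            counter += 1
    metadata = GenomeMetadata(records=records)

    singleton_members = set(rhmms) - {m for g in family_groups for m in g}
    partition = FamilyPartition.from_groups(
        family_groups + [{m} for m in sorted(singleton_members)]
    )
    truth = TruthSet(
        architectures={r: frozenset(true_arch[r]) for r in rhmms},
        classes=classes,
        family_partition=partition,
        ecod_pairs=sorted(ecod_pairs),
        sequence_pairs=sorted(sequence_pairs, key=lambda s: s.pair),
    )
    return Bundle(
        config=config,
        self_hits=self_hits,
        ecod_hits=ecod_hits,
        phrog_hits=phrog_hits,
        antidefence_hits=antidefence_hits,
        ecod_map=dict(universe.map),
        function_map=fmap,
        metadata=metadata,
        truth=truth,
        protein_lengths=lengths,
    )


def write_bundle(bundle: Bundle, out_dir: Path | str) -> None:
    """Write the full input bundle (and truth) into a directory as TSV/YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_hit_table(bundle.self_hits, out / "self_hits.tsv")
    write_hit_table(bundle.ecod_hits, out / "ecod_hits.tsv")
    write_hit_table(bundle.phrog_hits, out / "phrog_hits.tsv")
    write_hit_table(bundle.antidefence_hits, out / "antidefence_hits.tsv")
    write_ecod_map(bundle.ecod_map, out / "ecod_map.tsv")
    write_function_map(bundle.function_map, out / "function_map.tsv")
    write_metadata(bundle.metadata, out / "metadata.tsv")
    cfg = dataclasses.asdict(bundle.config)
    # YAML-friendly scalars only
    for k, v in cfg.items():
        if isinstance(v, tuple):
            cfg[k] = list(v) if not v or not isinstance(v[0], tuple) else [list(x) for x in v]
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")
    truth = {
        "ecod_pairs": [list(p) for p in bundle.truth.ecod_pairs],
        "sequence_pairs": [
            {"pair": list(s.pair), "p_id": s.p_id, "tier": s.tier.name,
             "fragment_len": s.fragment_len}
            for s in bundle.truth.sequence_pairs
        ],
        "families": {
            str(fid): sorted(members)
            for fid, members in bundle.truth.family_partition.families.items()
        },
        "classes": bundle.truth.classes,
        "architectures": {r: sorted(t) for r, t in bundle.truth.architectures.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True), encoding="utf-8")


def write_fasta_stub(bundle: Bundle, path: Path | str) -> None:
    """Placeholder FASTA for interface tests: one record per rHMM with a
    poly-alanine sequence of the protein's length (the generator is
    table-based and does not model amino-acid content)."""
    with open(path, "w", encoding="utf-8") as handle:
        for rid in sorted(bundle.protein_lengths):
            seq = "A" * bundle.protein_lengths[rid]
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                handle.write(seq[i:i + 60] + "\n")


@dataclass(frozen=True)
class RecoveryReport:
    ecod_precision: float
    ecod_recall: float
    sequence_precision: float
    sequence_recall: float
    family_ari: float
    n_ecod_true: int
    n_sequence_true: int


def _pr(predicted: set[tuple[str, str]], truth: set[tuple[str, str]]) -> tuple[float, float]:
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def score_recovery(
    ecod_calls: Iterable[MosaicCall],
    sequence_calls: Iterable[MosaicCall],
    partition: FamilyPartition,
    truth: TruthSet,
) -> RecoveryReport:
    """Precision/recall of mosaic-pair detection and ARI of the family
    partition against the planted truth (unordered pairs throughout)."""
    pred_ecod = {c.pair for c in ecod_calls}
    pred_seq = {c.pair for c in sequence_calls}
    true_ecod = set(truth.ecod_pairs)
    true_seq = {s.pair for s in truth.sequence_pairs}
    ep, er = _pr(pred_ecod, true_ecod)
    sp, sr = _pr(pred_seq, true_seq)
    order = sorted(truth.family_partition.member_to_family)
    ari = float(
        adjusted_rand_score(
            truth.family_partition.labels(order), partition.labels(order)
        )
    )
    return RecoveryReport(
        ecod_precision=ep,
        ecod_recall=er,
        sequence_precision=sp,
        sequence_recall=sr,
        family_ari=ari,
        n_ecod_true=len(true_ecod),
        n_sequence_true=len(true_seq),
    )
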