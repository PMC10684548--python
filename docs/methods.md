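# Methods

This note documents the model and procedure implemented by `phagemosaic`,
the parameters that matter, the numerical choices made where the published
descriptions leave room, and what the synthetic benchmark does and does not
establish.

## Units and inputs

The pipeline's atomic unit is the rHMM: one representative HMM profile per
protein cluster.  All inputs are tab-separated text tables of directional
local profile–profile hits, each carrying a hit probability, a percent
identity, 1-based inclusive aligned coordinates on query and subject, and
the two full sequence lengths.  Probabilities and identities are stored as
fractions in [0, 1]; hhsuite-style percent values are converted at parse
time.  Coordinates are never converted anywhere downstream.

Three searches feed the analysis: rHMM-vs-rHMM (self), rHMM-vs-ECOD
(domains) and rHMM-vs-PHROG plus an antidefence database (function).  An
ECOD id table maps domain subjects to X.H.T lineages; a function map
collapses PHROG labels into simplified functional classes; a metadata table
ties proteins to genomes, hosts, ICTV taxa and a temperate probability.

## Pair aggregation

HMM–HMM alignment is non-commutative, so each pair is searched both ways.
Aggregation is conservative by design:

* per direction, the probability is the mean of per-residue probabilities
  over that direction's query residues, where a residue covered by several
  HSPs takes the **maximum** probability among them.  The published
  description does not say how overlapping hits combine; the per-residue
  maximum is the least destructive reading of "probability assigned to each
  residue" and is validated against a brute-force per-residue array in the
  tests;
* per direction, identity is the alignment-length-weighted mean over HSPs
  (the multi-HSP case is unspecified in print; the choice is recorded here
  so it can be revisited — the single-best-hit alternative differs only
  for multi-HSP pairs);
* the pair-level `p` and `p_id` are minima over the non-empty directions.
  Pairs detected in only one direction are allowed, as happens in practice
  with asymmetric profile searches;
* coverage of each sequence counts the union of its aligned residues from
  **both** directions, making `qcov`/`scov` symmetric and
  direction-order-free; `cov_min`/`cov_max` are their min and max.

Two threshold contexts exist side by side and are never mixed: the
permissive context aggregates all hits with `p ≥ 0.5` (the homology
background), the strict context only hits with `p ≥ 0.95`.  They are kept
as separate immutable records rather than one mutable one.

## Annotation

A PHROG or antidefence hit qualifies at probability ≥ 0.95 and pairwise
coverage `min(qcov, scov) ≥ 0.8`.  The coverage merge for annotation is the
same `min` used elsewhere; "80% coverage" alone does not pin down the merge,
and `min` is the stricter reading.  Qualifying hits vote with their
simplified classes: exactly one non-generic class wins; the generic
catch-all labels *tail* and *structural protein* (a configurable set) are
tolerated alongside a specific class; two or more non-generic classes
discard the rHMM as ambiguous; generic-only evidence assigns the generic
class; no qualifying hit leaves the rHMM unknown.  A qualifying antidefence
hit overrides the class **only in the presence of qualifying PHROG
evidence**, mirroring the requirement that antidefence labels attach to
proteins that also look like phage proteins.

Domains require `p ≥ 0.95` and subject coverage `scov ≥ 0.7` (coverage of
the ECOD profile, not the rHMM).  An architecture is the set of T-groups;
multiplicity and order are ignored for identity, while the along-sequence
layout is retained for display.  H-group and T-group analyses share one
code path parameterised by level.

Class-level statistics only use classes backed by ≥ 500 PHROG sequences and
≥ 20 annotated rHMMs.  The class × domain presence matrix zeroes cells
below 5 rHMMs and can restrict to domains present in ≥ 3 classes.

## Mosaicism

The ECOD-based predicate is described in the README.  One reading issue is
settled here: "at least two distinct domains" is interpreted as at least
two distinct **X-groups** per side, reading the multi-domain floor jointly
with the unrelated-domain requirement; two T-groups from one X-group do not
qualify.  Self-pairs can never satisfy the predicate.

For the sequence-based predicate, the fragment length criterion (≥ 50 aa)
is applied to the **minimum** of the two sides' union-aligned residue
counts — the conservative choice, since the printed definition does not
name a side.  The permissive-background comparison is mandatory; calling
without it is an error rather than a silent pass.

Recency tiers from fragment identity: ≥ 0.5 contemporary, ≥ 0.7
high-confidence recent, ≥ 0.9 very-high-confidence recent, all inclusive.
An rHMM has a mosaic signal for a basis if it appears in at least one call
of that basis; a family is mosaic if any member has the signal.

## Families

Edges require `p ≥ 0.95` and `cov_min ≥ 0.8`; the weight is `p × cov_min`.
The in-package MCL adds a self-loop to every node with its maximum incident
weight (1 for isolated nodes), column-normalises, and alternates expansion
(matrix squaring) with inflation (entrywise square, renormalise), pruning
entries below 1e-6, until the matrix changes by less than 1e-8 or 100
iterations (non-convergence warns and clusters the current state).
Clusters are read from attractor rows; a node claimed by several attractors
goes to the one holding most of its mass, ties to the lowest attractor
index in sorted node order.  Connected components are clustered
independently — MCL can split but never merge them — which bounds the dense
matrices and makes large sparse inputs tractable.  Tests compare the
implementation against an unpruned dense re-implementation on random
graphs; the pruning threshold is small enough that the two have agreed on
every graph tried.  Family ids are assigned by each family's smallest
member, so labels are deterministic and node-order-free.

## Enrichment and networks

The odds ratio is `OR = (a/b)/(c/d)`; zero cells follow the natural limits
(0 or +infinity, no continuity correction) since the Fisher p-value remains
well-defined regardless.  Significance uses one-tailed ("greater") Fisher
exact tests via `scipy.stats.fisher_exact`, with Bonferroni multiplicity
equal to the number of features actually tested — domains occurring in at
least one architecture, or eligible classes.  The per-domain design counts
**unique architectures** (not rHMMs), flagging an architecture as mosaic
when any rHMM bearing it participates in an ECOD-basis call; restricting
the calls to contemporary tiers gives the contemporary variant of the same
test.  The per-class design counts families, restricted to families
containing at least one eligible-class rHMM, and runs once per basis
combination (ECOD alone; ECOD or sequence).

The mosaic class network links two classes (self-loops allowed) when calls
connect ≥ 4 distinct unordered architecture pairs between them; an edge is
contemporary if one supporting pair has fragment identity ≥ 0.5.  The
recently-emerged network is built from individual sequence-basis pairs at a
tier floor, with unannotated rHMMs mapped to an explicit "unknown" node.

## Ecology

Lifestyle: temperate at temperate probability ≥ 0.90, virulent at ≤ 0.10,
both inclusive exactly as printed; the probability itself is an input
column (its upstream predictor is out of scope).  Group assignment along
any axis ignores null members, requires unanimity among the rest, and
otherwise marks the rHMM conserved-across-groups.  Per-genome mosaic
fractions count proteins whose rHMM carries either signal over proteins
with an rHMM; a genome with none is reported missing, not zero.
Cross-boundary labels stratify calls at fragment identity 0.7.

## Synthetic data

The generator emulates the three searches with planted truth.  Default
conditions: 200 rHMMs, 20 ECOD-mosaic pairs, 20 sequence-mosaic pairs, 15
multi-member families (sizes 2–5), the rest singletons, ~10 functional
classes with two PHROG variants each, 40 genomes, noiseless.  Domain
lengths are 80–160 aa with 10–30 aa linkers; planted fragments are 60–120
aa in proteins padded beyond twice the fragment length so background
coverage stays ≤ 0.5; fragment identities cycle through age classes
centred at 0.35/0.55/0.75/0.95 to exercise every tier.  These sizes keep a
full pipeline run under a second while leaving every code path exercised.

Structural guarantees: each planted ECOD pair draws its shared and unique
X-groups from a reserved block, and distinct background architectures never
share a T-group, so on noiseless output no unplanted pair can satisfy
either predicate and precision is structurally 1.  Unrelated pairs emit no
hits at all; an optional spurious-hit rate adds sub-threshold background
fragments.  Noise enters as independent per-domain dropout (an ECOD call on
two-domain-per-side pairs then needs four detections, so recall approaches
`(1-d)^4`) and Gaussian downward probability jitter.  One
`numpy.random.default_rng(seed)` stream drives everything; no global RNG
state is touched, and equal seeds give byte-identical written bundles.

What the benchmark does **not** emulate: real sequence evolution (identity
is drawn, not evolved), uneven ECOD coverage across functional classes,
partial/overlapping domain hits, sub-domain mosaicism, or the long
repetitive regions that make e.g. tape-measure proteins prone to spurious
sequence signals.  Passing tests therefore establish correctness of the
computation, not detection power on real proteomes.

Recovery is scored as precision/recall over unordered pairs per basis and
as the adjusted Rand index of the family partition
(`sklearn.metrics.adjusted_rand_score`) against the planted one.

## Degenerate inputs and errors

Empty hit lists for a per-residue statistic raise a distinct error rather
than returning 0; a pair with both directions empty is an error; empty
architectures are valid and excluded from domain analyses; a contingency
table of all zeros is rejected; proteins mapped to two rHMMs, hits naming
unmapped PHROG classes or ECOD subjects, and mosaic signals on rHMMs absent
from a partition all fail loudly with the offending record named.

## Known limitations

The implementation deliberately reproduces printed thresholds as inclusive
bounds; datasets produced with other conventions need re-thresholding
upstream.  The per-direction identity of multi-HSP pairs is a weighted
mean (see above).  Bonferroni multiplicity equals features tested, which
may differ from sample-size figures quoted alongside published tests.  MCL
parameters (loop weight, pruning) are exposed because upstream defaults of
the original command-line tool cannot be recovered from text descriptions.
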