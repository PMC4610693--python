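"""Pairwise identity and greedy incremental clustering (cd-hit semantics).

Sequences are sorted by decreasing length; the longest founds the first
cluster and becomes its representative.  Each subsequent sequence is
compared against existing representatives and joins the first
(``first_fit``, the de novo default) or the best (``best_fit``)
representative whose identity reaches the threshold, otherwise it founds
a new cluster.  Identity is the number of identical aligned bases in the
optimal global alignment divided by the length of the shorter sequence
(cd-hit's convention) or, optionally, by the number of alignment
columns.

No k-mer heuristic is used; every undecided pair is aligned.  An
optional edit-distance pre-filter skips only pairs it can *prove* fall
below the threshold: for edit distance ``d`` and length difference
``D``, any alignment of the pair has at most
``shorter - max(0, d - D)/2`` matches, so identity is at most
``1 - max(0, d - D)/(2 * shorter)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import edlib

from . import _align
from .seqio import ReferenceLibrary, SequenceRecord

_EPS = 1e-9


@dataclass(frozen=True)
class IdentityParams:
    """Alignment scoring for percent-identity computation.

    Defaults are the de facto nucleotide (BLASTN-like) settings:
    match +2, mismatch 3, gap open 5, gap extend 2, with a gap of
    length L costing ``gap_open + gap_extend * L``.
    """

    match_score: int = 2
    mismatch_penalty: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    denominator: str = "shorter_sequence"

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if min(self.mismatch_penalty, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be >= 0")
        if self.denominator not in ("shorter_sequence", "alignment_columns"):
            raise ValueError(f"unknown denominator {self.denominator!r}")


DEFAULT_PARAMS = IdentityParams()


def pairwise_identity(a: str, b: str, params: IdentityParams = DEFAULT_PARAMS) -> float:
    """Fraction of identical aligned bases under the optimal global
    alignment; symmetric in its arguments."""
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    if a == b and "N" not in a:  # N never counts as a match
        return 1.0
    _score, matches, cols = _align.global_stats(
        a, b, params.match_score, params.mismatch_penalty,
        params.gap_open, params.gap_extend,
    )
    denom = min(len(a), len(b)) if params.denominator == "shorter_sequence" else cols
    return matches / denom


def provably_below(a: str, b: str, threshold: float) -> bool:
    """True when the edit-distance bound proves identity(a, b) < threshold."""
    d = edlib.align(a, b, task="distance")["editDistance"]
    la, lb = sorted((len(a), len(b)))
    bound = 1.0 - max(0, d - (lb - la)) / (2.0 * la)
    return bound < threshold - _EPS


@dataclass
class Cluster:
    """One representative-led cluster; members are (id, identity-to-rep)."""

    index: int
    representative: str
    members: list[tuple[str, float]] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [m for m, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """A partition of the input sequences at a stated threshold."""

    threshold: float
    clusters: list[Cluster]
    params: IdentityParams
    lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_ids(self) -> list[str]:
        return [m for cl in self.clusters for m in cl.member_ids]

    def validate_partition(self, expected_ids: set[str]) -> None:
        ids = self.member_ids()
        if len(ids) != len(set(ids)) or set(ids) != expected_ids:
            raise AssertionError("cluster set is not a partition of the input ids")


IdentityFn = Callable[[SequenceRecord, SequenceRecord], float]


def greedy_cluster(
    records: Sequence[SequenceRecord],
    threshold: float,
    params: IdentityParams = DEFAULT_PARAMS,
    mode: str = "first_fit",
    prefilter: bool = True,
    identity_fn: IdentityFn | None = None,
) -> ClusterSet:
    """Greedy incremental clustering at an identity threshold.

    Processing order is decreasing length, ties broken by ascending id.
    ``identity_fn`` may be supplied to memoize identities across repeated
    sweeps; it disables the pre-filter.
    """
    if not records:
        raise ValueError("cannot cluster an empty record list")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if mode not in ("first_fit", "best_fit"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("record ids must be unique")

    if identity_fn is None:
        def identity_fn_(rec: SequenceRecord, rep: SequenceRecord) -> float:
            if prefilter and provably_below(rec.residues, rep.residues, threshold):
                return 0.0
            return pairwise_identity(rec.residues, rep.residues, params)
    else:
        identity_fn_ = identity_fn

    order = sorted(records, key=lambda r: (-len(r.residues), r.id))
    clusters: list[Cluster] = []
    reps: list[SequenceRecord] = []
    for rec in order:
        best_idx = -1
        best_ident = -1.0
        for idx, rep in enumerate(reps):
            ident = identity_fn_(rec, rep)
            if ident >= threshold - _EPS:
                if mode == "first_fit":
                    best_idx, best_ident = idx, ident
                    break
                if ident > best_ident + _EPS:
                    best_idx, best_ident = idx, ident
        if best_idx >= 0:
            clusters[best_idx].members.append((rec.id, best_ident))
        else:
            clusters.append(
                Cluster(index=len(clusters), representative=rec.id,
                        members=[(rec.id, 1.0)])
            )
            reps.append(rec)

    return ClusterSet(
        threshold=threshold,
        clusters=clusters,
        params=params,
        lengths={r.id: len(r) for r in records},
    )


def cluster_against_reference(
    queries: Sequence[SequenceRecord],
    reference: ReferenceLibrary,
    threshold: float,
    params: IdentityParams = DEFAULT_PARAMS,
    prefilter: bool = True,
) -> tuple[dict[str, tuple[str, float]], list[str]]:
    """Assign each query to its best-identity reference species.

    Reference-guided (cd-hit-est-2d-like) assignment: a query matches the
    reference species with the highest identity >= threshold (ties go to
    the earliest reference record); otherwise it is reported unmatched.
    Results are memoized per distinct query sequence.
    """
    if len(reference) == 0:
        raise ValueError("reference library is empty")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")

    cache: dict[str, tuple[str, float] | None] = {}
    matched: dict[str, tuple[str, float]] = {}
    unmatched: list[str] = []
    for query in queries:
        seq = query.residues
        if seq in cache:
            hit = cache[seq]
        else:
            best: tuple[str, float] | None = None
            best_ident = -1.0
            for ref in reference.records:
                if seq != ref.residues and prefilter and provably_below(
                    seq, ref.residues, threshold
                ):
                    continue
                ident = pairwise_identity(seq, ref.residues, params)
                if ident >= threshold - _EPS and ident > best_ident + _EPS:
                    best = (reference.species_of(ref.id), ident)
                    best_ident = ident
                    if ident >= 1.0:
                        break
            cache[seq] = best
            hit = best
        if hit is None:
            unmatched.append(query.id)
        else:
            matched[query.id] = hit
    return matched, unmatched
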