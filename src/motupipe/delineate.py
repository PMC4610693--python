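"""Similarity-threshold optimization for species delineation.

Given a reference library with one sequence per species, a species is
*resolved* at a threshold when its sequence sits alone in a singleton
cluster; species sharing a multi-member cluster cannot be told apart by
that threshold.  The sweep clusters homopolymer-capped variants of the
library over a grid of thresholds (mirroring the 5-/4-/3-/2-mer library
experiment) and the optimal threshold maximizes the resolved fraction,
with ties going to the lowest (most merge-tolerant) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .cluster import DEFAULT_PARAMS, ClusterSet, IdentityParams, greedy_cluster, pairwise_identity
from .homopolymer import cap_records
from .seqio import ReferenceLibrary, SequenceRecord

#: The sweep grid used throughout: 97-100% thresholds, caps from none down to 2.
DEFAULT_THRESHOLDS = (0.97, 0.98, 0.99, 1.00)
DEFAULT_CAPS: tuple[int | None, ...] = (None, 5, 4, 3, 2)


@dataclass
class ResolutionReport:
    """How many species a clustering resolves to singletons."""

    n_species: int
    n_clusters: int
    n_singletons: int
    resolved_fraction: float
    unresolved: list[tuple[int, list[str]]]


@dataclass
class SweepResult:
    """Cluster counts over the (threshold, cap) grid; cap ``None`` means
    the unmodified library."""

    thresholds: tuple[float, ...]
    caps: tuple[int | None, ...]
    grid: dict[tuple[float, int | None], int]
    cluster_sets: dict[tuple[float, int | None], ClusterSet] = field(default_factory=dict)


def resolution_metrics(
    clusters: ClusterSet, taxonomy: Mapping[str, str]
) -> ResolutionReport:
    """Per-cluster species accounting; *taxonomy* maps sequence id to
    species (one sequence per species expected)."""
    species_seen: set[str] = set()
    unresolved: list[tuple[int, list[str]]] = []
    n_singletons = 0
    for cl in clusters.clusters:
        names = []
        for member_id in cl.member_ids:
            if member_id not in taxonomy:
                raise ValueError(f"sequence {member_id!r} has no species label")
            names.append(taxonomy[member_id])
        species_seen.update(names)
        if len(cl) == 1:
            n_singletons += 1
        else:
            unresolved.append((cl.index, sorted(names)))
    n_species = len(species_seen)
    resolved = n_species - sum(len(names) for _idx, names in unresolved)
    return ResolutionReport(
        n_species=n_species,
        n_clusters=clusters.n_clusters,
        n_singletons=n_singletons,
        resolved_fraction=resolved / n_species,
        unresolved=unresolved,
    )


def threshold_sweep(
    library: ReferenceLibrary,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    caps: Sequence[int | None] = DEFAULT_CAPS,
    params: IdentityParams = DEFAULT_PARAMS,
    keep_clusters: bool = False,
) -> SweepResult:
    """Cluster each capped variant of the library at every threshold.

    Identities are memoized per cap so the grid costs at most one
    alignment per sequence pair and cap.
    """
    thresholds = tuple(sorted(thresholds))
    caps = tuple(caps)
    grid: dict[tuple[float, int | None], int] = {}
    sets: dict[tuple[float, int | None], ClusterSet] = {}
    for cap in caps:
        records = library.records if cap is None else cap_records(library.records, cap)
        cache: dict[tuple[str, str], float] = {}

        def cached_identity(a: SequenceRecord, b: SequenceRecord) -> float:
            key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
            if key not in cache:
                cache[key] = pairwise_identity(a.residues, b.residues, params)
            return cache[key]

        for t in thresholds:
            cs = greedy_cluster(records, t, params=params, identity_fn=cached_identity)
            grid[(t, cap)] = cs.n_clusters
            if keep_clusters:
                sets[(t, cap)] = cs
    return SweepResult(thresholds=thresholds, caps=caps, grid=grid, cluster_sets=sets)


def pick_threshold(
    sweep: SweepResult, reports: Mapping[float, ResolutionReport]
) -> float:
    """The threshold maximizing the resolved fraction (ties: lowest)."""
    if not reports:
        raise ValueError("no resolution reports given")
    missing = set(sweep.thresholds) - set(reports)
    if missing:
        raise ValueError(f"reports missing for thresholds {sorted(missing)}")
    return min(
        reports,
        key=lambda t: (-reports[t].resolved_fraction, t),
    )


def plot_sweep(sweep: SweepResult, ax=None):
    """Cluster counts vs threshold, one line per homopolymer cap."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    for cap in sweep.caps:
        label = "uncapped" if cap is None else f"{cap}-mer"
        ys = [sweep.grid[(t, cap)] for t in sweep.thresholds]
        ax.plot([t * 100 for t in sweep.thresholds], ys, marker="o", label=label)
    ax.set_xlabel("similarity threshold (%)")
    ax.set_ylabel("number of clusters")
    ax.legend(title="homopolymer cap")
    return ax
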