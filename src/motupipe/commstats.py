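"""Community summaries, reproducibility correlations and detection accounting.

Technical-replicate (aliquot) reproducibility and covariate effects
(input DNA concentration, GC content) are measured with Spearman's rank
correlation on per-species read counts; species detection against a
known pooled community is reported as set differences with a
configurable minimum read support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .assign import AssignmentTable


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); N is excluded from both counts."""
    if not seq:
        raise ValueError("GC content of an empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("GC content undefined: sequence is all N")
    return (counts["G"] + counts["C"]) / total


def _midranks(values: Sequence[float]) -> np.ndarray:
    return stats.rankdata(values, method="average")


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    ``method="t"`` uses the usual t-approximation with n-2 degrees of
    freedom; ``method="exact"`` enumerates all permutations (two-sided,
    n <= 8 only) for small samples.
    """
    x = list(x)
    y = list(y)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("Spearman correlation needs at least 3 observations")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("Spearman correlation is undefined for a constant vector")
    if method == "t":
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    if method == "exact":
        if len(x) > 8:
            raise ValueError("exact permutation p-value supported for n <= 8 only")
        rx = _midranks(x) - (len(x) + 1) / 2
        ry = _midranks(y) - (len(y) + 1) / 2
        denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
        rho = float(rx @ ry / denom)
        hits = 0
        total = 0
        for perm in permutations(ry):
            r = float(rx @ np.asarray(perm) / denom)
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
            total += 1
        return rho, hits / total
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ReadProfile:
    """Per-species read counts of one sample over a fixed species domain
    (zeros kept for undetected library species)."""

    label: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("read counts must be >= 0")

    @property
    def species(self) -> set[str]:
        return set(self.counts)

    @classmethod
    def from_assignment(
        cls, assignments: "AssignmentTable", species_domain: Sequence[str], label: str
    ) -> "ReadProfile":
        counts = {sp: 0 for sp in species_domain}
        for sp, n in assignments.per_species.items():
            if sp not in counts:
                raise ValueError(f"assigned species {sp!r} outside the given domain")
            counts[sp] = n
        return cls(label=label, counts=counts)


def profile_correlation(a: ReadProfile, b: ReadProfile, method: str = "t") -> tuple[float, float]:
    """Spearman correlation of two samples' per-species read counts."""
    if a.species != b.species:
        raise ValueError("profiles cover different species domains")
    order = sorted(a.species)
    return spearman([a.counts[s] for s in order], [b.counts[s] for s in order], method=method)


def covariate_correlation(
    profile: ReadProfile, covariate: Mapping[str, float], method: str = "t"
) -> tuple[float, float]:
    """Spearman correlation of read counts against a per-species covariate
    (e.g. input DNA concentration or GC content)."""
    missing = profile.species - set(covariate)
    if missing:
        raise ValueError(f"covariate missing for species: {sorted(missing)[:5]}")
    order = sorted(profile.species)
    return spearman(
        [profile.counts[s] for s in order], [covariate[s] for s in order], method=method
    )


@dataclass
class DetectionReport:
    """Detected vs expected species of a sample with known composition."""

    truth: set[str]
    detected: set[str]
    missed: set[str]
    unexpected: set[str]
    detection_rate: float


def detection_report(
    assignments: "AssignmentTable", truth: set[str], min_reads: int = 1
) -> DetectionReport:
    """Count a species as detected when it has >= *min_reads* assigned
    reads; missed and unexpected species are plain set differences."""
    truth = set(truth)
    detected = {sp for sp, n in assignments.per_species.items() if n >= min_reads}
    return DetectionReport(
        truth=truth,
        detected=detected,
        missed=truth - detected,
        unexpected=detected - truth,
        detection_rate=len(truth & detected) / len(truth) if truth else 1.0,
    )
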