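"""Three-rule read rejection and primer trimming for pyrosequencing reads.

A read is discarded when (1) its mean Phred quality is below the
threshold, (2) its prefix has more than the allowed number of mismatches
against the forward primer, or (3) after primer trimming it is shorter
than the minimum length.  Rules are applied in that order and each read
receives at most one rejection reason.  Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .seqio import SequenceRecord, reverse_complement

#: Rejection reasons, in rule order.
LOW_QUALITY = "low_quality"
PRIMER_MISMATCH = "primer_mismatch"
TOO_SHORT = "too_short"


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the three filtering rules.

    ``forward_primer`` is matched (Hamming, anchored at position 0)
    against the read prefix and trimmed from kept reads; ``None``
    disables the primer rule (e.g. for re-filtering already trimmed
    reads).  If ``reverse_primer`` is given its reverse complement is
    looked for at the 3' end and trimmed when found, but its absence is
    not a rejection (many reads end before reaching it).  ``adaptor``,
    when set, is clipped from the 5' end before anything else if present
    verbatim.
    """

    forward_primer: str | None
    reverse_primer: str | None = None
    min_mean_quality: float = 10.0
    max_primer_mismatches: int = 2
    min_length: int = 200
    adaptor: str | None = None

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if self.max_primer_mismatches < 0:
            raise ValueError("max_primer_mismatches must be >= 0")
        if self.forward_primer == "":
            raise ValueError("forward_primer must be non-empty (or None to disable)")


@dataclass
class FilterReport:
    """Outcome of filtering: trimmed kept reads plus per-read reasons."""

    kept: list[SequenceRecord] = field(default_factory=list)
    rejected: dict[str, str] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)


def mean_quality(quality: Sequence[int]) -> float:
    """Arithmetic mean of Phred values."""
    if not quality:
        raise ValueError("mean quality of an empty quality list")
    return sum(quality) / len(quality)


def match_primer(
    read: SequenceRecord, primer: str, max_mm: int
) -> tuple[bool, int, int]:
    """Hamming-compare *primer* against the read prefix.

    Returns ``(found, mismatches, end)`` where ``end`` is the 0-based
    exclusive offset of the primer (= its length).  ``N`` in the read
    counts as a mismatch.  A primer longer than the read is never found.
    """
    if len(primer) > len(read.residues):
        return False, len(primer), len(primer)
    mismatches = sum(
        1
        for p, r in zip(primer, read.residues)
        if r == "N" or p != r
    )
    return mismatches <= max_mm, mismatches, len(primer)


def filter_reads(reads: Sequence[SequenceRecord], params: FilterParams) -> FilterReport:
    """Apply the quality -> primer -> length rules and trim kept reads."""
    report = FilterReport()
    rev_rc = reverse_complement(params.reverse_primer) if params.reverse_primer else None
    for read in reads:
        if read.quality is None:
            raise ValueError(
                f"read {read.id!r} has no quality values; parse reads from FASTQ "
                "or disable the quality rule by providing qualities"
            )
        if mean_quality(read.quality) < params.min_mean_quality:
            report.rejected[read.id] = LOW_QUALITY
            continue

        work = read
        if params.adaptor and work.residues.startswith(params.adaptor):
            n = len(params.adaptor)
            work = replace(
                work,
                residues=work.residues[n:] or "N",
                quality=work.quality[n:] or [0],
            )

        if params.forward_primer is not None:
            if len(params.forward_primer) > len(work.residues):
                report.rejected[read.id] = TOO_SHORT
                continue
            found, _mm, end = match_primer(
                work, params.forward_primer, params.max_primer_mismatches
            )
            if not found:
                report.rejected[read.id] = PRIMER_MISMATCH
                continue
            residues = work.residues[end:]
            quality = work.quality[end:]
        else:
            residues = work.residues
            quality = list(work.quality)

        if rev_rc and len(residues) >= len(rev_rc):
            tail = residues[-len(rev_rc):]
            mm = sum(1 for p, r in zip(rev_rc, tail) if r == "N" or p != r)
            if mm <= params.max_primer_mismatches:
                residues = residues[: -len(rev_rc)]
                quality = quality[: -len(rev_rc)]

        if len(residues) < params.min_length:
            report.rejected[read.id] = TOO_SHORT
            continue
        report.kept.append(replace(read, residues=residues, quality=quality))
    return report
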