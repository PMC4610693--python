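"""Homopolymer run detection, stepwise reduction and run capping.

Pyrosequencing miscalls the length of homopolymer runs (consecutive
identical bases), and the error rate grows with run length.  The
denoising device used here makes reads and reference commensurate by
*capping*: every run longer than ``k`` is replaced by exactly ``k``
copies of its base.  A run of 4 identical bases is already reduced when
capping at 3 — "beyond k-mers" is read as "longer than k".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from itertools import groupby
from typing import Iterable, Sequence

from .seqio import ReferenceLibrary, SequenceRecord


@dataclass(frozen=True)
class Run:
    """A maximal run of identical bases: ``seq[start:start+length]``."""

    base: str
    start: int
    length: int


def find_runs(seq: str) -> list[Run]:
    """Maximal homopolymer runs, left to right; they tile the sequence."""
    if not seq:
        raise ValueError("cannot scan an empty sequence for runs")
    runs = []
    pos = 0
    for base, group in groupby(seq):
        n = sum(1 for _ in group)
        runs.append(Run(base=base, start=pos, length=n))
        pos += n
    return runs


def max_run_length(records: Sequence[SequenceRecord]) -> int:
    """Longest homopolymer run over all sequences in the collection."""
    if not records:
        raise ValueError("max_run_length of an empty record list")
    best = 1
    for rec in records:
        for m in re.finditer(r"(.)\1*", rec.residues):
            n = m.end() - m.start()
            if n > best:
                best = n
    return best


def cap_runs(seq: str, k: int) -> str:
    """Replace every run longer than *k* with exactly *k* copies."""
    if k < 1:
        raise ValueError(f"cap length must be >= 1, got {k}")
    return re.sub(r"(.)\1{%d,}" % k, lambda m: m.group(1) * k, seq)


def cap_record(record: SequenceRecord, k: int) -> SequenceRecord:
    """Cap a record's runs, dropping the quality values of removed bases
    (the first *k* of each run are kept)."""
    if k < 1:
        raise ValueError(f"cap length must be >= 1, got {k}")
    capped = cap_runs(record.residues, k)
    if capped == record.residues:
        return record
    quality = None
    if record.quality is not None:
        quality = []
        for run in find_runs(record.residues):
            keep = min(run.length, k)
            quality.extend(record.quality[run.start:run.start + keep])
    return replace(record, residues=capped, quality=quality)


def cap_records(records: Iterable[SequenceRecord], k: int) -> list[SequenceRecord]:
    return [cap_record(r, k) for r in records]


def cap_library(library: ReferenceLibrary, k: int) -> ReferenceLibrary:
    """A new reference library with every sequence capped at *k*."""
    return ReferenceLibrary(
        records=cap_records(library.records, k),
        taxonomy=dict(library.taxonomy),
    )


def stepwise_reduce(records: Sequence[SequenceRecord], n: int) -> list[SequenceRecord]:
    """Reduce every run of length >= *n* by one base, yielding the
    "(n-1)-mer" library.  Equivalent to capping at ``n - 1``; chaining
    the reduction from n down to k+1 therefore telescopes to a cap at k.
    """
    if n < 2:
        raise ValueError(f"stepwise reduction needs n >= 2, got {n}")
    out = []
    for rec in records:
        capped = cap_record(rec, n - 1)
        tag = f"{n - 1}-mer"
        desc = f"{rec.description} [{tag}]".strip() if rec.description else f"[{tag}]"
        out.append(replace(capped, description=desc))
    return out
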