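import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

settings.register_profile(
    "default",
    settings(
        derandomize=True,
        max_examples=60,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_seq(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def mutate_seq(rng, seq: str, rate: float) -> str:
    out = []
    for base in seq:
        if rng.random() < rate:
            out.append("ACGT"[rng.integers(0, 4)])
        else:
            out.append(base)
    return "".join(out)


def run_rich_seq(rng, length: int = 450, min_run: int = 4, max_run: int = 6) -> str:
    """A sequence whose every homopolymer run has length >= min_run."""
    parts = []
    total = 0
    prev = None
    while total < length:
        choices = [b for b in "ACGT" if b != prev]
        base = choices[rng.integers(0, len(choices))]
        k = int(rng.integers(min_run, max_run + 1))
        parts.append(base * k)
        total += k
        prev = base
    return "".join(parts)


@pytest.fixture
def tiny_library():
    """Five well-separated species with a nested taxonomy, built by hand."""
    from motupipe.seqio import ReferenceLibrary, SequenceRecord, TaxonRecord

    rng = np.random.default_rng(7)
    root = random_seq(rng, 300)
    seqs = [mutate_seq(rng, root, 0.15) for _ in range(5)]
    genera = ["Alpha", "Alpha", "Beta", "Beta", "Gamma"]
    records = []
    taxonomy = {}
    for i, (seq, genus) in enumerate(zip(seqs, genera)):
        species = f"{genus} species{i}"
        ref_id = f"T{i:03d}"
        records.append(SequenceRecord(id=ref_id, residues=seq, description=species))
        taxonomy[species] = TaxonRecord(
            species=species,
            lineage=(
                ("phylum", "Phylum1"),
                ("family", "Famil" + ("yA" if genus in ("Alpha", "Beta") else "yB")),
                ("genus", genus),
                ("species", species),
            ),
            ref_id=ref_id,
        )
    return ReferenceLibrary(records=records, taxonomy=taxonomy)
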