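"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTA, FASTQ (Sanger Phred+33 only), a flat tab-separated
taxonomy table, and a cd-hit ``.clstr``-style cluster report.  All
sequence input is canonicalized at parse time to a single internal
alphabet {A, C, G, T, N}: lowercase is uppercased, U becomes T, and any
other character becomes N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import ClusterSet

#: Taxonomic ranks from most to least inclusive.
RANKS = ("phylum", "subphylum", "class", "order", "family", "genus", "species")

_ALPHABET = frozenset("ACGTN")

_CANON = {i: "N" for i in range(256)}
for _c in "ACGTN":
    _CANON[ord(_c)] = _c
    _CANON[ord(_c.lower())] = _c
_CANON[ord("U")] = "T"
_CANON[ord("u")] = "T"
_CANON_TABLE = str.maketrans({chr(i): v for i, v in _CANON.items()})


class SequenceFormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


def canonicalize(seq: str) -> str:
    """Uppercase, map U->T, and replace anything else with N."""
    return seq.translate(_CANON_TABLE)


@dataclass(slots=True)
class SequenceRecord:
    """One DNA sequence with optional per-base Phred qualities."""

    id: str
    residues: str
    description: str = ""
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        if not set(self.residues) <= _ALPHABET:
            bad = sorted(set(self.residues) - _ALPHABET)
            raise ValueError(f"record {self.id!r}: invalid residues {bad}")
        if self.quality is not None:
            if len(self.quality) != len(self.residues):
                raise ValueError(
                    f"record {self.id!r}: quality length {len(self.quality)} != "
                    f"sequence length {len(self.residues)}"
                )
            if any(q < 0 or q > 93 for q in self.quality):
                raise ValueError(f"record {self.id!r}: Phred values must be in [0, 93]")

    def __len__(self) -> int:
        return len(self.residues)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TaxonRecord:
    """Ranked lineage of one species, tied to its reference sequence."""

    species: str
    lineage: tuple[tuple[str, str], ...]
    ref_id: str

    def __post_init__(self) -> None:
        ranks = [r for r, _ in self.lineage]
        if len(set(ranks)) != len(ranks):
            raise ValueError(f"{self.species!r}: duplicate ranks in lineage")
        order = [RANKS.index(r) for r in ranks]  # raises on unknown rank
        if order != sorted(order):
            raise ValueError(f"{self.species!r}: ranks out of order {ranks}")
        names = dict(self.lineage)
        if names.get("species") != self.species:
            raise ValueError(
                f"{self.species!r}: lineage species entry {names.get('species')!r} "
                "does not match the species field"
            )

    def name_at(self, rank: str) -> str | None:
        return dict(self.lineage).get(rank)


@dataclass
class ReferenceLibrary:
    """Species-labelled sequences plus their ranked taxonomy.

    Exactly one sequence per species; record ids and species names are
    in bijection through ``TaxonRecord.ref_id``.
    """

    records: list[SequenceRecord]
    taxonomy: dict[str, TaxonRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("reference library record ids are not unique")
        ref_ids = [t.ref_id for t in self.taxonomy.values()]
        if len(set(ref_ids)) != len(ref_ids):
            raise ValueError("taxonomy ref_ids are not unique")
        if set(ref_ids) != set(ids):
            raise ValueError(
                "taxonomy and records disagree: every record id must be "
                "referenced by exactly one taxon"
            )
        for sp, t in self.taxonomy.items():
            if t.species != sp:
                raise ValueError(f"taxonomy key {sp!r} != TaxonRecord.species {t.species!r}")
        self._by_id = {r.id: r for r in self.records}
        self._species_by_ref = {t.ref_id: sp for sp, t in self.taxonomy.items()}

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> set[str]:
        return set(self.taxonomy)

    def record(self, ref_id: str) -> SequenceRecord:
        return self._by_id[ref_id]

    def species_of(self, ref_id: str) -> str:
        return self._species_by_ref[ref_id]

    def subset(self, species: Iterable[str]) -> "ReferenceLibrary":
        """A new library restricted to the given species."""
        keep = set(species)
        missing = keep - self.species
        if missing:
            raise KeyError(f"species not in library: {sorted(missing)}")
        tax = {sp: self.taxonomy[sp] for sp in keep}
        ref_ids = {t.ref_id for t in tax.values()}
        recs = [r for r in self.records if r.id in ref_ids]
        return ReferenceLibrary(records=recs, taxonomy=tax)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def parse_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse FASTA; ids are the first whitespace-delimited header token."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise SequenceFormatError(
                    f"{path.name}:{lineno}: expected FASTA header starting with '>'"
                )
            break
        else:
            return []
    records = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            tokens = title.split(None, 1)
            if not tokens:
                raise SequenceFormatError(f"{path.name}: empty FASTA header")
            rid = tokens[0]
            desc = tokens[1] if len(tokens) > 1 else ""
            residues = canonicalize(seq.replace(" ", ""))
            if not residues:
                raise SequenceFormatError(f"{path.name}: record {rid!r} has no residues")
            records.append(SequenceRecord(id=rid, residues=residues, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def parse_fastq(path: str | Path) -> list[SequenceRecord]:
    """Parse 4-line FASTQ with Sanger Phred+33 qualities."""
    path = Path(path)
    records = []
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                tokens = title.split(None, 1)
                rid = tokens[0]
                desc = tokens[1] if len(tokens) > 1 else ""
                quality = [ord(c) - 33 for c in qual]
                records.append(
                    SequenceRecord(
                        id=rid,
                        residues=canonicalize(seq),
                        description=desc,
                        quality=quality,
                    )
                )
        except ValueError as exc:
            raise SequenceFormatError(f"{path.name}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quality is None:
                raise ValueError(f"record {rec.id!r} has no quality; cannot write FASTQ")
            header = f"@{rec.id}" + (f" {rec.description}" if rec.description else "")
            qual = "".join(chr(q + 33) for q in rec.quality)
            fh.write(f"{header}\n{rec.residues}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Taxonomy TSV

_TAX_HEADER = ("ref_id",) + RANKS[:-1] + ("species",)


def parse_taxonomy(path: str | Path) -> dict[str, TaxonRecord]:
    """Parse the flat taxonomy table.

    Tab-separated columns: ref_id, phylum, subphylum, class, order,
    family, genus, species.  ``-`` marks an absent rank, which is then
    omitted from the lineage.  An optional header line (starting with
    ``ref_id``) is skipped.
    """
    path = Path(path)
    taxonomy: dict[str, TaxonRecord] = {}
    ref_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "ref_id":
                continue
            if len(fields) != 8:
                raise SequenceFormatError(
                    f"{path.name}:{lineno}: expected 8 tab-separated columns, got {len(fields)}"
                )
            ref_id = fields[0].strip()
            names = [f.strip() for f in fields[1:]]
            species = names[-1]
            if species in ("", "-"):
                raise SequenceFormatError(f"{path.name}:{lineno}: missing species name")
            if species in taxonomy:
                raise SequenceFormatError(f"{path.name}:{lineno}: duplicate species {species!r}")
            if ref_id in ref_ids:
                raise SequenceFormatError(f"{path.name}:{lineno}: duplicate ref_id {ref_id!r}")
            lineage = tuple(
                (rank, name)
                for rank, name in zip(RANKS, names)
                if name not in ("", "-")
            )
            taxonomy[species] = TaxonRecord(species=species, lineage=lineage, ref_id=ref_id)
            ref_ids.add(ref_id)
    return taxonomy


def write_taxonomy(taxonomy: Mapping[str, TaxonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TAX_HEADER) + "\n")
        for species in sorted(taxonomy):
            t = taxonomy[species]
            names = dict(t.lineage)
            row = [t.ref_id] + [names.get(rank, "-") for rank in RANKS]
            fh.write("\t".join(row) + "\n")


def load_reference(fasta_path: str | Path, taxonomy_path: str | Path) -> ReferenceLibrary:
    """Read a reference library from a FASTA file plus taxonomy TSV."""
    return ReferenceLibrary(
        records=parse_fasta(fasta_path), taxonomy=parse_taxonomy(taxonomy_path)
    )


# ---------------------------------------------------------------------------
# Cluster report (.clstr-style)


@dataclass
class ParsedClusterMember:
    id: str
    length: int
    identity: float
    is_representative: bool


@dataclass
class ParsedCluster:
    index: int
    members: list[ParsedClusterMember] = field(default_factory=list)


def write_clusters(clusters: "ClusterSet", path: str | Path) -> None:
    """Write a cd-hit ``.clstr``-style report.

    Identities are written as full-precision fractions (not rounded
    percentages) so that ``parse_clusters(write_clusters(x))`` is
    lossless on ids and identities.
    """
    lengths = getattr(clusters, "lengths", None) or {}
    with open(path, "w") as fh:
        for cl in clusters.clusters:
            fh.write(f">Cluster {cl.index}\n")
            for n, (member_id, identity) in enumerate(cl.members):
                length = lengths.get(member_id, 0)
                tail = "*" if member_id == cl.representative else f"at {identity:.17g}"
                fh.write(f"{n}\t{length}nt, >{member_id}... {tail}\n")


def parse_clusters(path: str | Path) -> list[ParsedCluster]:
    path = Path(path)
    clusters: list[ParsedCluster] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Cluster"):
                idx = int(line.split()[1])
                clusters.append(ParsedCluster(index=idx))
                continue
            if not clusters:
                raise SequenceFormatError(f"{path.name}:{lineno}: member line before any cluster")
            try:
                _, rest = line.split("\t", 1)
                size_part, id_part = rest.split(", >", 1)
                length = int(size_part[:-2])  # strip "nt"
                member_id, tail = id_part.split("... ", 1)
            except ValueError as exc:
                raise SequenceFormatError(f"{path.name}:{lineno}: malformed member line") from exc
            if tail == "*":
                identity, is_rep = 1.0, True
            else:
                identity, is_rep = float(tail[3:]), False
            clusters[-1].members.append(
                ParsedClusterMember(member_id, length, identity, is_rep)
            )
    return clusters
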