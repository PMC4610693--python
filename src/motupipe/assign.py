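"""Read-to-species assignment, residual MOTU clustering and classification.

The full read-analysis chain: quality-filtered, homopolymer-capped reads
are assigned to the best reference species at a high identity threshold
(99% by default); reads matching no reference are clustered de novo into
molecular operational taxonomic units (MOTUs), low-coverage MOTUs
(< 10 reads) are dropped, and each surviving MOTU representative is
classified against a taxonomy-annotated sequence database by local
alignment with score and identity gates.  When several database species
tie at the same (rounded) identity, the MOTU is named by the deepest
taxonomic rank they all share — e.g. two congeners yield "<Genus> sp.".
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from ._align import local_stats
from .cluster import (
    DEFAULT_PARAMS,
    IdentityParams,
    cluster_against_reference,
    greedy_cluster,
)
from .commstats import DetectionReport, detection_report
from .homopolymer import cap_library, cap_records, max_run_length
from .readfilter import FilterParams, FilterReport, filter_reads
from .seqio import (
    RANKS,
    ReferenceLibrary,
    SequenceRecord,
    load_reference,
    parse_fastq,
    write_fasta,
)


@dataclass
class AssignmentTable:
    """Read-to-species matches plus the unassigned pool."""

    per_read: dict[str, tuple[str, float]]
    per_species: dict[str, int]
    unassigned: list[str]

    @property
    def n_reads(self) -> int:
        return len(self.per_read) + len(self.unassigned)

    @property
    def assigned_fraction(self) -> float:
        return len(self.per_read) / self.n_reads if self.n_reads else 0.0

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tspecies\tidentity\n")
            for rid, (sp, ident) in self.per_read.items():
                fh.write(f"{rid}\t{sp}\t{ident:.6f}\n")
            for rid in self.unassigned:
                fh.write(f"{rid}\t-\t-\n")


def read_assignment_tsv(path: str | Path) -> AssignmentTable:
    per_read: dict[str, tuple[str, float]] = {}
    per_species: dict[str, int] = {}
    unassigned: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: not an assignment table")
        for line in fh:
            rid, sp, ident = line.rstrip("\n").split("\t")
            if sp == "-":
                unassigned.append(rid)
            else:
                per_read[rid] = (sp, float(ident))
                per_species[sp] = per_species.get(sp, 0) + 1
    return AssignmentTable(per_read=per_read, per_species=per_species, unassigned=unassigned)


def assign_reads(
    reads: Sequence[SequenceRecord],
    reference: ReferenceLibrary,
    threshold: float = 0.99,
    params: IdentityParams = DEFAULT_PARAMS,
    check_cap: bool = True,
) -> AssignmentTable:
    """Best-fit assignment of reads against the reference library.

    Reads are expected to be homopolymer-capped to the same level as the
    reference; with ``check_cap`` the call refuses reads whose longest
    run exceeds the reference's (the observable symptom of a cap
    mismatch).
    """
    if check_cap and reads:
        k_reads = max_run_length(reads)
        k_ref = max_run_length(reference.records)
        if k_reads > k_ref:
            raise ValueError(
                f"cap mismatch: reads contain {k_reads}-mer runs but the reference's "
                f"longest run is {k_ref}; cap the reads to the reference level first"
            )
    matched, unmatched = cluster_against_reference(reads, reference, threshold, params)
    per_species: dict[str, int] = {}
    for sp, _ident in matched.values():
        per_species[sp] = per_species.get(sp, 0) + 1
    return AssignmentTable(per_read=matched, per_species=per_species, unassigned=unmatched)


@dataclass
class Motu:
    """A residual cluster treated as a species proxy."""

    index: int
    representative: str
    read_count: int
    member_ids: list[str] = field(default_factory=list)
    label: str = "unclassified"


def cluster_residuals(
    reads: Sequence[SequenceRecord],
    threshold: float = 0.99,
    min_reads: int = 10,
    params: IdentityParams = DEFAULT_PARAMS,
) -> list[Motu]:
    """De novo cluster unassigned reads; drop clusters below *min_reads*.

    Surviving MOTUs are ordered by read count (descending, ties by
    cluster creation order); the representative is the longest member
    (ties broken by ascending id), as in the clustering engine.
    """
    if not reads:
        return []
    clusters = greedy_cluster(reads, threshold, params=params, mode="first_fit")
    survivors = [cl for cl in clusters.clusters if len(cl) >= min_reads]
    survivors.sort(key=lambda cl: (-len(cl), cl.index))
    return [
        Motu(
            index=n,
            representative=cl.representative,
            read_count=len(cl),
            member_ids=cl.member_ids,
        )
        for n, cl in enumerate(survivors)
    ]


@dataclass
class TaxonomicHit:
    """Best database hit of a MOTU representative after the score and
    identity gates."""

    score: int
    identity: float
    assigned_name: str
    assigned_rank: str


def classify_motu(
    representative: SequenceRecord,
    db: ReferenceLibrary,
    min_score: int = 100,
    min_identity: float = 0.90,
    params: IdentityParams = DEFAULT_PARAMS,
    identity_precision: int = 3,
) -> TaxonomicHit | None:
    """Classify a MOTU representative against a taxonomy-annotated database.

    Local alignment against every database sequence; hits with raw score
    <= *min_score* or identity (matches / alignment columns) <=
    *min_identity* are discarded.  The top hit is taken by score; all
    hits whose identity, rounded to ``identity_precision`` decimals,
    equals the top hit's are treated as tied, and a multi-species tie is
    named by the deepest rank shared by every tied lineage (a genus-rank
    tie is reported as "<Genus> sp.").  Returns None when no hit
    qualifies ("unclassified").
    """
    hits: list[tuple[int, float, str]] = []  # (score, identity, species)
    for ref in db.records:
        score, matches, cols = local_stats(
            representative.residues, ref.residues,
            params.match_score, params.mismatch_penalty,
            params.gap_open, params.gap_extend,
        )
        if cols == 0:
            continue
        identity = matches / cols
        if score > min_score and identity > min_identity:
            hits.append((score, identity, db.species_of(ref.id)))
    if not hits:
        return None

    top = max(hits, key=lambda h: (h[0], h[1], h[2]))
    top_round = round(top[1], identity_precision)
    tied = [h for h in hits if round(h[1], identity_precision) == top_round]
    tied_species = sorted({h[2] for h in tied})
    if len(tied_species) == 1:
        return TaxonomicHit(
            score=top[0], identity=top[1],
            assigned_name=tied_species[0], assigned_rank="species",
        )

    lineages = [dict(db.taxonomy[sp].lineage) for sp in tied_species]
    shared_rank = None
    shared_name = None
    for rank in RANKS[:-1]:  # species cannot be shared by distinct species
        names = {lin.get(rank) for lin in lineages}
        if len(names) == 1 and None not in names:
            shared_rank, shared_name = rank, names.pop()
    if shared_rank is None:
        return None
    name = f"{shared_name} sp." if shared_rank == "genus" else shared_name
    best_tied = max(tied, key=lambda h: (h[0], h[1], h[2]))
    return TaxonomicHit(
        score=best_tied[0], identity=best_tied[1],
        assigned_name=name, assigned_rank=shared_rank,
    )


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class PipelineConfig:
    """Every knob of the filter -> cap -> assign -> MOTU -> classify chain."""

    reference_fasta: str
    taxonomy_tsv: str
    reads_fastq: list[str]
    forward_primer: str
    outdir: str
    reverse_primer: str | None = None
    min_mean_quality: float = 10.0
    max_primer_mismatches: int = 2
    min_length: int = 200
    cap: int = 3
    assign_threshold: float = 0.99
    motu_threshold: float = 0.99
    motu_min_reads: int = 10
    classify_min_score: int = 100
    classify_min_identity: float = 0.90
    classify_db_fasta: str | None = None
    classify_db_taxonomy: str | None = None
    truth_species: list[str] | None = None
    detection_min_reads: int = 1
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class AliquotResult:
    label: str
    filter_report: FilterReport
    assignments: AssignmentTable
    motus: list[Motu]
    motu_hits: dict[str, TaxonomicHit | None]
    detection: DetectionReport | None


@dataclass
class PipelineResult:
    aliquots: dict[str, AliquotResult]
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole chain on each aliquot and write all intermediates.

    Per aliquot the output directory receives ``<label>.kept.fasta``,
    ``<label>.assign.tsv``, ``<label>.motus.tsv`` and
    ``<label>.hits.tsv``; a ``manifest.json`` logs every parameter.
    Outputs are a pure function of the inputs, so a rerun is
    byte-identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = load_reference(config.reference_fasta, config.taxonomy_tsv)
    capped_reference = cap_library(reference, config.cap)
    if config.classify_db_fasta:
        db = load_reference(
            config.classify_db_fasta,
            config.classify_db_taxonomy or config.taxonomy_tsv,
        )
    else:
        db = reference

    fparams = FilterParams(
        forward_primer=config.forward_primer,
        reverse_primer=config.reverse_primer,
        min_mean_quality=config.min_mean_quality,
        max_primer_mismatches=config.max_primer_mismatches,
        min_length=config.min_length,
    )

    aliquots: dict[str, AliquotResult] = {}
    for fastq in config.reads_fastq:
        label = Path(fastq).stem
        reads = parse_fastq(fastq)
        freport = filter_reads(reads, fparams)
        write_fasta(freport.kept, outdir / f"{label}.kept.fasta")
        with open(outdir / f"{label}.rejected.tsv", "w") as fh:
            fh.write("read_id\treason\n")
            for rid, reason in freport.rejected.items():
                fh.write(f"{rid}\t{reason}\n")

        capped = cap_records(freport.kept, config.cap)
        table = assign_reads(capped, capped_reference, config.assign_threshold)
        table.write_tsv(outdir / f"{label}.assign.tsv")

        unassigned_ids = set(table.unassigned)
        residual = [r for r in capped if r.id in unassigned_ids]
        motus = cluster_residuals(
            residual, config.motu_threshold, config.motu_min_reads
        )
        by_id = {r.id: r for r in residual}
        hits: dict[str, TaxonomicHit | None] = {}
        for motu in motus:
            hit = classify_motu(
                by_id[motu.representative], db,
                min_score=config.classify_min_score,
                min_identity=config.classify_min_identity,
            )
            hits[motu.representative] = hit
            if hit is not None:
                motu.label = hit.assigned_name

        with open(outdir / f"{label}.motus.tsv", "w") as fh:
            fh.write("motu\trepresentative\tread_count\tlabel\n")
            for motu in motus:
                fh.write(f"{motu.index}\t{motu.representative}\t{motu.read_count}\t{motu.label}\n")
        with open(outdir / f"{label}.hits.tsv", "w") as fh:
            fh.write("representative\tassigned_name\tassigned_rank\tscore\tidentity\n")
            for rep, hit in hits.items():
                if hit is None:
                    fh.write(f"{rep}\tunclassified\t-\t-\t-\n")
                else:
                    fh.write(
                        f"{rep}\t{hit.assigned_name}\t{hit.assigned_rank}\t"
                        f"{hit.score}\t{hit.identity:.6f}\n"
                    )

        detection = None
        if config.truth_species is not None:
            detection = detection_report(
                table, set(config.truth_species), min_reads=config.detection_min_reads
            )
        aliquots[label] = AliquotResult(
            label=label,
            filter_report=freport,
            assignments=table,
            motus=motus,
            motu_hits=hits,
            detection=detection,
        )

    manifest = {"motupipe_version": __version__, "config": asdict(config)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(aliquots=aliquots, manifest=manifest)
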