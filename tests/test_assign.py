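import numpy as np
import pytest

from conftest import mutate_seq, random_seq
from motupipe.assign import (
    AssignmentTable,
    PipelineConfig,
    assign_reads,
    classify_motu,
    cluster_residuals,
    read_assignment_tsv,
    run_pipeline,
)
from motupipe.homopolymer import cap_library, cap_records
from motupipe.seqio import ReferenceLibrary, SequenceRecord, TaxonRecord
from motupipe.synthetic_data import (
    ErrorModel,
    SimulationConfig,
    simulate_reads,
    simulate_reference,
    simulate_study,
)


def reads_from(library, rng, n, exclude=()):
    """Error-free reads drawn uniformly from library species."""
    pool = [r for r in library.records if library.species_of(r.id) not in exclude]
    reads, truth = [], {}
    for i in range(n):
        rec = pool[int(rng.integers(0, len(pool)))]
        rid = f"rd{i:04d}"
        reads.append(SequenceRecord(id=rid, residues=rec.residues))
        truth[rid] = library.species_of(rec.id)
    return reads, truth


class TestAssignReads:
    def test_zero_error_counts_match_truth(self, rng):
        lib = simulate_reference(SimulationConfig(seed=3, n_species=10), rng)
        reads, truth = reads_from(lib, rng, 100)
        table = assign_reads(reads, lib, 0.99)
        assert table.unassigned == []
        counts = {}
        for sp in truth.values():
            counts[sp] = counts.get(sp, 0) + 1
        assert table.per_species == counts
        assert table.n_reads == 100

    def test_reads_from_absent_species_unassigned(self, rng):
        lib = simulate_reference(SimulationConfig(seed=3, n_species=10), rng)
        absent = sorted(lib.species)[0]
        reference = lib.subset(lib.species - {absent})
        seq = lib.record(lib.taxonomy[absent].ref_id).residues
        reads = [SequenceRecord(id=f"q{i}", residues=seq) for i in range(5)]
        table = assign_reads(reads, reference, 0.99)
        assert table.per_read == {}
        assert table.unassigned == [f"q{i}" for i in range(5)]

    def test_cap_mismatch_detected(self, rng):
        lib = simulate_reference(SimulationConfig(seed=3, n_species=6), rng)
        capped = cap_library(lib, 3)
        reads = [SequenceRecord(id="q", residues="ACGT" * 20 + "GGGGGG" + "ACGT" * 20)]
        with pytest.raises(ValueError, match="cap mismatch"):
            assign_reads(reads, capped, 0.99)

    def test_assigned_fraction_decreases_with_substitution_rate(self, rng):
        lib = simulate_reference(SimulationConfig(seed=5, n_species=8), rng)
        fractions = []
        for rate in (0.0, 0.005, 0.02):
            sub_rng = np.random.default_rng(42)
            cfg = SimulationConfig(
                seed=5, n_species=8, n_reads=150, forward_primer="",
                truncation_rate=0.0, junk_rate=0.0,
            )
            model = ErrorModel(hp_anchors=((3, 1.0),), substitution_rate=rate,
                               chimera_rate=0.0)
            reads, _truth = simulate_reads(lib, cfg, model, sub_rng)
            table = assign_reads(reads, lib, 0.99, check_cap=False)
            fractions.append(table.assigned_fraction)
        assert fractions[0] == 1.0
        assert fractions[0] > fractions[1] > fractions[2]


class TestClusterResiduals:
    def _identical_reads(self, rng, n, length=300):
        seq = random_seq(rng, length)
        return [SequenceRecord(id=f"r{i}", residues=seq) for i in range(n)]

    def test_nine_reads_below_coverage_floor(self, rng):
        assert cluster_residuals(self._identical_reads(rng, 9)) == []

    def test_ten_reads_form_one_motu(self, rng):
        motus = cluster_residuals(self._identical_reads(rng, 10))
        assert len(motus) == 1
        assert motus[0].read_count == 10

    def test_two_divergent_groups(self, rng):
        a = self._identical_reads(rng, 50)
        seq = random_seq(rng, 300)
        b = [SequenceRecord(id=f"s{i}", residues=seq) for i in range(50)]
        motus = cluster_residuals(a + b)
        assert len(motus) == 2
        assert [m.read_count for m in motus] == [50, 50]

    def test_lower_floor_gives_superset(self, rng):
        reads = []
        for g in range(6):
            seq = random_seq(rng, 250)
            for i in range(int(rng.integers(3, 20))):
                reads.append(SequenceRecord(id=f"g{g}_r{i}", residues=seq))
        strict = {m.representative for m in cluster_residuals(reads, min_reads=10)}
        loose = {m.representative for m in cluster_residuals(reads, min_reads=5)}
        assert strict <= loose


def classification_db(rng):
    """Two congeners plus an outgroup, all annotated."""
    base = random_seq(rng, 300)
    cal_a = base
    cal_b = mutate_seq(rng, base, 0.02)
    out = random_seq(rng, 300)
    recs = [
        SequenceRecord(id="D001", residues=cal_a),
        SequenceRecord(id="D002", residues=cal_b),
        SequenceRecord(id="D003", residues=out),
    ]
    lineage = lambda sp: (
        ("phylum", "Arthropoda"), ("class", "Copepoda"),
        ("family", "Calanidae"), ("genus", "Calanus"), ("species", sp),
    )
    tax = {
        "Calanus helgolandicus": TaxonRecord(
            species="Calanus helgolandicus", lineage=lineage("Calanus helgolandicus"),
            ref_id="D001"),
        "Calanus pacificus": TaxonRecord(
            species="Calanus pacificus", lineage=lineage("Calanus pacificus"),
            ref_id="D002"),
        "Beroe cucumis": TaxonRecord(
            species="Beroe cucumis",
            lineage=(("phylum", "Ctenophora"), ("genus", "Beroe"),
                     ("species", "Beroe cucumis")),
            ref_id="D003"),
    }
    return ReferenceLibrary(records=recs, taxonomy=tax), base


def midpoint_query(a: str, b: str) -> str:
    """A sequence exactly equidistant (Hamming) from a and b: differing
    positions are split evenly; an odd leftover gets a third base."""
    diff = [i for i in range(len(a)) if a[i] != b[i]]
    out = list(a)
    for n, i in enumerate(diff):
        if n < len(diff) // 2:
            out[i] = b[i]
        elif n == len(diff) - 1 and len(diff) % 2 == 1:
            out[i] = next(c for c in "ACGT" if c not in (a[i], b[i]))
    return "".join(out)


class TestClassifyMotu:
    def test_single_close_hit_assigned_to_species(self, rng):
        db, base = classification_db(rng)
        query = SequenceRecord(id="m", residues=base)
        hit = classify_motu(query, db)
        assert hit.assigned_rank == "species"
        assert hit.assigned_name == "Calanus helgolandicus"

    def test_congener_tie_assigned_to_genus_sp(self, rng):
        db, _base = classification_db(rng)
        query_seq = midpoint_query(db.record("D001").residues, db.record("D002").residues)
        hit = classify_motu(SequenceRecord(id="m", residues=query_seq), db)
        assert hit.assigned_rank == "genus"
        assert hit.assigned_name == "Calanus sp."

    def test_weak_hits_unclassified(self, rng):
        db, _ = classification_db(rng)
        query = SequenceRecord(id="m", residues=random_seq(rng, 300))
        assert classify_motu(query, db) is None

    def test_identity_gate(self, rng):
        db, base = classification_db(rng)
        query = SequenceRecord(id="m", residues=mutate_seq(rng, base, 0.15))
        # ~85% identity: below the 90% gate regardless of score
        assert classify_motu(query, db) is None

    def test_tie_rule_is_order_invariant(self, rng):
        db, _base = classification_db(rng)
        query = SequenceRecord(
            id="m",
            residues=midpoint_query(db.record("D001").residues, db.record("D002").residues),
        )
        names = set()
        for order in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
            shuffled = ReferenceLibrary(
                records=[db.records[i] for i in order], taxonomy=db.taxonomy
            )
            names.add(classify_motu(query, shuffled).assigned_name)
        assert names == {"Calanus sp."}


class TestRunPipeline:
    @pytest.fixture(scope="class")
    @staticmethod
    def fixture_dir(tmp_path_factory):
        outdir = tmp_path_factory.mktemp("study")
        cfg = SimulationConfig(
            seed=99, n_species=8, n_reads=200, truncation_rate=0.0, junk_rate=0.0
        )
        return simulate_study(cfg, outdir, model=ErrorModel.zero())

    def _config(self, fx, outdir):
        return PipelineConfig(
            reference_fasta=str(fx.reference_fasta),
            taxonomy_tsv=str(fx.taxonomy_tsv),
            reads_fastq=[str(p) for p in fx.fastq_paths],
            forward_primer=fx.forward_primer,
            outdir=str(outdir),
            truth_species=fx.truth_species,
        )

    def test_read_conservation_and_outputs(self, fixture_dir, tmp_path):
        result = run_pipeline(self._config(fixture_dir, tmp_path / "out"))
        for label, aliquot in result.aliquots.items():
            n_input = aliquot.filter_report.n_input
            assert n_input == 200
            table = aliquot.assignments
            assert len(table.per_read) + len(table.unassigned) == len(aliquot.filter_report.kept)
            motu_reads = sum(m.read_count for m in aliquot.motus)
            assert motu_reads <= len(table.unassigned)
            for suffix in ("kept.fasta", "assign.tsv", "motus.tsv", "hits.tsv"):
                assert (tmp_path / "out" / f"{label}.{suffix}").exists()
        assert (tmp_path / "out" / "manifest.json").exists()

    def test_rerun_is_byte_identical(self, fixture_dir, tmp_path):
        run_pipeline(self._config(fixture_dir, tmp_path / "a"))
        run_pipeline(self._config(fixture_dir, tmp_path / "b"))
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files_a == files_b
        for name in files_a:
            if name == "manifest.json":  # differs only in the outdir path
                continue
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes(), name

    def test_assignment_tsv_round_trip(self, fixture_dir, tmp_path):
        result = run_pipeline(self._config(fixture_dir, tmp_path / "out"))
        label, aliquot = next(iter(result.aliquots.items()))
        back = read_assignment_tsv(tmp_path / "out" / f"{label}.assign.tsv")
        assert back.per_species == aliquot.assignments.per_species
        assert back.unassigned == aliquot.assignments.unassigned
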