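import numpy as np
import pytest

from conftest import run_rich_seq
from motupipe.cluster import pairwise_identity
from motupipe.homopolymer import cap_runs, find_runs
from motupipe.seqio import ReferenceLibrary, SequenceRecord, TaxonRecord, parse_fastq
from motupipe.synthetic_data import (
    ErrorModel,
    SimulationConfig,
    apply_homopolymer_errors,
    hp_accuracy,
    simulate_reads,
    simulate_reference,
    simulate_study,
)


class TestHpAccuracy:
    def test_anchor_values(self):
        model = ErrorModel()
        assert hp_accuracy(3, model) == 0.99
        assert hp_accuracy(9, model) == 0.64

    def test_interpolation_strictly_between_anchors(self):
        model = ErrorModel()
        acc = hp_accuracy(6, model)
        assert 0.64 < acc < 0.99

    def test_flat_below_smallest_anchor(self):
        model = ErrorModel()
        assert hp_accuracy(1, model) == hp_accuracy(2, model) == 0.99

    def test_monotone_non_increasing(self):
        model = ErrorModel()
        accs = [hp_accuracy(k, model) for k in range(1, 15)]
        assert accs == sorted(accs, reverse=True)
        assert all(0.0 <= a <= 1.0 for a in accs)

    def test_invalid_model(self):
        with pytest.raises(ValueError):
            ErrorModel(hp_anchors=())
        with pytest.raises(ValueError):
            ErrorModel(hp_anchors=((3, 0.5), (9, 0.9)))  # accuracy increasing


class TestSimulateReference:
    def test_identities_within_configured_range(self):
        cfg = SimulationConfig(seed=13, n_species=10, identity_range=(0.90, 0.98))
        lib = simulate_reference(cfg, np.random.default_rng(13))
        recs = lib.records
        idents = [
            pairwise_identity(recs[i].residues, recs[j].residues)
            for i in range(10)
            for j in range(i + 1, 10)
        ]
        assert len(idents) == 45
        assert min(idents) >= 0.89  # low end - 0.01
        assert max(idents) <= 0.99  # high end + 0.01

    def test_sibling_species_share_genus(self):
        cfg = SimulationConfig(seed=13, n_species=12)
        lib = simulate_reference(cfg, np.random.default_rng(13))
        genus_counts = {}
        for t in lib.taxonomy.values():
            g = t.name_at("genus")
            genus_counts[g] = genus_counts.get(g, 0) + 1
        assert max(genus_counts.values()) >= 2

    def test_same_seed_reproduces_library(self):
        cfg = SimulationConfig(seed=21, n_species=8)
        a = simulate_reference(cfg, np.random.default_rng(21))
        b = simulate_reference(cfg, np.random.default_rng(21))
        assert [(r.id, r.residues) for r in a.records] == [
            (r.id, r.residues) for r in b.records
        ]

    def test_infeasible_range_reports_achieved(self):
        # 10 bp sequences: identity is a multiple of 1/10, so nothing can
        # land strictly inside (0.985, 0.99) +/- tolerance
        cfg = SimulationConfig(
            seed=5, n_species=2, seq_length=10, hp_seed_runs=0,
            identity_range=(0.985, 0.99), max_tuning_attempts=3,
        )
        with pytest.raises(RuntimeError, match="achieved"):
            simulate_reference(cfg, np.random.default_rng(5))


class TestHomopolymerErrors:
    def test_miscalls_change_run_length_by_one(self, rng):
        model = ErrorModel()
        seq = "C" + "A" * 7 + "G"
        lengths = set()
        for _ in range(500):
            out, events = apply_homopolymer_errors(seq, model, rng)
            a_run = [r for r in find_runs(out) if r.base == "A"][0]
            lengths.add(a_run.length)
            for ev in events:
                assert ev[0] == "hp" and ev[3] in (-1, 1)
        assert lengths <= {6, 7, 8}
        assert len(lengths) > 1  # some miscalls at 36% per call

    def test_miscall_frequency_calibrated_at_k5(self, rng):
        model = ErrorModel()
        k, trials = 5, 2000
        seq = "C" + "A" * k + "G"
        miscalls = 0
        for _ in range(trials):
            out, _ = apply_homopolymer_errors(seq, model, rng)
            a_run = [r for r in find_runs(out) if r.base == "A"][0]
            miscalls += a_run.length != k
        p = 1 - hp_accuracy(k, model)
        se = (p * (1 - p) / trials) ** 0.5
        assert abs(miscalls / trials - p) <= 3 * se


def run_rich_library(rng, n_species=4):
    recs, tax = [], {}
    for i in range(n_species):
        sp = f"Runsp{i}"
        rid = f"RR{i:03d}"
        recs.append(SequenceRecord(id=rid, residues=run_rich_seq(rng)))
        tax[sp] = TaxonRecord(
            species=sp, lineage=(("genus", f"Rung{i}"), ("species", sp)), ref_id=rid
        )
    return ReferenceLibrary(records=recs, taxonomy=tax)


class TestSimulateReads:
    def _config(self, **kw):
        defaults = dict(
            seed=1, n_species=4, n_reads=50, forward_primer="",
            truncation_rate=0.0, junk_rate=0.0,
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_zero_error_reads_equal_sources(self, rng, tiny_library):
        cfg = self._config(n_species=5)
        reads, truth = simulate_reads(tiny_library, cfg, ErrorModel.zero(), rng)
        by_species = {
            sp: tiny_library.record(t.ref_id).residues
            for sp, t in tiny_library.taxonomy.items()
        }
        for read in reads:
            assert read.residues == by_species[truth.per_read[read.id].species]

    def test_chimera_rate_one_marks_all_reads(self, rng, tiny_library):
        cfg = self._config(n_species=5)
        model = ErrorModel(hp_anchors=((3, 1.0),), substitution_rate=0.0, chimera_rate=1.0)
        reads, truth = simulate_reads(tiny_library, cfg, model, rng)
        for read in reads:
            parents = truth.per_read[read.id].chimera_parents
            assert parents is not None and parents[0] != parents[1]

    def test_capping_erases_hp_errors_on_run_rich_library(self, rng):
        # every true run >= 4, so a +/-1 miscall never drops a run below
        # the cap: capped read == capped source exactly
        lib = run_rich_library(rng)
        cfg = self._config()
        model = ErrorModel(substitution_rate=0.0, chimera_rate=0.0)
        reads, truth = simulate_reads(lib, cfg, model, rng)
        src = {sp: lib.record(t.ref_id).residues for sp, t in lib.taxonomy.items()}
        for read in reads:
            source = src[truth.per_read[read.id].species]
            assert cap_runs(read.residues, 3) == cap_runs(source, 3)

    def test_truth_covers_every_read(self, rng, tiny_library):
        cfg = self._config(n_species=5, junk_rate=0.1, truncation_rate=0.2)
        reads, truth = simulate_reads(tiny_library, cfg, ErrorModel(), rng)
        assert {r.id for r in reads} == set(truth.per_read)
        assert all(r.quality is not None for r in reads)


class TestSimulateStudy:
    def test_fixture_files_and_defaults(self, tmp_path):
        cfg = SimulationConfig(seed=77)
        assert (cfg.n_species, cfg.n_reads, cfg.n_aliquots) == (30, 2000, 2)
        fast_cfg = SimulationConfig(seed=77, n_species=6, n_reads=40)
        fx = simulate_study(fast_cfg, tmp_path)
        for p in (fx.reference_fasta, fx.taxonomy_tsv, *fx.fastq_paths):
            assert p.exists()
        assert (tmp_path / "config.json").exists()
        assert (tmp_path / "abundance.tsv").exists()
        assert len(fx.fastq_paths) == 2
        assert len(parse_fastq(fx.fastq_paths[0])) == 40

    def test_contaminant_design(self, tmp_path):
        cfg = SimulationConfig(
            seed=42, n_species=8, n_reads=60, truth_size=4, n_contaminants=1,
            contaminant_fraction=0.2,
        )
        fx = simulate_study(cfg, tmp_path)
        (contaminant, frac) = fx.contaminants[0]
        assert frac == 0.2
        assert contaminant not in fx.truth_species
        assert contaminant in fx.reference.species
        observed = {
            rt.species
            for truth in fx.truths.values()
            for rt in truth.per_read.values()
        }
        assert observed <= set(fx.truth_species) | {contaminant}

    def test_different_seeds_differ(self, tmp_path):
        a = simulate_study(SimulationConfig(seed=1, n_species=6, n_reads=30), tmp_path / "a")
        b = simulate_study(SimulationConfig(seed=2, n_species=6, n_reads=30), tmp_path / "b")
        assert a.fastq_paths[0].read_text() != b.fastq_paths[0].read_text()
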