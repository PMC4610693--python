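"""Synthetic reference libraries and 454-style amplicon read sets.

The generator emulates the statistical structure the pipeline assumes:

* a ~450 bp marker library of N species evolved along a random
  bifurcating tree, with realized pairwise identities tuned into a
  configured range and homopolymer runs seeded into the root sequence;
* taxonomy derived from the tree (clades become genus/family/... labels,
  so sibling species share a genus and LCA behaviour is constructible);
* pyrosequencing reads whose dominant error mode is run-length miscall:
  a homopolymer run of length k is called correctly with probability
  ``hp_accuracy(k)`` (anchored at 99% for 3-mers and 64% for 9-mers,
  log-linearly interpolated) and otherwise lengthened or shortened by
  one base; plus uniform substitutions and single-breakpoint chimeras;
* per-species abundances (uniform or lognormal), optional contaminant
  species spiked at a fixed read fraction, and two or more "aliquot"
  technical replicates drawn from the same abundance vector.

Every read carries a ground-truth record (source species, error events,
chimera parents) so recovery can be measured exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cluster import DEFAULT_PARAMS, pairwise_identity
from .seqio import (
    ReferenceLibrary,
    SequenceRecord,
    TaxonRecord,
    write_fasta,
    write_fastq,
    write_taxonomy,
)

_BASES = "ACGT"

#: Synthetic 20-mer standing in for the forward amplification primer
#: (the real primer sequences are run-specific configuration, not data).
SYNTHETIC_FORWARD_PRIMER = "ACGGTTCACGTAGCTAGACC"


@dataclass(frozen=True)
class ErrorModel:
    """Pyrosequencing error model.

    ``hp_anchors`` are (run length, probability of a correct length
    call); between anchors the accuracy is interpolated log-linearly in
    run length, below the smallest anchor it is flat, beyond the largest
    the last slope is extrapolated (clamped to [0, 1]).  A miscalled run
    is shortened by one base with probability ``hp_bias``, else
    lengthened by one.
    """

    hp_anchors: tuple[tuple[int, float], ...] = ((3, 0.99), (9, 0.64))
    hp_bias: float = 0.5
    substitution_rate: float = 0.002
    chimera_rate: float = 0.01

    def __post_init__(self) -> None:
        if not self.hp_anchors:
            raise ValueError("error model needs at least one homopolymer anchor")
        ks = [k for k, _ in self.hp_anchors]
        accs = [a for _, a in self.hp_anchors]
        if ks != sorted(ks) or len(set(ks)) != len(ks):
            raise ValueError("anchors must have strictly increasing run lengths")
        if any(not 0.0 <= a <= 1.0 for a in accs):
            raise ValueError("anchor accuracies must be in [0, 1]")
        if accs != sorted(accs, reverse=True):
            raise ValueError("accuracy must be non-increasing in run length")
        for p in (self.hp_bias, self.substitution_rate, self.chimera_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    @classmethod
    def zero(cls) -> "ErrorModel":
        """An error-free model (for recovery baselines)."""
        return cls(hp_anchors=((3, 1.0),), substitution_rate=0.0, chimera_rate=0.0)


def hp_accuracy(k: int, model: ErrorModel) -> float:
    """Probability of calling a length-*k* run at its true length."""
    if k < 1:
        raise ValueError("run length must be >= 1")
    anchors = model.hp_anchors
    if k <= anchors[0][0]:
        return anchors[0][1]
    for (k0, a0), (k1, a1) in zip(anchors, anchors[1:]):
        if k <= k1:
            if a0 <= 0.0 or a1 <= 0.0:
                return 0.0 if k > k0 else a0
            log_a = math.log(a0) + (math.log(a1) - math.log(a0)) * (k - k0) / (k1 - k0)
            return min(1.0, math.exp(log_a))
    # extrapolate beyond the last anchor with the final slope
    if len(anchors) == 1:
        return anchors[0][1]
    (k0, a0), (k1, a1) = anchors[-2], anchors[-1]
    if a1 <= 0.0:
        return 0.0
    slope = (math.log(a1) - math.log(max(a0, 1e-300))) / (k1 - k0)
    return max(0.0, min(1.0, math.exp(math.log(a1) + slope * (k - k1))))


@dataclass
class SimulationConfig:
    """Study design of one simulated experiment.

    ``truth_size`` restricts the pooled community to a random subset of
    the library (the ZPDNA-style design); ``n_contaminants`` species
    outside the pool are spiked at ``contaminant_fraction`` of the reads
    each.  ``n_novel_species`` extra species are generated and withheld
    from the written reference library (but kept in the classification
    database) so that residual MOTUs exist.
    """

    seed: int
    n_species: int = 30
    seq_length: int = 450
    identity_range: tuple[float, float] = (0.90, 0.98)
    hp_max_run: int = 6
    hp_seed_runs: int = 8
    n_novel_species: int = 0
    abundance: str = "uniform"  # or "lognormal"
    lognormal_sigma: float = 1.0
    truth_size: int | None = None
    truth_includes_novel: bool = False
    n_contaminants: int = 0
    contaminant_fraction: float = 0.05
    n_reads: int = 2000
    n_aliquots: int = 2
    forward_primer: str = SYNTHETIC_FORWARD_PRIMER
    truncation_rate: float = 0.05
    truncation_min: int = 120
    junk_rate: float = 0.01
    max_tuning_attempts: int = 12

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        lo, hi = self.identity_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("identity range must satisfy 0 < low < high < 1")
        if self.n_contaminants * self.contaminant_fraction >= 1.0:
            raise ValueError("contaminant fractions must sum below 1")


@dataclass
class ReadTruth:
    """Ground truth of one emitted read."""

    read_id: str
    species: str
    events: list[tuple] = field(default_factory=list)
    n_hp_errors: int = 0
    n_substitutions: int = 0
    chimera_parents: tuple[str, str] | None = None
    truncated: bool = False
    junk: bool = False


@dataclass
class SimulationTruth:
    """Ground truth of one aliquot: per-read records plus the abundance
    vector the reads were drawn from."""

    per_read: dict[str, ReadTruth]
    abundance: dict[str, float]


# ---------------------------------------------------------------------------
# Reference library generation


def _random_tree(leaves: list[int], rng: np.random.Generator, counter: list[int]):
    """Random bifurcating tree as nested (node_id, left, right) tuples."""
    if len(leaves) == 1:
        return ("leaf", leaves[0])
    node_id = counter[0]
    counter[0] += 1
    k = int(rng.integers(1, len(leaves)))
    return ("node", node_id,
            _random_tree(leaves[:k], rng, counter),
            _random_tree(leaves[k:], rng, counter))


def _random_root(config: SimulationConfig, rng: np.random.Generator) -> str:
    seq = list(rng.choice(list(_BASES), size=config.seq_length))
    for _ in range(config.hp_seed_runs):
        length = int(rng.integers(4, config.hp_max_run + 1))
        pos = int(rng.integers(0, config.seq_length - length))
        base = _BASES[rng.integers(0, 4)]
        seq[pos:pos + length] = base * length
    return "".join(seq)


def _mutate(seq: str, sub_rate: float, rng: np.random.Generator,
            indel_rate_factor: float = 0.05) -> str:
    """Substitutions at *sub_rate* per base plus rare 1-bp indels."""
    out = []
    indel_rate = sub_rate * indel_rate_factor
    for base in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(base)
            out.append(_BASES[rng.integers(0, 4)])  # insertion
            continue
        if rng.random() < sub_rate:
            choices = [b for b in _BASES if b != base]
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(base)
    return "".join(out) if out else seq


def _evolve(tree, seq: str, r_leaf: float, r_int: float,
            rng: np.random.Generator, out: dict[int, str]) -> None:
    if tree[0] == "leaf":
        out[tree[1]] = _mutate(seq, r_leaf, rng)
        return
    for child in tree[2:]:
        child_seq = _mutate(seq, r_int, rng)
        _evolve(child, child_seq, r_leaf, r_int, rng, out)


def _leaf_paths(tree, path=(), out=None):
    """Leaf id -> tuple of internal node ids from the root down."""
    if out is None:
        out = {}
    if tree[0] == "leaf":
        out[tree[1]] = path
        return out
    for child in tree[2:]:
        _leaf_paths(child, path + (tree[1],), out)
    return out


def _tree_height(tree) -> int:
    if tree[0] == "leaf":
        return 0
    return 1 + max(_tree_height(c) for c in tree[2:])


def _taxonomy_from_tree(tree, n_total: int) -> dict[int, TaxonRecord]:
    """Rank labels from tree depth: depth-1 clades are phyla, then class,
    order, family; the leaf's parent clade is its genus."""
    paths = _leaf_paths(tree)
    depth_ranks = ("phylum", "class", "order", "family")
    taxonomy: dict[int, TaxonRecord] = {}
    prefixes = {"phylum": "Phylum", "class": "Class", "order": "Order",
                "family": "Family"}
    for leaf, path in sorted(paths.items()):
        lineage: list[tuple[str, str]] = []
        for d, rank in enumerate(depth_ranks, start=1):
            node = path[min(d, len(path) - 1)] if path else 0
            lineage.append((rank, f"{prefixes[rank]}{node:02d}"))
        genus_node = path[-1] if path else 0
        genus = f"Genus{genus_node:02d}"
        species = f"{genus} species{leaf:03d}"
        lineage.append(("genus", genus))
        lineage.append(("species", species))
        taxonomy[leaf] = TaxonRecord(
            species=species, lineage=tuple(lineage), ref_id=f"REF{leaf:04d}"
        )
    return taxonomy


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator
) -> ReferenceLibrary:
    """Generate a species library with tuned pairwise identities.

    A root sequence is evolved along a random bifurcating tree; terminal
    and internal branch mutation rates are retuned multiplicatively
    until all realized pairwise identities (measured with the alignment
    engine) fall inside ``identity_range`` (+/- 0.005), or an error
    reports the achieved range after ``max_tuning_attempts``.
    """
    n_total = config.n_species + config.n_novel_species
    leaves = [int(x) for x in rng.permutation(n_total)]
    tree = _random_tree(leaves, rng, counter=[0])
    root = _random_root(config, rng)
    height = max(1, _tree_height(tree))
    lo, hi = config.identity_range
    r_leaf = (1.0 - hi) * 0.4
    r_int = max(1e-4, ((1.0 - lo) * 0.45 - r_leaf) / max(1, height - 1))

    achieved = (0.0, 0.0)
    for attempt in range(config.max_tuning_attempts):
        evolve_rng = np.random.default_rng(rng.integers(0, 2**31))
        seqs: dict[int, str] = {}
        _evolve(tree, root, r_leaf, r_int, evolve_rng, seqs)
        idents = [
            pairwise_identity(seqs[i], seqs[j], DEFAULT_PARAMS)
            for i in range(n_total)
            for j in range(i + 1, n_total)
        ]
        mn, mx = min(idents), max(idents)
        achieved = (mn, mx)
        if mn >= lo - 0.005 and mx <= hi + 0.005:
            taxonomy_by_leaf = _taxonomy_from_tree(tree, n_total)
            records = [
                SequenceRecord(
                    id=taxonomy_by_leaf[leaf].ref_id,
                    residues=seqs[leaf],
                    description=taxonomy_by_leaf[leaf].species,
                )
                for leaf in range(n_total)
            ]
            taxonomy = {t.species: t for t in taxonomy_by_leaf.values()}
            return ReferenceLibrary(records=records, taxonomy=taxonomy)
        # multiplicative retune: siblings too similar -> faster terminal
        # branches; deepest pairs too divergent -> slower internal ones
        f_leaf = (1.0 - hi) / max(1e-6, 1.0 - mx)
        f_int = (1.0 - lo) / max(1e-6, 1.0 - mn)
        r_leaf *= min(3.0, max(0.3, f_leaf))
        r_int *= min(3.0, max(0.3, f_int))
    raise RuntimeError(
        f"could not tune pairwise identities into {config.identity_range} "
        f"after {config.max_tuning_attempts} attempts; achieved {achieved}"
    )


# ---------------------------------------------------------------------------
# Read simulation


def apply_homopolymer_errors(
    seq: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, list[tuple]]:
    """Run-length miscalls: each maximal run of length k is lengthened or
    shortened by one base with probability ``1 - hp_accuracy(k)``."""
    out = []
    events: list[tuple] = []
    pos = 0
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        k = j - i
        base = seq[i]
        if rng.random() < 1.0 - hp_accuracy(k, model):
            delta = -1 if rng.random() < model.hp_bias else 1
            events.append(("hp", i, k, delta))
            out.append(base * (k + delta))
        else:
            out.append(base * k)
        pos += k
        i = j
    return "".join(out), events


def _apply_substitutions(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[tuple]]:
    if rate <= 0.0:
        return seq, []
    arr = list(seq)
    events = []
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for pos in hits:
        old = arr[pos]
        choices = [b for b in _BASES if b != old]
        new = choices[rng.integers(0, 3)]
        arr[pos] = new
        events.append(("sub", int(pos), old, new))
    return "".join(arr), events


def draw_abundance(
    species: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    contaminants: Sequence[tuple[str, float]] = (),
) -> dict[str, float]:
    """Per-species read probabilities; contaminant fractions are fixed and
    the remaining mass is shared by the pooled species."""
    if config.abundance == "uniform":
        weights = np.ones(len(species))
    elif config.abundance == "lognormal":
        weights = rng.lognormal(0.0, config.lognormal_sigma, size=len(species))
    else:
        raise ValueError(f"unknown abundance model {config.abundance!r}")
    cont_total = sum(f for _, f in contaminants)
    weights = weights / weights.sum() * (1.0 - cont_total)
    abundance = dict(zip(species, weights))
    for sp, frac in contaminants:
        abundance[sp] = abundance.get(sp, 0.0) + frac
    return abundance


def simulate_reads(
    library: ReferenceLibrary,
    config: SimulationConfig,
    model: ErrorModel,
    rng: np.random.Generator,
    abundance: dict[str, float] | None = None,
    label: str = "sample",
) -> tuple[list[SequenceRecord], SimulationTruth]:
    """One aliquot of 454-style reads with ground truth.

    Each read: a source species drawn from the abundance vector, an
    optional two-parent chimera, run-length miscalls, substitutions
    (over primer and insert alike), an optional 3' truncation, and
    Phred qualities (high baseline, degraded over miscalled runs).
    """
    if abundance is None:
        abundance = draw_abundance(sorted(library.species), config, rng)
    names = sorted(abundance)
    probs = np.array([abundance[s] for s in names])
    probs = probs / probs.sum()
    seq_of = {sp: library.record(library.taxonomy[sp].ref_id).residues for sp in names}

    reads: list[SequenceRecord] = []
    truth: dict[str, ReadTruth] = {}
    for i in range(config.n_reads):
        rid = f"{label}_r{i:05d}"
        species = names[rng.choice(len(names), p=probs)]
        rt = ReadTruth(read_id=rid, species=species)

        if rng.random() < config.junk_rate:
            length = int(rng.integers(150, 400))
            residues = "".join(rng.choice(list(_BASES), size=length))
            quality = [int(q) for q in rng.integers(2, 15, size=length)]
            rt.junk = True
            reads.append(SequenceRecord(id=rid, residues=residues, quality=quality))
            truth[rid] = rt
            continue

        core = seq_of[species]
        if model.chimera_rate > 0.0 and rng.random() < model.chimera_rate:
            others = [s for s in names if s != species]
            partner = others[rng.integers(0, len(others))]
            frac = rng.uniform(0.3, 0.7)
            cut_a = int(len(core) * frac)
            other = seq_of[partner]
            cut_b = int(len(other) * frac)
            core = core[:cut_a] + other[cut_b:]
            rt.chimera_parents = (species, partner)
            rt.events.append(("chimera", cut_a, partner))

        core, hp_events = apply_homopolymer_errors(core, model, rng)
        rt.events.extend(hp_events)
        rt.n_hp_errors = len(hp_events)

        residues = config.forward_primer + core
        residues, sub_events = _apply_substitutions(
            residues, model.substitution_rate, rng
        )
        rt.events.extend(sub_events)
        rt.n_substitutions = len(sub_events)

        if rng.random() < config.truncation_rate and len(residues) > config.truncation_min:
            cut = int(rng.integers(config.truncation_min, len(residues)))
            residues = residues[:cut]
            rt.truncated = True

        quality = [int(q) for q in rng.integers(30, 41, size=len(residues))]
        bad = min(len(hp_events) * 3, len(quality))
        if bad:  # degrade some positions when runs were miscalled
            idx = rng.choice(len(quality), size=bad, replace=False)
            for p in idx:
                quality[p] = int(rng.integers(15, 26))

        reads.append(SequenceRecord(id=rid, residues=residues, quality=quality))
        truth[rid] = rt

    return reads, SimulationTruth(per_read=truth, abundance=abundance)


# ---------------------------------------------------------------------------
# Study fixtures


@dataclass
class StudyFixture:
    """On-disk fixture set of one simulated study."""

    outdir: Path
    reference: ReferenceLibrary
    database: ReferenceLibrary
    truth_species: list[str]
    contaminants: list[tuple[str, float]]
    reference_fasta: Path
    taxonomy_tsv: Path
    database_fasta: Path
    database_taxonomy: Path
    fastq_paths: list[Path]
    truths: dict[str, SimulationTruth]
    forward_primer: str


def simulate_study(
    config: SimulationConfig,
    outdir: str | Path,
    model: ErrorModel | None = None,
) -> StudyFixture:
    """Write a complete fixture set: reference FASTA + taxonomy, one FASTQ
    per aliquot, truth tables and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if model is None:
        model = ErrorModel()
    rng = np.random.default_rng(config.seed)

    full = simulate_reference(config, rng)
    all_species = sorted(full.species)
    novel: list[str] = []
    if config.n_novel_species:
        novel = [str(s) for s in
                 rng.choice(all_species, size=config.n_novel_species, replace=False)]
    reference = full.subset(set(all_species) - set(novel)) if novel else full
    database = full

    pool_candidates = all_species if config.truth_includes_novel else sorted(reference.species)
    if config.truth_size is not None:
        truth_species = sorted(
            str(s) for s in rng.choice(pool_candidates, size=config.truth_size, replace=False)
        )
    else:
        truth_species = list(pool_candidates)

    contaminants: list[tuple[str, float]] = []
    if config.n_contaminants:
        outside = sorted(set(reference.species) - set(truth_species))
        picked = rng.choice(outside, size=config.n_contaminants, replace=False)
        contaminants = [(str(sp), config.contaminant_fraction) for sp in picked]

    abundance = draw_abundance(truth_species, config, rng, contaminants)

    reference_fasta = outdir / "reference.fasta"
    taxonomy_tsv = outdir / "reference_taxonomy.tsv"
    write_fasta(reference.records, reference_fasta)
    write_taxonomy(reference.taxonomy, taxonomy_tsv)
    database_fasta = outdir / "database.fasta"
    database_taxonomy = outdir / "database_taxonomy.tsv"
    write_fasta(database.records, database_fasta)
    write_taxonomy(database.taxonomy, database_taxonomy)

    fastq_paths: list[Path] = []
    truths: dict[str, SimulationTruth] = {}
    for a in range(1, config.n_aliquots + 1):
        label = f"aliquot{a}"
        reads, truth = simulate_reads(
            database, config, model, rng, abundance=abundance, label=label
        )
        fq = outdir / f"{label}.fastq"
        write_fastq(reads, fq)
        fastq_paths.append(fq)
        truths[label] = truth
        with open(outdir / f"{label}.truth.tsv", "w") as fh:
            fh.write("read_id\tspecies\tn_hp_errors\tn_substitutions\tchimera\ttruncated\tjunk\n")
            for rid, rt in truth.per_read.items():
                chim = "|".join(rt.chimera_parents) if rt.chimera_parents else "-"
                fh.write(
                    f"{rid}\t{rt.species}\t{rt.n_hp_errors}\t{rt.n_substitutions}\t"
                    f"{chim}\t{int(rt.truncated)}\t{int(rt.junk)}\n"
                )

    with open(outdir / "abundance.tsv", "w") as fh:
        fh.write("species\tfraction\n")
        for sp in sorted(abundance):
            fh.write(f"{sp}\t{abundance[sp]:.8f}\n")
    echo = {
        "config": dataclasses.asdict(config),
        "error_model": dataclasses.asdict(model),
        "truth_species": truth_species,
        "contaminants": [[sp, f] for sp, f in contaminants],
    }
    with open(outdir / "config.json", "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return StudyFixture(
        outdir=outdir,
        reference=reference,
        database=database,
        truth_species=truth_species,
        contaminants=contaminants,
        reference_fasta=reference_fasta,
        taxonomy_tsv=taxonomy_tsv,
        database_fasta=database_fasta,
        database_taxonomy=database_taxonomy,
        fastq_paths=fastq_paths,
        truths=truths,
        forward_primer=config.forward_primer,
    )


# Preset study designs -------------------------------------------------------


def preset_alldna(seed: int) -> SimulationConfig:
    """Every library species pooled at (near) equal abundance."""
    return SimulationConfig(seed=seed)


def preset_zpdna(seed: int) -> SimulationConfig:
    """A 12-species pool from a 30-species library plus one contaminant
    species spiked at 5% of the reads."""
    return SimulationConfig(
        seed=seed, truth_size=12, n_contaminants=1, contaminant_fraction=0.05
    )


def preset_zphts(seed: int) -> SimulationConfig:
    """A natural-community stand-in: part of the community is absent from
    the reference library (but present in the classification database),
    so residual MOTUs appear."""
    return SimulationConfig(
        seed=seed, n_novel_species=6, truth_size=18, truth_includes_novel=True,
        abundance="lognormal",
    )


PRESETS = {"alldna": preset_alldna, "zpdna": preset_zpdna, "zphts": preset_zphts}
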