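# Methods

## Identity engine

Pairwise identity is defined on an optimal global alignment under integer
scoring (defaults: match +2, mismatch −3, gap open 5, gap extend 2, a gap
of length L costing `open + extend·L` — the de facto BLASTN-style
nucleotide settings; the workflow this package re-implements never
published its scoring, so the parameters are exposed on
`IdentityParams`). Identity is identical aligned bases divided by the
shorter sequence length (cd-hit's convention) or, optionally, by alignment
columns.

Optimal alignments are rarely unique, and "number of identical bases"
varies across co-optimal alignments, so identity would otherwise depend on
traceback order. The kernel therefore optimizes the triple
(score, matches, −columns) lexicographically: among score-optimal
alignments it reports the one with the most identical bases, ties broken
toward fewer columns. The triple is packed into a single additive int64
key, which caps supported sequence length at 2000 bp (ample for ~450 bp
amplicons; longer input raises an error rather than silently truncating).
`N` never counts as a match, including `N`–`N` pairs.

The test suite verifies the kernel three ways: against an exhaustive
path-enumerating aligner on tiny inputs, against an independently written
recursive memoized aligner on thousands of random pairs, and against
Bio.Align.PairwiseAligner scores under the equivalent gap convention.

### Edit-distance pre-filter

Clustering at high thresholds skips provably hopeless pairs using the
Levenshtein distance `d` (edlib): any global alignment of sequences with
length difference `D` has at most `shorter − max(0, d−D)/2` identical
bases, because its substitutions + gaps form an edit script of size ≥ d
while the length imbalance accounts for only D of the gaps. Hence
identity ≤ 1 − max(0, d−D)/(2·shorter); pairs with this bound below the
threshold are skipped without aligning. The filter never changes results
(property-tested filter-on vs filter-off) — it only saves time.

## Greedy clustering semantics

De novo clustering processes sequences in decreasing length (ties:
ascending id); the first sequence founds cluster 0. `first_fit` (the de
novo default, matching cd-hit) joins the first representative at or above
threshold in cluster-creation order; `best_fit` joins the
maximum-identity representative, ties to the lowest cluster index.
Reference-guided assignment always uses best identity (species attribution
should be the best hit), ties to the earliest reference record.
Thresholds compare with a 1e−9 epsilon so that "equal to the threshold"
joins despite float representation.

**Cluster counts are not strictly monotone in the threshold.** Raising the
threshold can make an early sequence found its own cluster; as a new
representative it may then absorb several later sequences that would
otherwise each have founded singletons, so the total count can *drop* as
the threshold rises. A four-sequence scheme shows this is inherent to any
greedy incremental scheme (id(B,A)=0.94, id(C,B)=id(D,B)=0.96, all other
pairs 0.80: t=0.93 yields {A,B},{C},{D} but t=0.95 yields {A},{B,C,D}),
and about 2% of generated 8-species libraries realize it within the
0.90–1.00 grid. The engine agrees exactly with a naive quadratic
re-statement of the rule on every tested instance, so the non-monotonicity
is a property of the algorithm, not a defect; the corresponding idealized
invariant is asserted in the acceptance tests and documents this gap when
it fails. Practical threshold sweeps on well-separated species libraries
(the 97–100% grid) are monotone in all observed cases.

## Read filtering

Rules run in order quality → primer → length, one rejection reason per
read: mean Phred < 10 (the single-number reading of the source rule);
more than 2 Hamming mismatches against the forward primer anchored at
position 0 (amplicon reads begin with the primer once adaptors are
clipped; a fixed adaptor string can be clipped first via `adaptor`); and
< 200 bp *after* trimming, since downstream clustering sees the trimmed
read. `N` counts as a primer mismatch. The reverse primer, when
configured, is searched as its reverse complement at the 3′ end and
trimmed if found, but its absence does not reject the read — pyrosequencing
reads routinely end before it. Primer sequences are configuration, not
constants: the marker's published primer pair is run-specific input.

Filtering is idempotent on the quality and length rules; it is *not*
literally idempotent with a forward primer configured, because kept reads
have the primer trimmed away. Re-filtering pipeline output should pass
`forward_primer=None` (tested this way).

## Homopolymer capping

`cap_runs(seq, k)` replaces every maximal run longer than k with exactly
k bases; "beyond 4-mers reduced to 3-mers" is implemented as cap at 3, so
4-mers are also reduced — only that reading makes reads commensurate with
a 3-mer-capped reference. Stepwise reduction (the 5-/4-/3-/2-mer library
series) is cap at n−1 per step and telescopes to a single cap
(property-tested). Capped records drop the quality values of removed
positions (first k per run kept) to preserve the record invariant.

## Threshold optimization

A species is *resolved* when its (single) reference sequence is a
singleton cluster; `resolved_fraction = 1 − (species in multi-member
clusters)/n_species`. The sweep grid defaults to thresholds
{0.97, 0.98, 0.99, 1.00} × caps {uncapped, 5, 4, 3, 2}; identities are
memoized per cap so the grid costs at most one alignment per pair.
`pick_threshold` maximizes resolved fraction, ties to the lowest (most
merge-tolerant) threshold.

## MOTU classification

Residual (unassigned) reads are clustered de novo at 99%; clusters under
10 reads are discarded as likely noise. Representatives are classified by
*local* alignment against an annotated database under the same scoring;
the score gate (> 100, raw Smith–Waterman score) stands in for the
megablast score gate of the original workflow — bit-score constants are
search-tool-version-specific, while a raw-score gate under fixed scoring
is reproducible; both gates are configurable. Identity is matches /
alignment columns (the local-alignment convention). Hits are gated at
identity > 0.90; the top hit is taken by score, and any hit whose
identity rounds (to 0.1%, configurable) to the top hit's identity is
treated as tied. Multi-species ties are assigned the deepest rank shared
by every tied lineage; genus-rank ties are reported as "<Genus> sp.".
The tie rule uses sets, so database record order never affects the
assignment (property-tested).

## Statistics

Spearman's rho is the Pearson correlation of mid-ranks (scipy's
implementation behind the module surface), p-values from the
t-approximation with n−2 df; an exact permutation p (two-sided) is
available for n ≤ 8. Constant vectors and n < 3 raise instead of
returning NaN. Read profiles keep zero counts for undetected library
species so aliquot comparisons share a domain. Detection uses a
configurable minimum read support (default 1; 5 and 10 reproduce the
usual what-if floors; both detection rate and the unexpected-species set
are monotone non-increasing in the floor).

Correlations use raw read counts, not proportions; with equal aliquot
totals Spearman is insensitive to the distinction, and raw counts avoid
committing to a compositional model.

## Synthetic data

The generator emulates the study design the pipeline assumes:

* **Library**: a random root (~450 bp, with 8 seeded homopolymer runs of
  4–6 bp — the marker's indel-prone slippage structure) evolved along a
  random bifurcating tree. Terminal and internal branch substitution
  rates are retuned multiplicatively (≤ 12 attempts) until all realized
  pairwise identities, measured by the alignment engine, fall within the
  configured range (default 0.90–0.98, ± 0.005 tolerance): congeners near
  the top of the range make the 98–99% thresholds discriminative, as in
  the real marker. Taxonomy derives from tree depth (clades → phylum /
  class / order / family; the leaf's parent clade is its genus), so
  sibling species share a genus and LCA behaviour is constructible.
* **Reads**: per read, a source species from the abundance vector; a
  single-breakpoint two-parent chimera with probability 0.01 (PCR
  artifact rate, order-of-magnitude); run-length miscalls — each maximal
  run of length k is ±1 base with probability 1 − accuracy(k), where
  accuracy is log-linearly interpolated between the anchors (3, 0.99) and
  (9, 0.64) and extrapolated beyond with the final slope, clamped to
  [0, 1]; substitutions at 0.002/base (typical pyrosequencing point-error
  scale); the synthetic forward primer prepended (errors apply to it
  too, yielding realistic primer-mismatch rejects); 5% of reads truncated
  and 1% emitted as low-quality junk to exercise the length and quality
  rules. Qualities are drawn high (Phred 30–40) and degraded near
  miscalled runs.
* **Abundance**: `uniform` emulates equimolar pooling and is the default
  (it makes detection and exact-recovery statements sharp); `lognormal`
  (σ = 1) emulates the strong amplification skew real equimolar pools
  exhibit and is what makes aliquot *rank* reproducibility measurable —
  under uniform abundances, replicate ranks are pure noise and Spearman ρ
  is near zero by construction.
* **Aliquots** are independent multinomial draws from one shared
  abundance vector (technical replicates of one amplicon pool).

What it does **not** model: flowgram-level signal, PCR-cycle-explicit
amplification (skew is imposed directly), run-length slips of more than
±1, primer-binding-site divergence across taxa, and intragenomic rDNA
copy variation. Passing tests therefore demonstrate correctness of the
analysis chain under the stated error structure, not performance on any
particular real community.

Determinism: every simulation consumes one `numpy` Generator seeded from
the config; identical seeds give byte-identical fixtures (tested).

## Problem sizes

Tests and the acceptance script use 30-species libraries with 2 × 2000-read
aliquots for pipeline studies, 8-species/200 bp libraries for sweep
properties, 200 random ≤ 12-sequence instances for oracle equivalence, and
10,000 trials per run length for error-model calibration — sizes chosen so
the whole suite completes in well under a minute of alignment work while
keeping every statistical assertion comfortably powered.

## Known limitations

* No chimera removal: the simulator creates chimeras, the pipeline does
  not filter them (they mostly fail the 99% identity gate and land in the
  unassigned pool, occasionally seeding small MOTUs).
* Greedy cluster counts are order-dependent and only statistically
  monotone in the threshold (above).
* The identity engine is exact but quadratic per pair with no k-mer
  heuristic; it is sized for reference libraries and filtered amplicon
  sets (memoization collapses duplicate reads), not for millions of
  unique sequences.
* Read abundances are proxies for template + amplification effects;
  nothing here supports inferring organismal abundance from read counts.
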