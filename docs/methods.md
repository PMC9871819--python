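# Methods

This note documents the models, procedures, parameters and numerical
choices behind `ftszprov`. The package implements a comparative-genomics
workflow for tracing the origin of paralogs inside a modular protein family
(the FtsZ/tubulin superfamily is the motivating case): collect homologs
with a profile HMM of the family's shared N-terminal domain, curate a
taxonomically balanced dataset, build trimmed-alignment phylogenies with
bootstrap supports, profile the genomic neighborhoods of the focal genes,
and test C-terminus provenance by anchored tail extraction and
thresholdless HMM cross-search. Because the original analysis runs over a
corpus of tens of thousands of annotated genomes and external binaries, the
package ships a simulator of family evolution that reproduces the study's
*conditions* at desk scale with full ground truth, and every capability is
validated against that truth or against independent oracles.

## Profile HMMs

The model is the classic match/insert/delete profile HMM with position-
specific match emissions, background insert emissions, and per-position
transition distributions (each outgoing set sums to 1). Scores are
log2-odds ("bits") against an i.i.d. background (Swiss-Prot-style residue
frequencies). `X` is accepted as an unknown residue and scores log-odds 0.

**Local alignment wrapper.** In the default local mode the core model may
align to any target substring. Entry/exit is uniform over (first, last)
match-state pairs with weight `2/(M(M+1))`, and the flanking residues are
emitted by a background wrapper whose loop probability mirrors the null
model, leaving a net `log2(2/(L+2))` length term. With this wrapper the
model assigns at most unit total probability mass, so the expected odds
ratio on background sequences is bounded by 1 and null bit scores center
below zero — the property that makes E-values meaningful. A glocal mode
(global in the model, free flanks in the target) is available by flag; its
scores are not calibrated-comparable to local scores.

**Construction.** Alignment columns whose non-gap fraction meets the
occupancy threshold (default 0.5) become match states. Match emissions are
`(counts + w·background) / (n + w)` with pseudocount weight `w` (default 1);
transitions are counted from each row's implied state path and Laplace
smoothed (+1). Insert residues outside the first/last match columns are
treated as flank, not model.

**Viterbi and envelopes.** The best-path alignment uses the same state
space with deterministic tie-breaking: match preferred over delete over
insert, and the leftmost placement among equal-scoring alternatives. The
hit envelope is the span of target positions emitted by match/insert states
on the best path; it anchors the C-terminus extraction.

**Calibration and E-values.** E-values follow HMMER semantics:
`E = db_size · P(S ≥ s)` with `db_size` the number of sequences searched in
the invocation (which makes the null self-consistency check below exact).
`P(S ≥ s)` comes from a Gumbel law fitted to forward bit scores of
`n_random` (default 1000) background sequences whose lengths are
Normal(mean family length, 0.2·mean) truncated at 30. Numerical choice:
the fit is a *right-censored* maximum-likelihood Gumbel — observations
below the 75th percentile enter the likelihood only through the cdf. Full-
sample MLE weights the bulk of the distribution, where forward null scores
deviate from the Gumbel limit, and misestimates exactly the tail that
E-values are computed from; the censored fit recovers parameters of true
Gumbel samples within ±0.1 (location) and ±0.05 (rate) at n = 5000 and
keeps held-out null hit counts at E ≤ 1 inside the 99% binomial envelope.

**Forward recursion.** The forward pass is exact (no acceleration
filters); the within-position delete chain is computed in log space with a
cumulative-transform scan so the whole recursion vectorises across a batch
of target sequences. Equivalence with an exhaustive enumeration of all
local alignment paths is asserted to 1e-9 bits for all models with M ≤ 3
and targets up to 6 residues (randomized battery of 100 cases).

## Alignment

`pairwise_global` is Needleman–Wunsch with affine gaps (BLOSUM62, gap open
−11, gap extend −1 by default; a gap of length k costs `open + (k−1)·extend`)
with the tie order diagonal > up > left. `progressive_align` builds a UPGMA
guide tree from 3-mer cosine distances over records sorted by id (so the
result is independent of input order for distinct sequences) and merges
profiles up the tree with the same affine DP over average-pairwise column
scores; once aligned, two residues never change relative alignment. The
horizontal gap state of the affine DP is computed with a running-maximum
transform, which is exact because re-opening a gap from within a gap is
dominated by extension whenever open ≤ extend. An adapter hook can delegate
to an external aligner executable; its FASTA output is subjected to the
same invariants (every row must ungap to its input).

The aligner recovers ≥ 90% of true residue-homology pairs on simulated
families with branch lengths ≤ 0.3 — sufficient for the distance
phylogenies here, but it does no iterative refinement and will degrade on
deeply diverged tails; that is why tail *models* (profile HMMs), not tail
alignments, carry the provenance test.

## Curation

* **Coverage filter:** keep rows with ≥ 60% non-gap characters relative to
  the full alignment length (inclusive boundary).
* **Redundancy by taxonomic class:** greedy length-sorted clustering;
  a sequence joins the first representative with pairwise identity at or
  above the class cutoff. Identity is matches over global-alignment length
  (gaps count in the denominator) — an approximation of CD-HIT's behaviour
  without its word filters. The cutoff is 0.95 for classes of ≤ 20
  sequences, 0.55 at ≥ 250, and linearly interpolated (rounded to 2
  decimals) in between; only the endpoints are prescribed, the linear
  completion is the simplest monotone choice and is exposed in config.
* **One per order:** a uniformly random pick per taxonomic order under the
  stage seed, with an include-list that forces retention of named ids.
* **Gap-threshold trimming** (trimAl `-gt` semantics): keep columns whose
  non-gap fraction is ≥ gt; the workflow uses 0.7 (collection), 0.2
  (phylogeny), 0.1 (soft trim for tail models).
* **Entropy trimming** (BMGE-inspired, deliberately not bit-compatible):
  per column, residue counts are absorbed into the most frequent residue
  they share a positive similarity score with (strictly more frequent, ties
  alphabetical), and the normalised Shannon entropy of the merged
  distribution is the column score in [0, 1] — 0 for conserved columns, 1
  for a uniform column. Columns are removed when the raw or window-3
  smoothed score exceeds `h` (default 0.55; conserved columns are immune to
  smoothing) or when the gap fraction exceeds 0.2. The default similarity
  matrix is BLOSUM45, the lowest-stringency BLOSUM available in the
  environment's matrix collection.
* **Merging:** profile–profile alignment of two alignments; within-profile
  columns are preserved exactly (only shared gap columns are inserted).

## Phylogenies

Pairwise distances are `d = −ln(1 − p − 0.2 p²)` (Kimura's protein
correction) over mutually ungapped columns, with a documented saturation
ceiling of 5.0 substitutions/site at p ≥ 0.85 where the correction is
undefined. Trees come from Saitou–Nei neighbor joining with two
deterministic rules: equal-minimum Q entries resolve to the smallest index
pair, and negative branch lengths are clamped to zero with the deficit
moved to the sibling edge. NJ is exact on additive matrices (asserted on a
randomized battery: RF distance 0 and distance round-trip on 50 random 5–8
leaf trees).

Supports are column-resampling bootstrap percentages: each replicate
resamples alignment columns with replacement, rebuilds the NJ tree, and an
internal edge's support is the percentage of replicates containing the same
bipartition. Maximum-likelihood inference is out of scope by design; an
externally computed Newick tree with support labels can be read in and
drives rooting, collapsing and annotation identically.

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path (ties: lexicographically smallest leaf pair) and is checked against a
brute-force property (root height equals half the tree diameter). Collapse
contracts internal edges below a support threshold into polytomies,
discarding the contracted length; the workflow's display threshold is 85%,
configurable because no single threshold is canonical. iTOL color-strip and
heatmap dataset files are emitted as plain text and round-trip parse.

## Genomic context

Windows span the focal gene ± 5 kb (configurable; the figure-level
description of the source workflow mentions a 10 kb flank but its
operational methods state 5 kb up/downstream, which is adopted). Gene
coordinates are an input contract (1-based inclusive in tables, 0-based
half-open internally); gene calling is not reimplemented. A neighbor is any
gene overlapping the window by ≥ 1 bp — boundary genes are kept rather than
silently dropped; a gene whose half-open end equals the window start does
not overlap. Neighbors are annotated with a domain-HMM library at E ≤ 1e-3
and counted presence-only: a domain counts once per genome regardless of
repeats within a protein, within a neighborhood, or across multiple focal
copies in the same genome. The abundance table is domains × clades with
genome counts, and the ranking keeps the top k = 25 domains (ties
alphabetical).

## C-terminus provenance

For each phylogenetic group of interest, member tails are extracted
starting at the end of the N-terminal domain's Viterbi envelope (anchor
required at single-sequence E ≤ 1e-3; anchorless members are recorded and
skipped; tails shorter than 20 residues are discarded — a minimum the
source workflow leaves unstated but without which tail models are
meaningless). Tails are aligned, soft-trimmed at gt = 0.1, built into a
profile HMM and calibrated. The cross-search runs every group model against
every collection member with *no* E-value threshold; the dense model ×
target E-value matrix serialises losslessly and is mapped onto the
reference tree as an iTOL heatmap with decade bin edges
(1e-10, 1e-5, 1e-3, 1e-1) bracketing the strong/weak/marginal strata the
analysis distinguishes. The provenance report aggregates per
(family × taxonomic-domain) stratum — median and minimum E-value and the
fraction of targets at E ≤ 1e-3 — and flags strata whose median E-value is
≤ 1e-2, the weakest stratum still read as a provenance signal.

## The simulator

The synthetic corpus defines the study conditions; everything downstream is
validated against its ground truth.

* **Species tree:** a birth-only (Yule) tree, rescaled to unit root height
  (so branch lengths are fractions of the total divergence depth), with
  taxonomy assigned by cutting at fixed depths — phylum 0.25, class 0.5,
  order 0.75 — and the two root children tagged as taxonomic domains (the
  larger clade is "Bacteria_like"). Depth-cutting keeps the generator
  self-contained; no external taxonomy is consulted.
* **Deep-split constraint for scenarios:** the histories being emulated
  presuppose two substantial domains separated by an ancient divergence, so
  the duplication and provenance scenarios draw trees until the minority
  root clade holds at least 5 of 32 (resp. 4 of 24) genomes and both stems
  span ≥ 0.15 of root height (deterministic sub-seed redraws). Unconstrained
  Yule draws frequently place the root split inside the radiation or leave
  1–2 "archaeal" genomes, which contradicts the emulated history and makes
  the group analyses undefined.
* **Family architecture:** one conserved N-terminal domain (200 residues,
  conservation 0.95 high / default 0.85) plus a variable C-terminal tail
  (100 residues, conservation 0.55), matching the real family's ~300-residue
  members. A segment's substitution rate is `1 − conservation`.
* **Substitutions:** a single fixed reversible exchangeability matrix
  derived from BLOSUM62 target odds (`s_ij = 2^(score_ij/2)`) with the
  background frequencies, scaled to one expected substitution per site per
  unit branch length and applied through its eigendecomposition. The
  simulator's divergence is validated against an independent jump-process
  (Gillespie) sampler of the same process to within 2 percentage points of
  identity.
* **Indels:** Poisson at 0.02 per expected substitution, geometric lengths
  (p = 0.7), never inside the first 10 residues of the N-terminal segment
  so the anchor always exists; deletions never empty a segment.
* **Homology truth:** every residue carries a site id threaded through
  substitutions and indels, with a global column order maintained at
  insertion time — the true alignment of any record subset is
  reconstructable, as are segment boundaries and per-segment identities.
* **Events:** duplication (copies a lineage with new paralog labels), loss,
  lateral transfer (the donor lineage is grafted into the recipient subtree;
  the transferred copy departs from the donor's state at the end of the
  donor branch — a documented simplification), and C-terminus swap (replaces
  everything after the N-terminal segment with a fresh random tail lineage
  and a new ancestry label). Events are validated against the tree (branch
  existence, on-branch times, donor/recipient coexistence).
* **Genomes:** each genome is one contig; each focal copy is embedded in
  its clade's neighborhood template (domain id, preceding gap, optional
  strand; strands alternate by default). Neighbor proteins are noisy copies
  (10% mutation) of a per-domain consensus derived deterministically from
  the domain name and the corpus seed; the matching HMM library is built
  from noisy training copies of the same consensus.

What the simulator does *not* emulate: population-level processes,
nucleotide sequences and codon structure, rate heterogeneity across sites
within a segment, compositional bias, domain rearrangements beyond the
single tail swap, and realistic intergenic architecture. Passing the
simulation batteries therefore demonstrates that the pipeline's inferential
machinery recovers known histories under clock-like, composition-neutral
evolution — not that it is robust to the alignment artifacts,
long-branch-attraction and biased sampling that real data add.

## Pipeline and reproducibility

Stages run in a fixed order (collect → curate → align/trim → tree →
context → cterm), each writing its artifacts plus a manifest (sha256
checksums, stage seed, version) into its own subdirectory. Per-stage seeds
are derived from the root seed and a fixed stage index, so toggling a stage
never shifts another stage's random stream; two runs with the same config
are byte-identical (text outputs use LF and 6-significant-digit floats;
the exact HMM and hit-matrix serialisations use 12 and 17 significant
digits respectively, the latter so E-value matrices round-trip exactly).
The `--threads` option affects wall time only and is currently accepted for
interface stability.

## Problem sizes

The bundled experiments run at the following sizes, chosen so the full
battery completes on a single CPU in minutes: duplication recovery on 32
genomes with 100 bootstrap replicates and 20 seeded replicates; C-terminus
provenance on 24 genomes with 20 seeded replicates; genomic-context
contrast on 20 genomes; calibration at 1000 null sequences (5000 for the
parameter-recovery check); oracle batteries of 50–100 randomized cases.

## Known limitations

* NJ + Felsenstein bootstrap is a deliberate stand-in for ML inference;
  deep, rate-heterogeneous splits that the source analysis resolves with
  complex mixture models are outside what this tree engine can adjudicate.
* The entropy trimmer is BMGE-inspired, not BMGE-compatible.
* Identity-based clustering is quadratic in class size — adequate for
  curated toy corpora, not for tens of thousands of sequences.
* One best envelope per target: multi-domain architectures on a single
  target are not parsed separately.
* The E-value calibration is per-model and per-invocation; scores from
  different models are comparable only through their E-values.
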