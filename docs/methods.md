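# Methods

## Overview

`mirfuse` classifies ~70-nt RNA windows as pre-miRNA hairpins or not by
fusing the binary decisions of four feature-based base classifiers with a
small feed-forward network, and scans metagenomic contigs with that ensemble.
This note records the model, its assumptions, the parameters that matter,
what the synthetic data emulate, and the numerical choices and limitations.

## Secondary-structure prediction

All features are defined over a predicted pseudoknot-free secondary
structure in dot-bracket form. Two backends are provided:

* **builtin-nussinov** (default): maximizes the number of base pairs
  (Watson–Crick plus G·U wobble) subject to a minimum hairpin loop of 3
  unpaired nucleotides, with a surrogate energy of −1.0 kcal/mol per pair.
  The DP fill is O(L³) (JIT-accelerated when numba is importable, with an
  equivalent pure-Python fallback); traceback is deterministic — at each
  open interval the 5′-most nucleotide is paired with its 5′-most admissible
  optimal partner, so every downstream feature value is reproducible.
  Correctness is tested against exhaustive enumeration of all admissible
  structures for short sequences.
* **external-mfe**: shells out to ViennaRNA's `RNAfold` for thermodynamic
  MFE structures. The feature definitions are backend-agnostic; the builtin
  backend is the default so that no external software is required and all
  shipped tests are self-contained.

Assumption: one structure per sequence suffices. Suboptimal ensembles,
nearest-neighbor thermodynamics and pseudoknots are out of scope. Because no
folding-engine version or temperature is pinned by the published parameter
set, analyses that depend on exact MFE values cannot be matched bit-exactly
across engines; all in-package comparisons therefore fix the backend.

Multi-branched structures are *not* rejected by default; a
`single_loop_only` switch (using the terminal-loop counter) restricts
classification to single stem-loops when desired.

## Feature spaces

* **triplet32** — per 3-nt window, the bracket-normalized structure pattern
  (`')'`→`'('`; 8 patterns) × one nucleotide identity; 32 bins, normalized
  by the window count L−2. The identity used is the **middle** nucleotide of
  the window; the convention is isolated in the ordering constants
  (`TRIPLET_LABELS`) so it is auditable in one place.
* **hybrid34** — triplet32 plus the structure's MFE (kcal/mol, raw — not
  length-normalized) and the Monte-Carlo P-value.
* **seqstruct512** — trinucleotide (64) × 3-bit paired/unpaired code (8);
  512 bins, labelled like `AUG001`. Normalization by L−2 is applied to both
  count vectors before classification (it keeps RBF-SVM kernels
  scale-invariant across sequence lengths); raw counts remain available via
  the `normalize` flag. The fixed lexicographic label orders define the
  on-disk TSV column order; the reader tolerates reordered columns by
  matching labels.

**Monte-Carlo P-value.** The fraction of dinucleotide-shuffled copies whose
MFE is *strictly* lower than the original's (ties count as not lower), so
p ∈ [0,1] and a homopolymer has p = 0. Shuffling uses Euler-path sampling
(Altschul–Erickson): a random arborescence toward the terminal nucleotide
fixes each vertex's last outgoing edge, the remaining edges are permuted
uniformly, and the path is re-walked. This preserves the exact multiset of
overlapping dinucleotides and both terminal residues, and can reach every
valid shuffle. Default `n_shuffles = 1000`; the test suite and the
acceptance script use 15–25 shuffles per sequence, which is sufficient to
separate designed stems from shuffles at their effect size while keeping
runtimes in seconds.

## Base committee

Surrogates with the canonical algorithm/feature-space pairings are trained
on user or synthetic corpora (the original published models are not
redistributable): an RBF-SVM on triplet32, a random forest on hybrid34, and
two RBF-SVMs on seqstruct512 that differ only in training corpus — on
synthetic data they receive disjoint stratified halves, mirroring the viral
vs. broad-eukaryote provenance of their archetypes. Defaults: SVM cost 1.0
and kernel width 1/n_features; forest of 500 trees; all hyperparameters and
seeds are recorded in model metadata and in the serialized model header.
An optional training mode performs 5-fold model selection keeping the
fold-model of maximal validation specificity; it is off by default.

Each base emits a hard decision: the sign of its margin (SVM decision
function; signed vote fraction for the forest), with a score of exactly 0
mapping to +1. The ensemble consumes hard ±1 decisions by default — the
committee's real-valued margins are retained in `DecisionVector.scores` for
users who want them — because mixing four incomparable margin scales into
one linear solve would implicitly re-weight the bases by margin magnitude.

## Fusion network

Architecture 4-3-1: logistic sigmoid hidden units, linear output, 19
parameters (12 hidden weights + 3 hidden biases + 3 output weights + 1
output bias). Inputs are the ±1 base decisions (a {0,1} encoding is
available via re-encoding before the call); teaching targets are ±1.

Training is extreme-learning-machine style. Per restart, hidden weights and
biases are drawn i.i.d. uniform(−1,1); with H the n×3 hidden activation
matrix, the output layer solves min‖[H|1]β − y‖² via `numpy.linalg.lstsq`
(rank-revealing SVD pseudo-inverse with the default singular-value cutoff).
Fifty restarts by default; the network with minimal SSE is selected and the
full per-restart SSE trace is kept in the `TrainingRecord`. Consequences
asserted in the tests: the normal-equation residual vanishes (≤1e−8 at
n = 1000), and with full-rank activations the network interpolates up to 3
distinct samples exactly (SSE ≤ 1e−12).

A frozen published 4-3-1 parameter set ships as `data/table2.json` and loads
via `table2_network()`. Its sign convention cannot be verified from the
published record (with all-positive inputs its score is negative), so
`classify` exposes `threshold` and `polarity` as configuration, with
`calibrate_polarity` choosing the accuracy-maximizing orientation on a
labeled set; the default is score ≥ threshold → +1, ties inclusive.

## Evaluation

The six statistics are computed exactly from TP/TN/FP/FN and reported as
percentages; a zero denominator yields `nan` plus a warning, never a silent
0. Rounding (1 decimal) happens only in the reporting layer.

The ROC is built by a single linear scan over score-sorted samples, one
point per distinct score (ties grouped, producing diagonal segments),
anchored at (0,0) for threshold +∞ and (1,1); trapezoidal AUC equals the
Mann–Whitney concordance with ties at ½ (property-tested against a
brute-force pairwise oracle and against scikit-learn). The AUC standard
error uses DeLong placement values V10/V01 with sample variances
(ddof = 1), and the 95% CI is AUC ± 1.96·SE clipped to [0,1] — a plain
normal approximation, no logit transform.

## Mining pipeline

Windows of 70 nt at 1-nt shift (both configurable); a contig of length L
yields max(0, ⌊(L−70)/step⌋+1) fragments. T→U transcription at ingest;
windows containing ambiguity codes are counted and excluded from
classification rather than guessed. Only the given strand is scanned by
default (`both_strands` adds the reverse complement, reported in forward
coordinates). Internally coordinates are 0-based half-open; the TSV report
is 1-based inclusive and says so in its header. Overlapping positive
windows — near-duplicates by construction at 1-nt shift — can be merged
into regions with `merge_candidate_windows` (off by default). The whole run
is deterministic given the config seed and input order.

## Synthetic data

The generators emulate, and do not reproduce, real corpora:

* **Positives**: 5′ arm drawn at the target GC fraction, random loop, 3′ arm
  as the reverse complement with mismatches injected at `mismatch_rate`.
  Defaults — stem 22 bp, loop 8 nt (52 nt total, in the published 60–70 nt
  precursor ballpark), 10% mismatches, GC 0.5 — give long imperfect stems
  with low surrogate MFE, like genuine precursors.
* **Negatives**: matched length and composition, either dinucleotide
  shuffles of fresh hairpins (default) or codon-structured random sequence
  with no in-frame stop codons, emulating coding-region provenance.
* **Planted contigs**: uniform random DNA with hairpin DNA inserted at
  recorded loci and a BED-like truth sidecar, shaped like the 20-contig
  samples the mining stage targets.
* **Committee tables**: truth at a set prevalence; each classifier flips it
  with 1−sensitivity or 1−specificity; an agreement parameter makes all four
  classifiers share a single error draw with that probability — the simplest
  mechanism spanning independent to identical error regimes without changing
  marginal rates.

Dataset defaults mirror the published 500 positive / 1000 negative
composition. What passing tests on these data do show: the feature spaces
separate strong stems from matched-composition non-stems, the surrogates
learn that separation, fusion does not lose accuracy relative to the best
base, and the pipeline recovers planted signals end to end. What they do not
show: performance on real miRBase/RefSeq corpora, whose negatives are
genomic hairpins far harder than shuffles, and whose positives carry family
structure, bulges and species biases the generator does not model. Published
benchmark figures on the authors' corpora are therefore not reproduced here,
only the formulas and worked examples that are corpus-independent.

## Problem sizes

The shipped test suite and `scripts/acceptance.py` run at desk scale as the
package's own choice of benchmark size: corpora of 100–300 sequences,
15–25 Monte-Carlo shuffles, 20 planted contigs of 150 nt, ELM problems up to
n = 5000. All generators accept larger sizes unchanged; `gen_dataset`
defaults to the full 500/1000 composition.

## Known limitations

* The builtin fold maximizes pair count, not free energy; its "MFE" is a
  surrogate (−1/pair) suitable for ranking and shuffling tests, not for
  thermodynamic interpretation.
* The frozen published fusion network's decision polarity/threshold must be
  calibrated on labeled data before use; it is configuration, not a fact the
  package can derive.
* Surrogate base classifiers trained on synthetic corpora stand in for the
  original published models; absolute performance numbers on real data are
  corpus-dependent and not claimed.
* Mature-miRNA (22-nt) localization within candidate hairpins, homology
  validation, and reverse-complement-aware deduplication of merged regions
  are out of scope.
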