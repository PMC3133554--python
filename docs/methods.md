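# Methods

## Problem and model

Linear (continuous) B-cell epitopes are short stretches of a protein chain
that antibodies can bind directly.  `epitopescan` predicts them in two stages:

1. **Peptide stage.**  A soft-margin kernel SVM classifies fixed-length
   peptides (default 15 residues) as antigenic (+1) or not (−1).  The decision
   rule is the sign of the real-valued decision score; an exact zero is
   reported as a third, indeterminate verdict and counted as non-positive in
   confusion tables.  To find epitopes in a whole protein, every full window
   (length *w*, step *s*; defaults 15 and 1) is featurized and scored
   independently; there are ⌊(L−w)/s⌋+1 windows and no partial windows at the
   termini.
2. **Region stage.**  For an arbitrary-length protein region the window-score
   list from stage one is collapsed to a fixed-length summary vector, and a
   second SVM (RBF kernel by default) predicts whether immunizing with the
   whole region yields a specific immune response.  Because the summary has
   fixed dimension, regions of any length ≥ *w* are handled without structural
   information.

## Feature system

A peptide of length L is encoded by six concatenated blocks (53,633 features
when all are enabled):

| block | dim | content |
|---|---|---|
| ngram | 53,129 | cumulative multiset n-grams, orders 1–5 |
| pssm | 400 | identity × conservation-column grid of mean PSSM percentages |
| ss | 63 | identity-averaged H/E/C probabilities + 3-state composition |
| acc | 20 | identity-averaged solvent accessibility |
| disorder | 20 | identity-averaged disorder probability |
| seg | 1 | fraction of low-complexity residues |

The n-gram block treats every contiguous window of length k as a *multiset*
(canonicalized by sorting its residues), so the index space is all residue
multisets of size ≤ 5 — combinations with repetition, giving the cumulative
dimension ladder 20, 230, 1770, 10625, 53129 — and counts are divided by the
number of windows L−k+1 so peptides of different lengths are comparable.  The
encoding is deliberately compositional rather than positional: it is invariant
under peptide reversal, and each realized order sums to 1.

The annotation blocks average per-residue signals within each residue
identity: the PSSM block averages the 20 weighted-observed-percentage columns
(divided by 100 so all raw features live in [0, 1]); the secondary-structure
block averages the (helix, strand, coil) probability triple per identity and
appends the fractions of peptide residues assigned to each state; accessibility
and disorder contribute one identity-averaged value each; low complexity one
scalar for the whole peptide.  All identity-averaged blocks are invariant to
any permutation of peptide positions that preserves the residue–annotation
pairing.  Features are computed on the original epitope span, never on
extension context.

The best-performing combination (`BEST_FEATURE_BLOCKS`) is n-grams + PSSM +
secondary structure + accessibility; disorder and seg are implemented and
available but excluded from the default pipeline configuration.

## Annotations

Five per-residue inputs are parsed from the text formats the common predictors
emit: PSI-BLAST ASCII PSSMs (the *second* block of 20 score columns — the
weighted observed percentages, which carry the conservation signal; the first
20 are log-odds), `.ss2`-style 3-state secondary structure (file column order
coil, helix, strand; configurable), 20-class relative solvent accessibility
(class percentage / 100 collapses the 20 states to one scalar in [0, 1]),
per-residue disorder probabilities, and seg-masked FASTA (lowercase =
low-complexity).  Parsers tolerate whitespace variation only; structural
deviations raise rather than guess.  Every parser has a paired writer and
round-trips exactly.

## Training and evaluation protocol

* Datasets are deduplicated before training: one record per distinct peptide
  string, and peptides observed with both labels are removed entirely
  (conflicting labels poison training).
* Variable-length database epitopes are brought to the training length by a
  centered crop/extension inside the parent protein; the left side receives
  ⌊deficit/2⌋ and, when a terminus is reached, the remainder comes from the
  other side.  Coordinates are 1-based inclusive throughout, matching the
  annotation file numbering.
* Features are min–max scaled to [0, 1] on the training set; test values may
  fall outside and are not clipped; constant features map to 0.  In
  cross-validation the scaler is refitted inside every training split, so no
  test-fold information leaks into the scaling (asserted by a sentinel-feature
  test).
* Evaluation is stratified 5-fold CV; the headline report pools out-of-fold
  confusion counts and scores (per-fold reports are retained).  AUC is the
  rank-based (trapezoidal) area under the ROC with ties averaged.

## Numerical and design choices

* **Kernels.**  C defaults to 1.0 and gamma to 1/dimension; both are exposed.
  `coef0` defaults to 1, i.e. the inhomogeneous polynomial kernel
  (γ⟨x,y⟩+1)^d.  With γ = 1/53,633 a *homogeneous* cubic kernel would collapse
  to ~10⁻²⁰ magnitudes and degenerate the optimization; the +1 constant keeps
  the kernel well-scaled (it is ignored by the linear and RBF kernels).
* **Sparse pipeline.**  Vectors are sparse maps over the fixed global index
  layout (most of the 53,633-dim n-gram space is empty); the scaler transform
  preserves sparsity, adding explicit offsets only for columns whose training
  minimum is nonzero.  The SVM solver is delegated to an established
  implementation (libsvm via scikit-learn); the package's own contributions are
  the feature system, the protocol, the scanner and the two-stage
  architecture.
* **Top-window reporting.**  Adjacent scan windows are nearly identical, so
  the raw top-k windows of a scan are usually k one-residue shifts of a single
  site.  `top_windows` therefore applies greedy non-maximum suppression by
  default (each selected window removes the windows overlapping it), naming k
  distinct candidate sites; `call_epitopes` returns the plain score-sorted
  list of all positive windows, with ties broken by position.
* **Peptides longer than the window** are summarized by their maximum window
  score — the existential reading of "this peptide contains a good epitope".
* **Region summaries.**  The region feature vector is q = 20 evenly spaced
  empirical quantiles of the window-score list plus five order statistics
  (mean, max, min, fraction of positive scores, longest positive run as a
  fraction of the scan).  The encoding uses only scan scores and has fixed
  dimension for any region length; it is pluggable so alternative summaries
  can be dropped in.
* **Degenerate inputs.**  Sequences shorter than the window, annotation/
  sequence length mismatches, single-class training sets, empty score lists
  and malformed annotation rows all raise typed errors rather than returning
  partial results.

## Synthetic data: what it emulates and what it does not

No real epitope corpus or predictor output ships with the package; generators
produce data with known planted signal so every stage has a recovery-style
test.

* **Peptides.**  Positives are drawn with residue frequencies shifted toward a
  configurable enriched set (default D, E, K, N, Q, S, G, P — approximating
  classical hydrophilicity/turn-propensity scales, so the planted signal is
  biologically flavored).  Enriched residues get weight 1 + 4·effect_size;
  at effect size 0 both classes are exactly uniform.
* **Annotations.**  Synthetic annotations shift coil probability (Dirichlet
  concentration 2,2,2+8·bias), accessibility (Beta, mean 0.5 → 0.85) and
  disorder (Beta, mean 0.3 → 0.8) upward with the label bias; PSSM rows are
  Dirichlet draws concentrated on the true residue.  All values are emitted on
  the exact grids the file writers print, so write→parse round trips are
  bit-exact.
* **Proteins and regions.**  Background sequence at bias 0 with positive-class
  15-mers spliced at non-overlapping seeded positions (sorted draws in the gap
  coordinate system guarantee feasibility); a truth table records the planted
  intervals.  Regions are length 100; positives contain the planted epitopes,
  negatives none.

All randomness flows from a single seed through one named generator; identical
configurations produce byte-identical outputs.

What passing recovery tests show: the pipeline detects a strong, known
compositional + structural signal at realistic dimensionality, and detects
nothing when the signal is absent.  What they do not show: performance on real
epitope data, which has correlated residues, homology structure between
entries, label noise from heterogeneous assays, and PSSMs with real family
statistics — none of which the generators emulate.  Published headline
figures on curated corpora are therefore not comparable to the synthetic
recovery numbers.

## Problem sizes

The shipped experiments use desk-scale sizes chosen once: 400+400 peptides of
length 15 at effect size 0.8 (chance-level controls at effect size 0, three
seeds); 60 proteins of 200 aa with 2 planted epitopes each for scan recovery;
150+150 regions of length 100 for the region stage.  These are stated here as
the package's study conditions.

## Known limitations

* The region-summary encoding is one reasonable choice among several; only
  scan-score information is used, as intended, but the specific statistics are
  a package design decision.
* Discontinuous/conformational epitopes are out of scope by construction.
* The synthetic annotation model draws residues independently; it does not
  reproduce the spatial autocorrelation of real secondary-structure or
  disorder tracks.
* Class weighting for imbalanced corpora is not applied by default; pass a
  larger C or resample externally if needed.
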