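# Methods

This note documents the modelling choices behind `aippred`: what each
stage computes, the defaults and why, what the synthetic generator does
and does not emulate, and the numerical conventions that differ between
implementations in this field.

## Problem setting

The task is binary classification of short peptides (typically 5–30
residues over the 20 canonical amino acids) into anti-inflammatory (AIP)
and non-anti-inflammatory classes from sequence alone. The signal
exploited is compositional: AIPs are enriched in leucine, lysine and
arginine and in aliphatic/basic dipeptides, while inactive peptides are
enriched in aspartate, glycine, valine, tyrosine and proline and in
acidic-led dipeptides. The pipeline therefore encodes composition,
selects the informative components, and fits a forest-based classifier.

## Encoders

**AAC / DPC.** Per-residue and per-ordered-dipeptide frequencies. The DPC
denominator is the number of overlapping dipeptides in the sequence,
L−1, so every vector sums to one; dividing instead by the constant 400
is a uniform rescaling offered as `denominator="constant"` but never the
default, because a constant denominator would leak sequence length into
every feature.

**AAI.** Eight high-quality AAindex scales (BLAM930101, BIOV880101,
MAXF760101, TSAJ990101, NAKH920108, CEDJ970104, LIFS790101, MIYS990104)
are bundled as plain-text data. Each scale is min–max normalized to
[0, 1] over the 20 residues before averaging, so scales with large
numeric ranges (e.g. residue volumes) cannot dominate; the encoding is
AAC(i) × mean normalized scale value of residue i, which is
20-dimensional and length-independent. The scale values were transcribed
from the published AAindex database; since only their rank/spacing
structure survives normalization, small transcription imprecision cannot
change any structural property of the encoding.

**CTD.** Seven three-group residue partitions (hydrophobicity, normalized
van der Waals volume, polarity, polarizability, charge, secondary
structure, solvent accessibility) in the canonical Dubchak-style form.
Composition is the percentage of each group; transition the percentage of
adjacent pairs (of L−1) that cross each unordered group pair;
distribution the chain positions (as % of L, 1-based) of the first, 25%,
50%, 75% and 100% occurrences of each group. The occurrence index for
fraction f of a group with n members is ceil(f·n) floored at 1 — stated
explicitly because off-by-one conventions differ between published
implementations. An absent group contributes five zeros.

**PCP.** Nine global properties with the residue sets listed in the API
docs. The absolute-charge feature is |count(K)+count(R) −
count(D)−count(E)| / L; histidine is treated as positive only in the
"positively charged fraction" set and excluded from the net-charge
arithmetic, since its protonation at physiological pH is marginal.
Molecular weight uses average residue masses plus one water and is
normalized per residue so the feature does not trivially encode length.

**Hybrid.** Concatenation in the fixed order AAC, AAI, DPC, CTD, PCP
(full length 596). Feature names (`AAC_A`, `DPC_AC`,
`CTD_hydrophobicity_T_12`, …) are stable and versioned
(`ENCODER_VERSION`); model bundles refuse to predict under a different
encoder version, because silent feature misalignment is the most common
failure mode when models outlive their feature code.

## Feature selection

FIS estimation grows, within each of 5 stratified CV folds, a forest of
`n_trees` (default 10,000) whose per-node split-candidate count (mtry) is
varied uniformly over 1..50. Standard forest implementations fix mtry per
forest, so the variation is realized by partitioning the trees into
sub-forests of (near-)equal size per mtry value; averaging importances
across sub-forests is equivalent in expectation to a per-tree draw.
Gini importances are averaged per fold (tree-count weighted), then across
folds (unweighted), then renormalized to sum to one. Averaging across
CV repetitions as well as folds is available via `repeats` but off by
default. Test- and acceptance-scale runs use 200–500 trees; the planted
signal in the synthetic data is strong enough that the importance ranking
is already stable there.

The cutoff sweep first drops features with FIS below a floor (default
0.0005), then emits one candidate set per cutoff in 0.0005..0.0039, step
0.0001 — exactly 35 nested sets with the defaults. The sweep is generated
by integer stepping (i = 0..round((high−low)/step)) so floating-point
accumulation can never change the set count. A cutoff retaining zero
features is skipped with a warning rather than raising, so aggressive
sweeps degrade gracefully.

## Model training

Four algorithm families are tuned by exhaustive grid search under a
repeated stratified k-fold plan (default 10×5), maximizing mean
out-of-fold AUC:

* RF — grid ntree ∈ {50, 70, …, 990, 1000} (the 20-step from 50 does not
  land on 1000, so 1000 is appended), mtry 1..7, nsplit 2..10;
* ERT — same grid; differs from RF in using the entire training sample
  per tree (no bootstrap) and randomized split thresholds, asserted in
  tests by configuration introspection rather than output comparison;
* SVM (RBF) — cost 2⁻⁵..2¹⁵ and gamma 2⁻¹⁵..2³ in ×4 steps, with
  Platt-calibrated probabilities fitted inside the training folds only;
* k-NN — odd k in 1..31; probability = fraction of positive neighbours.

Ties in the grid go to the smaller parameter values. Per-repeat winners
are combined by an element-wise median; an even-count median is snapped
to the nearest grid point, ties toward the smaller value (so per-repeat
ntree winners {410, 450} give the on-grid 430).

The probability cutoff is tuned on out-of-fold scores of the selected
model by maximizing MCC over the grid 0.01..0.99 (step 0.01); among
maximizers the cutoff closest to 0.5 wins, then the smaller. MCC is the
natural objective here because class imbalance is handled only through
the cutoff, never by resampling, and MCC is the headline
threshold-dependent metric. A probability exactly at the cutoff is called
positive (≥ convention) everywhere.

`run_pipeline` composes the stages: encode → FIS → sweep → per-set grid
search → best set by mean CV AUC (ties to the smaller set) → consensus
parameters → cutoff tuning on a fresh out-of-fold pass → final fit on all
data. `fast=True` tunes once on the full matrix and reuses the consensus
point per set, trading a possible per-set optimum for a large constant
factor. All randomness derives from the single `seed` via fixed offsets
per stage and repeat, so identical seeds give bit-identical artifacts.

## Evaluation

Sensitivity, specificity and accuracy are ratios of confusion counts. MCC
is computed by the standard product-moment formula and defined as 0 when
a marginal is zero; the algebraically equivalent PS/NS-parameterized form
common in this literature is implemented separately and used only as a
property-test cross-check (the two agree to 1e-12 on random confusion
tables). AUC is the Mann–Whitney rank statistic with midrank ties, which
equals the trapezoidal area under the empirical ROC step curve. Two
models' per-repeat AUC samples are compared with a Welch (unequal
variance) two-tailed t-test; a correlated-ROC test on the paired curves
is a noted alternative but not the default, since the repeated-CV AUC
samples are the quantities the pipeline actually produces.

## Enrichment analysis

Per-peptide composition values (not pooled counts) are the test units:
each residue/dipeptide/position-indicator is compared between classes by
a two-sided Welch t-test. Items constant in both classes with equal means
are flagged `no_variance` (p = NaN); constant with different means is
perfect separation (p = 0). C-terminal positions are indexed 1..n from
the last residue inward. No multiple-testing correction is applied by
default (raw p ≤ α, matching common practice for these descriptive
scans); Benjamini–Hochberg is available via `bh_correct=True`.

## Redundancy reduction

A greedy longest-first (Hobohm-style) clustering stands in for CD-HIT:
records are visited by length descending (id ascending on ties) and kept
iff their identity to every kept record is below the threshold (default
0.8). Identity is the maximal number of matched residues under a global
alignment with unit match score and free gaps/mismatches — equivalently
the longest common subsequence — normalized by the shorter sequence
length (the CD-HIT convention). This reproduces CD-HIT's contract
(no kept pair at or above the threshold, deterministic, idempotent) but
not its word-filter heuristics, and is documented as a stand-in.

## Synthetic data

The generator emulates the known compositional contrast between the
classes: positive-class residue weights up-weight L, K, R by
2^effect_size and negative-class weights up-weight D, G, V, Y, P the same
way; residues are i.i.d. given the class; lengths are uniform on 5–25
(typical of T-cell assay epitopes) and identical between classes.
Class-typical dipeptides (LL, SL, LK, IK, KR positive; DV, KG, DD, EF,
GD negative) are planted by overwriting two adjacent positions with a
per-record insertion probability, so planting never changes the length
distribution. Presets: `null` (effect 0, no planting), `figure1_weak`
(effect 0.5, insertion 0.1), `figure1_strong` (effect 1.0, insertion
0.3).

What the generator deliberately does **not** model: positional structure
(beyond what planting induces), residue autocorrelation, class-dependent
length, MHC-binding or any actual immunological mechanism, and the
label noise of curated assay data. Passing tests therefore demonstrate
that the pipeline recovers planted compositional signal and behaves
correctly at chance on null data — not that any particular accuracy will
transfer to real assay-derived peptides.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline at reduced scale — 250
peptides per class, 500-tree importance forests, 5 swept cutoffs, 2 CV
repeats, single-point-to-small grids — chosen so the planted-signal
checks are comfortably stable across seeds while the whole suite stays
quick on one CPU. FIS determinism is exact for a fixed seed; sweep-count
arithmetic is integer-stepped; cutoff ties use a 1e-15 tolerance on MCC
equality; TSV writers emit full-precision `repr` values so round-trips
and reproducibility checks are bit-exact.

## Known limitations

* The bundled AAindex scale values are transcribed constants, not fetched
  from a live database; provenance comments identify each scale.
* The redundancy reducer is O(n²) alignments — fine for thousands of
  peptides, not for proteome-scale sets.
* SVM probability calibration uses the estimator's internal CV (Platt);
  with very small training folds the calibrated probabilities are noisy.
* `consensus_params` medians each parameter independently, which can
  produce a combination never evaluated during the search; this mirrors
  the median-parameter convention in the peptide-prediction literature.
* Reported CV AUCs on synthetic presets are properties of the generator,
  not estimates of performance on experimental data.
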