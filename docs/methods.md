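# Methods

This note records the models, parameter choices and numerical decisions
behind `spanr`, and what the synthetic test bed does and does not show
about real data.

## NOESY simulation

The simulator emulates a 3D ¹⁵N-edited NOESY: every cross peak is anchored
to one residue's backbone amide by its (δHN, δN) pair, and its indirect ¹H
dimension carries the shift of a nearby hydrogen. For each base amide with
assigned H and N, and each other assigned hydrogen at distance r, a peak
is emitted with probability

    p(r) = min(1, (r0 / r)^6),   p(r) = 0 for r > r_max,

with defaults r0 = 3.0 Å and r_max = 6.0 Å. The r⁻⁶ law follows the NOE
intensity's distance dependence; the saturation at r0 reflects that short
contacts are always observed, and the hard cutoff the practical
observability limit of a NOESY. The exact acceptance law is a modeling
choice (only its r⁻⁶ character is physically fixed) and both parameters
are configurable. The diagonal peak (δHN, δN, δHN) is always emitted. An
optional Gaussian shift jitter (default 0 ppm) exists solely for
robustness testing; all simulation used for scoring in the tests is
zero-jitter, so a peak's shifts identify its source atoms exactly.

Simulated spectra are also a data-sufficiency filter: structures for
which fewer than half the residues generate a potential contact are
flagged (coverage < 0.5; exactly 0.5 passes), since such data cannot
constrain the full fold.

## Potential contacts and tolerances

A potential contact pairs a peak with every assigned hydrogen whose shift
differs from the peak's indirect ¹H position by strictly less than
Δshift. Defaults: Δshift = 0.03 ppm for the candidate window, and
(0.03, 0.3) ppm ¹H/¹⁵N windows for anchoring experimental peaks without
an anchor column — linewidth-scale tolerances typical of well-resolved
¹⁵N-edited spectra at 600 MHz. All are configurable; Δshift and the CS
weight tolerance δ_measure are kept as two parameters (defaulting to the
same value) because nothing forces them to coincide. A residue "generates"
a potential contact if it appears as anchor or partner (the inclusive
reading).

## Contact score

For every long-range potential contact (sequence separation ≥ 5) whose
residue pair has Cα–Cα separation < ε_CS in the proposed structure, a
weight w = max(0, 1 − δ_PC/δ_measure) is contributed (δ_PC the
peak-to-assignment shift difference). Per residue pair the maximum weight
over supporting contacts is kept, capped at 1; CS is the sum of per-pair
scores over the long-range upper triangle divided by the maximum number
of long-range pairs, (n−4)(n−5)/2 for separation ≥ 5 (general form
m(m+1)/2 with m = n − min_sep). The max-cap aggregation is what keeps
CS ≤ 1 under the stated normalizer; any additive uncapped rule could
exceed it. Decisions kept switchable:

- contact test metric: Cα–Cα (default) or amide-H-to-candidate-H
  (`contact_mode="hh"`) — both readings are defensible and the choice
  changes CS little on the synthetic corpus;
- weight shape: linear ramp (default, transparent) or Gaussian
  exp(−(δ_PC/δ_measure)²).

ε_CS defaults to 12 Å, the grid-search optimum of the CS–TM correlation
(the `gridsearch` command reruns that procedure on synthetic corpora).

## Distance score

DS considers long-range peaks only, and additionally excludes any peak
that has a short-range candidate: a short-range explanation is always
geometrically plausible and says nothing about the fold. Each considered
peak is reduced to the candidate minimizing the proposed structure's
Cα separation (the r⁻⁶ intensity makes the closest pair the dominant
contributor); the peak is unexplained iff that minimum exceeds ε_D =
10 Å, the maximum Cα separation compatible with an observable NOE once
side-chain reach is accounted for. DS = unexplained/considered. With zero
considered peaks DS is undefined and reported as missing, never silently
0 — a structure that explains nothing and a dataset that asks nothing are
different situations.

## RPF

True pairs are all (backbone amide H, other hydrogen) pairs closer than
d_noe = 5.0 Å in the proposed structure (strict <); identified pairs come
from *all* potential contacts (RPF is a global measure, not a long-range
one), excluding the amide paired with itself. Recall = |identified ∩
true| / |true|; precision is the distance-weighted fraction of identified
pairs that are true, with weights min(1, (d_noe/d)⁶) by default (uniform
available). F defaults to the product-over-sum form F = RP/(R+P); the
conventional F1 = 2RP/(R+P) is one flag away (`f_convention="f1"`). The
product-over-sum default matters because the classifier's feature scale
must match whichever convention trained it.

## TM-score

Same-sequence TM-score: residues correspond by index, no alignment
search. d0 = 1.24(L−15)^{1/3} − 1.8 floored at 0.5 Å, L the reference
length (also the normalization length — the reference-structure
convention). The maximization over superpositions seeds Kabsch fits on
fragments of length L, L/2, L/4, … (≥ 4; start positions strided by half
the fragment), then iterates superpose-on-close-residues (cutoff
max(d0, 3.0) Å, grown in 0.5 Å steps when fewer than 3 residues qualify)
to convergence, keeping the best score. This recovers TM = 1 for
identical structures exactly and is invariant under rigid motion of
either input; it is a faithful reimplementation of the published score,
not a wrapper around the original program, so third-decimal agreement
with other implementations is not guaranteed.

## PAE features

The AlphaFold predicted-aligned-error matrix is symmetrized and reduced
to two scalars: the mean off-diagonal PAE and the mean over long-range
pairs (|i−j| ≥ 5). How the original analysis reduced the PAE to SVM
inputs is the largest open inference in this reimplementation; the two
summaries chosen here are recorded in the trained model's feature names
so every model is self-describing.

## SPANR classifier

Binary SVM, RBF kernel, C = 1, gamma = "scale", balanced class weights
(the class imbalance of real corpora makes per-class rates, and their
mean — the balanced accuracy — the honest metric). Features are
standardized with statistics frozen on the training split only. Labels:
consistent iff TM > 0.5, strictly. Probability calibration is a sigmoid
(Platt) fit via internal cross-validation on the training data
(`CalibratedClassifierCV(..., method="sigmoid", ensemble=False)`), which
is why the probability-producing model differs slightly from the raw
decision-function SVM. `predict` thresholds the calibrated consistent
probability at 0.5 so class and confidence never disagree. Models
serialize to a single versioned archive; loading any other version fails
loudly. PAE-using feature sets refuse datasets containing mismatched
entries, whose pairing has no meaningful PAE.

Mismatch augmentation doubles a dataset by pairing each member's NMR
data with the prediction of a uniformly chosen *other* member; all
structure-dependent features (CS, DS, RPF) and the TM label are
recomputed against the donor structure. This floods the dataset with
poor structures and is what turns the CS/DS–TM correlations strongly
positive/negative.

## Synthetic data

Folds are idealized Cα traces — α-helix (1.5 Å rise, 100°/residue,
radius set for an exact 3.8 Å consecutive spacing), β-hairpin (two
antiparallel strands ~5 Å apart with a one-residue turn, 3.8 Å spacing
via a ±0.85 Å zigzag) and a mixed helix-plus-packed-strand topology —
decorated with backbone N/C in a local frame, a placed amide H (1.01 Å,
planar geometry) and a single pseudo side-chain hydrogen at 1.5 Å from
Cα. One side-chain H per residue keeps candidate ambiguity controlled;
an `ambiguity` knob compresses the side-chain shift distribution to
stress the Δshift matching instead. Shifts are drawn per atom: HN ~
N(8.3, 0.5), N ~ N(119, 4), side-chain H ~ N(2.0, 1.0) ppm — realistic
centers and spreads, but with no dependence on structure (no ring
currents, no secondary-structure trends).

Decoys apply per-residue rigid Gaussian displacements of scale `level`
(0.5–8 Å ladder) plus, above 2 Å, a random hinge rotation of the second
half of the chain — emulating the correlated, topology-breaking errors
of genuinely wrong predictions rather than mere thermal noise. The mean
TM decreases monotonically along the ladder, and the default ladder on
60-residue folds yields both label classes in substantial proportions.
The corpus generator alternates hairpin and mixed topologies: a pure
ideal helix is a rod with no long-range contact inside the NOE range, so
it cannot exercise DS (it remains available for unit tests). The
synthetic PAE is drawn from the TM label plus noise and is explicitly
non-physical.

What passing on this corpus shows: the scores order structures correctly
when the spectrum is informative, unambiguous in anchor assignment, and
complete. What it does not show: robustness to missing assignments,
shift-table errors, spectral overlap at real densities (tens of
hydrogens per residue), peak-picking noise, conformational averaging, or
unstructured regions. Those belong to real-data validation, not to this
test bed.

## Problem sizes and determinism

The test and acceptance corpora use 300 members of 60 residues (plus a
50-member subset for self-consistency checks and 200 instances of ≤ 20
residues for brute-force oracle comparison) — large enough for stable
rank correlations and classifier evaluation while keeping the whole
suite interactive. Every stochastic step (fold jitter, shift draws,
NOESY acceptance, decoy noise, augmentation pairing, train/test split,
calibration folds) is driven by explicit integer seeds; regenerating
with the same seeds is bit-reproducible, and the acceptance script
derives all of its seeds from a single `--seed`.

## Known limitations

- Backbone amide H placement only; side-chain protons must come from the
  input file (or the generator). No mmCIF, no ligands, no insertion
  codes, first chain only by default.
- Experimental peak anchoring assumes well-separated amide (δHN, δN)
  pairs; overlapping amides drop peaks (counted and warned) rather than
  splitting them probabilistically.
- The TM-score fragment search uses strided seed positions; pathological
  cases could in principle favor an unseeded superposition, though the
  whole-chain seed bounds the score from below.
- CS depends on Δshift/δ_measure, so absolute CS values are comparable
  only within one tolerance setting; DS is far less sensitive to it.
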