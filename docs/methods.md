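# Methods

## Problem and model

Given an RNA (or DNA, converted T→U) sequence, the task is binary
classification of each cytosine: can it carry the m⁵C modification?  The
model is purely sequence-based.  A candidate site is its (2ξ+1)-nt window
with C at the center; the window is mapped to a fixed-length vector of
lagged covariances of physical-chemical dinucleotide properties, and a
bootstrap ensemble of decision trees votes on the class.  The assumptions
are therefore: (i) the local sequence context of a site carries enough
signal to separate the classes; (ii) that signal is expressible through
dinucleotide physical-chemical profiles and their correlations up to lag λ;
(iii) sites are exchangeable — no transcript-level or positional effects
beyond the window.

## Window extraction

Coordinates are 1-based.  For a site at position *p* with flank ξ, the
window spans *p*−ξ … *p*+ξ; positions before the first residue are filled
with the first residue, positions beyond the last with the last residue
(nearest-neighbour fill).  This keeps every window at exactly 2ξ+1 nt with
a central C, at the cost of repeating boundary content for sites within ξ
of a sequence end.  Benchmarks deduplicate exact window strings **within**
each label subset (first occurrence kept, input order preserved); the same
string may legitimately appear in both subsets, since redundancy reduction
is a within-class concern.  No similarity threshold below exact identity is
applied.  Windows containing any non-ACGU symbol are excluded from
benchmarks and counted in the log — ambiguity codes carry no usable
physical-chemical profile.  When benchmarks are built from genome-scale
input, every non-annotated C is a negative candidate; a seeded subsampling
option reduces negatives to a chosen ratio (default 3 per positive).

## Property table and standardization

The encoding needs one numeric value per property per dinucleotide.  The
package ships a curated default of ten RNA dinucleotide parameters — six
A-form helical step descriptors (shift, slide, rise, tilt, roll, twist) and
four nearest-neighbour thermodynamic quantities (stacking energy, enthalpy,
entropy, free energy) with values approximating the published literature
for RNA steps.  The table is a plain TSV and fully swappable; every trained
model records a SHA-256 checksum of the table it was encoded with, and
applying a model across a table change is an explicit incompatibility
error.  Before encoding, each property row is standardized to mean 0 and
unit **population** standard deviation over the 16 dinucleotides, so
properties contribute on a common scale regardless of their native units.
A constant property row is rejected (zero variance carries no contrast).

## Encoding

For a window of length *L*, with standardized property profiles
P_m(D_1 … D_{L−1}), the features are, for each lag g = 1…λ:

* AC(m, g) — the autocovariance of property m, centred on the **window's
  own** profile mean and normalized by the number of summands (L−1−g);
* CC(μ₁, μ₂, g) for all 90 ordered pairs μ₁ ≠ μ₂ — the analogous lagged
  cross-covariance.

This window-mean-centred, count-normalized form is adopted as the single
normative definition, and a brute-force loop implementation pins it in the
test suite.  The vector layout is lag-major (all ten AC components for
lag 1, then lag 2, …; then the 90 CC components per lag in lexicographic
pair order), giving Ω = 100λ components.  Running the cross-covariances
over all 90 ordered pairs (rather than 45 unordered ones) is deliberate:
CC is asymmetric in its two properties, and 22 ≈ √500 makes the standard
subspace heuristic consistent with the classifier's published subspace
dimension.  λ must satisfy λ ≤ L−2 so every lag retains at least one
summand; λ = 0 would produce an empty vector and is rejected.  A k-mer
composition block (4^k normalized frequencies, alphabetical order) can be
appended, but the default predictor is pure AC/CC: the pseudo-component
definition involves no raw composition terms, and the default is kept
minimal.

Defaults: ξ = 20 (41-nt windows) and λ = 5, the operating point at which
this window/lag family performs best on the real benchmark; both are
plain parameters.

## Classifier

`VoteForestClassifier` wraps a random forest of 100 trees grown to purity
(no depth or leaf limits), each on a bootstrap resample of the training
set, with 22 candidate features drawn at random per split.  "Subspace
dimension 22" is interpreted as per-split candidate features — the common
forest convention; a per-tree mode (each tree confined to one fixed
22-feature subset) is available behind `subspace_mode="tree"` for fidelity
experiments.  The score of a sample is the fraction of trees whose hard
vote is positive — not the mean of leaf class frequencies — so scores are
multiples of 1/100; the decision threshold is 0.5 with ties called
positive.  The 1:3 class imbalance is left unweighted, which produces the
characteristic high-specificity / lower-sensitivity profile.  Training is
deterministic given data and seed.

## Evaluation

Metrics are computed from misclassification counts: with N⁺ positives of
which N₋⁺ are missed and N⁻ negatives of which N₊⁻ are called positive,
Sn = 1 − N₋⁺/N⁺, Sp = 1 − N₊⁻/N⁻, Acc = 1 − (N₋⁺+N₊⁻)/(N⁺+N⁻), and MCC in
the equivalent count-parameterized form of the Matthews coefficient (the
test suite verifies the algebraic identity against the textbook TP/FP/TN/FN
formula on 1,000 random count tuples).  When the MCC denominator vanishes
(e.g. all predictions in one class) MCC is reported as 0 with a warning.

The jackknife (leave-one-out) test is the normative protocol: it yields a
unique outcome for a fixed benchmark.  Fold *i* trains a fresh forest with
seed `master_seed + i`, so the whole jackknife is reproducible while trees
still differ across folds.  Stratified k-fold (seeded shuffle, proportional
class allocation, same per-fold seed derivation) is the cheaper proxy;
k = N degenerates to the jackknife and is delegated to it.  ROC/AUC are
computed over the pooled out-of-fold vote fractions; AUC equals the
pairwise rank statistic with ties counted ½.

## Synthetic data

The generator emulates the structure the method assumes: fixed-width
C-centered windows with class-dependent composition, at the real
benchmark's scale and 1:3 class ratio (475/1,425, ξ=20) by default.
Negatives are i.i.d. draws from a background composition (uniform by
default).  Positives carry, with probability `signal_strength`, a planted
signal: flank composition shifted toward an A/G-rich distribution
(0.40/0.10/0.40/0.10) and a fixed periodic motif (GAGAGAGA) written
immediately 3′ of the center.  The motif is periodic by design — the
encoding is built from lagged covariances, and a periodic element produces
a deterministic lag signature, so `signal_strength = 1` yields a
nearly separable problem (jackknife Acc > 0.95 at modest sample sizes)
while `signal_strength = 0` makes the classes exchangeable and calibrates
cross-validated MCC to ≈ 0.  The default strength 0.8 gives a strongly but
not perfectly separable problem.  Duplicate windows within a class are
resampled (capped retries, then an error), so generated benchmarks satisfy
the dedup invariant by construction.

What passing tests on synthetic data do and do not show: they establish
that extraction, encoding, training and evaluation are correct and that the
pipeline recovers a planted, covariance-visible signal at the benchmark's
scale and imbalance.  They do not show that real m⁵C sites are separable in
this feature space — the generator models no methyltransferase biology, no
transcriptome composition, and no similarity structure between windows —
and numerical performance on real data additionally depends on the exact
property table used.

## Numerical choices and degenerate inputs

* Population (not sample) SD in standardization; standardize-twice is a
  no-op to 1e−12.
* Covariance normalization by the summand count L−1−g; lags with no
  summand are errors, not zeros.
* Prediction ties at exactly the threshold are positive.
* Single-class training labels, empty datasets, mixed window lengths,
  non-C annotated positions, and unknown sequence ids are all hard errors
  with explicit messages, not silent repairs.
* Saved models embed format version, forest configuration, feature
  dimension, layout version and property-table checksum; any mismatch at
  prediction time is an incompatibility error (CLI exit code 3).

## Problem sizes used in the shipped checks

The test suite and the acceptance script scale the expensive protocols
down: jackknife properties run on 30–60-sample benchmarks with ξ=8–10 and
λ=3; the full-pipeline check uses 400 samples at ξ=20/λ=5 under 10-fold
cross-validation; the acceptance script runs the complete 1,900-sample
configuration under 10-fold cross-validation rather than the 1,900-fold
jackknife.  These sizes are the package's own choices for routine
verification; the full jackknife remains available through
`m5cpred cv --mode jackknife` or `evaluate.jackknife`.

## Known limitations

* The ten property values are a curated approximation of published RNA
  dinucleotide parameters, not a canonical reference set; conclusions
  about real data are conditional on the table supplied.
* Exact-string deduplication only; no similarity-threshold redundancy
  reduction (e.g. CD-HIT-style clustering).
* No probability calibration of vote fractions; scores are ensemble vote
  shares, not calibrated posteriors.
* No handling of genome assemblies, strands, or liftover — inputs are
  taken as the transcribed strand.
* Class imbalance is not reweighted; sensitivity at the default threshold
  is correspondingly conservative.
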