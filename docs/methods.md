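# Methods

## Window formulation

A candidate site is the cysteine-centered window P = R₁…R_L with L = 2ξ + 1
(ξ = 10 by default, L = 21) and the cysteine at position ξ + 1. Flank
positions outside the parent protein are padded with the dummy residue Z,
which participates in the alphabet as member 21 everywhere — in pair
tallies, propensities and identity computations — because terminal context
("this site sits near an end") is itself informative. ξ is configurable;
every downstream dimension (441 × (L−1) and 441 × (L−2) matrices,
Ω = (L−1) + (L−2)) is derived from it, never hard-coded.

Coordinates are 1-based and inclusive throughout, including all file
formats. Sequences are uppercased on ingest. The rare/ambiguous letters
B, J, O, U, X are rejected by default; an opt-in flag maps them to the pad
symbol, because silently coercing them to a standard residue would corrupt
the frequency tables. Annotated SNO positions that do not fall on a
cysteine raise an error rather than being guessed around.

## Encoding

For gap g ∈ {0, 1}, subsite j carries the ordered pair (R_j, R_{j+g+1});
there are L−1 gap-0 and L−2 gap-1 subsites. Class-conditional occurrence
frequencies F±_g(Dᵢ|j) are tallied with every window weighted equally, and
the propensity matrices are Z^g = F⁺_g − F⁻_g, entries in [−1, 1]. The
feature vector reads the propensity of the window's own pair at each
subsite: ψ_u = z⁰[pair(R_u, R_{u+1}), u] for u ≤ L−1, then
ψ_{(L−1)+u} = z¹[pair(R_u, R_{u+2}), u] for u ≤ L−2. The gap-1 block
indexes its own columns 1..L−2 (the concatenation is an orthogonal sum of
the two blocks; a literal continuation of the gap-0 column index would
overrun the 19-column matrix).

No pseudocount smoothing is applied by default — an unseen pair has
frequency exactly 0 — matching the frequency definition; an additive
`smoothing` parameter (default 0) is exposed for experimentation and keeps
columns stochastic.

## Decision rule

Class norms are the componentwise means of the training feature vectors;
the query is assigned the class whose norm is nearer in Euclidean distance
(SNO iff 𝔻(ψ, ℙ⁺) < 𝔻(ψ, ℙ⁻)). The reversed comparison has circulated in
print; because 𝔻 is a distance and positive-class features trend positive
by construction, only the nearest-norm direction is self-consistent, and it
is the default. `rule="literal"` preserves the reversed reading for
auditability. Exact ties (which require 𝔻⁺ = 𝔻⁻ to the last bit, e.g. an
all-zero model) are broken by a seeded uniform draw; the seed is an
explicit, logged parameter.

Training windows are encoded against matrices built from the full training
set; there is no leave-one-out correction inside `fit` — held-out behavior
is measured by the evaluation module.

## Evaluation protocol

Metrics are Sn, Sp, Acc and MCC with SNO as the positive class, implemented
in the conventional TP/TN/FP/FN ratio form and, as an independent
cross-check, in the missed/over-called form (Sn = 1 − N⁺₋/N⁺ etc.).
Degenerate denominators: MCC with any empty marginal is reported as 0.0
with a flag; Sn (Sp) is reported as missing — not 0 — when no positives
(negatives) were evaluated, distinguishing "none evaluated" from "all
missed". Full double precision is retained; percentages are a display
concern (one decimal for CV/independent summaries, two for protein-level).

Cross-validation is stratified 10-fold, repeated 50 times by default with
per-repeat seeds `seed + repeat`, re-randomizing only the fold assignment.
Stratification is the default because it keeps each fold's class ratio
within one sample of the global ratio (with balanced classes it is nearly
equivalent to plain shuffling); a flag disables it. The k folds of one
repeat pool into a single confusion table before metrics are computed —
with balanced folds this coincides with per-fold averaging in expectation
and is better behaved for MCC on small folds. Mean and sample standard
deviation across repeats are reported.

The independent test verifies train/test disjointness by exact 21-mer
identity when asked. Whole-protein evaluation predicts every cysteine of
every protein and treats each cysteine without a SNO annotation as a true
non-SNO site.

## Redundancy filter

The winnowing step removes windows with ≥ 40% sequence identity to any
already-kept window. Because windows are fixed-length and pre-aligned on
the central cysteine, identity is defined as the ungapped fraction of
positions with identical residues over the full window (9/21 ≈ 42.9%
removes; 8/21 ≈ 38.1% keeps, at the default threshold). Pad positions
count toward identity by default; a flag excludes positions where both
windows carry the pad. The pass is greedy in input order and deterministic.
This is a documented stand-in for the unpublished procedure that produced
the original benchmark; no equivalence is claimed.

## Synthetic data generator

The generator emulates the statistical structure the encoding assumes:
class-dependent, position-specific residue composition around the central
cysteine. Negative windows draw all non-center residues i.i.d. from a
background distribution (uniform by default; a natural-abundance preset is
included, masses normalized internally). Positive windows are identical
except at the biased positions {8, 9, 12, 13} — two adjacent pairs flanking
the center — where the planted residue (L, K, D, F respectively; an
arbitrary fixed choice) is emitted with probability
`effect + (1 − effect) · background`. Planting marginal biases at adjacent
and near-adjacent positions induces class-dependent pair frequencies at
every subsite overlapping them, exercising both the gap-0 and gap-1
propensity pathways. At effect 0 the classes are exchangeable (a null
benchmark, CV accuracy ≈ 0.5); at effect 1 they are separable.

Protein mode concatenates window-length blocks, one annotated cysteine per
block, with block context drawn from the positive or negative distribution
according to the site's label; additional cysteines arising from the
background are left unannotated (true non-SNO), as in real annotation
tables.

What the generator does *not* emulate: real SNO motif biology, residue
autocorrelation along the chain, homology between windows, or the
composition of curated databases. Passing tests on synthetic data therefore
demonstrate that the pipeline recovers the kind of signal its features can
express, at the stated sample sizes — not field performance on curated
benchmarks.

## Problem sizes and numerical choices

The CV studies in the acceptance script use 400 windows per class with 10
repeats of 10-fold CV — a desk-scale experiment whose standard error on
accuracy is below two percentage points; the independent test uses an
81 + 100 class shape and the protein study 14 proteins, mirroring the
shapes of the published supplementary benchmarks this package's protocol is
designed for. Frequencies and features are float64 throughout; integer
counts are retained alongside frequencies so exact rational recomputation
is possible. Oracle comparisons in the tests use 1e−12 absolute tolerance;
the two metric formulations agree to ~4e−16 over 10⁴ random tables.

## Known limitations

- Training on the original curated benchmark tables requires obtaining them
  separately (they are third-party data and not redistributed here); the
  full protocol runs unchanged once they are supplied as peptide-table TSV
  and FASTA + annotations under `data/external/`.
- The nearest-norm classifier is a two-centroid linear rule in feature
  space; no probability calibration or alternative thresholds are offered.
- Higher-order couplings (pairs separated by two or more residues) and
  physicochemical-property encodings are out of scope.
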