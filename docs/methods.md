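# Methods

This note records the modeling choices behind `hypermet`: what is
computed, under which assumptions, with which defaults, and what the
synthetic benchmarks do and do not demonstrate.

## Hypergraph construction

Diseases are hyperedges; metabolites, proteins, and GO terms are
vertices.  A disease's membership set is the union of

- metabolites directly associated with it (disease–metabolite table),
- GO terms directly associated with it (disease–GO table),
- proteins linked (metabolite–protein table) to any of its member
  metabolites.

The input tables never state protein–disease links directly, and two
routes could plausibly admit proteins into a hyperedge.  The default uses
only the metabolite bridge, because it rests on the two explicitly
disease-anchored tables; the alternative route through protein–GO
annotations of the disease's GO terms is available behind
`protein_via_go` (CLI `--protein-via-go`) rather than silently chosen.

Hyperedges that end up empty are dropped with a warning and vertices
belonging to no hyperedge are pruned (and recorded), because the
smoothing operator needs `D_e^{-1}` and `D_v^{-1/2}` to exist.  The
median of an even-length distribution is the mean of the two central
order statistics.

## Similarity features

- **Metabolites** — Tanimoto coefficient over bitset fingerprints.  The
  fingerprint function is pluggable; the default backend hashes circular
  substructures (Morgan, radius 2, 2048 bits) via rdkit, but every
  synthetic pathway generates bitsets directly so the chemistry toolkit
  is an optional dependency.  Two empty fingerprints score 0 (no shared
  features), but the matrix diagonal is forced to 1.
- **Proteins** — affine-gap pairwise alignment with BLOSUM62, gap open
  11, gap extend 1; local mode by default (mirroring blastp).  Two
  normalizations are implemented because both are defensible and they
  disagree: `identity_fraction` (aligned identity% / 100; the default)
  and `minmax` (off-diagonal min–max rescaling of raw scores, which
  collapses to all-1 with a warning when every score is equal).  Reports
  record which was used.  Exhaustive all-vs-all alignment is intended for
  synthetic scale; precomputed score tables can be ingested instead.
- **GO terms** — ancestor-set Jaccard
  `|A(t1)∩A(t2)| / |A(t1)∪A(t2)|` with `A(t) = {t} ∪ ancestors(t)` over
  `is_a`/`part_of` links.  This "ancestral contribution" instantiation
  needs no corpus frequencies (unlike Resnik/Lin), lands naturally in
  [0, 1], and is monotone along specialization chains.

All three matrices are validated for symmetry, unit diagonal, and range
on construction.

## Autoencoder reduction

Each type's similarity matrix has its own width, so rows are compressed
to a shared width by a per-type single-hidden-layer autoencoder (linear
encoder/decoder by default, `tanh` optional) trained full-batch with Adam
on mean squared reconstruction error, stopping when the improvement per
epoch falls below `tol` (1e-7) or at `max_epochs`.  Reduction happens
*before* message passing: the smoothing operator mixes rows of different
entity types, which is only meaningful once they share one feature
space.

## Hypergraph network and training objective

The smoothing operator is the standard symmetric normalization
`Θ = D_v^{-1/2} H W_e D_e^{-1} Hᵀ D_v^{-1/2}` with identity hyperedge
weights, held in factored sparse form (`D_e^{-1}` kept unsplit, which
also keeps hand-checkable instances exact in floating point).  Θ is
symmetric with eigenvalues in [0, 1]; it performs one
vertex→hyperedge→vertex round of degree-normalized averaging (Laplacian
smoothing).  Two layers `ReLU(Θ X W)` map the reduced features to the
embedding space, with inverted dropout after each activation during
training only.

The network is trained **self-supervised**: embeddings must reconstruct
hyperedge membership.  Each (vertex, hyperedge) cell is scored
`sigmoid(z_v · a_e)` with `a_e` the mean of member embeddings, against
binary cross-entropy on the incidence matrix.  No association labels
enter this stage, so nothing the downstream classifier is evaluated on
leaks into its input features.  Implementation details:

- The loss is computed densely over all incidence cells with positive
  cells up-weighted by the negative/positive cell ratio — the
  deterministic equivalent of 1:1 negative-pair sampling.  Instances
  beyond 5×10⁶ cells are rejected with guidance (the full published
  dataset scale, 19,442 × 178 ≈ 3.5×10⁶, fits the dense path).
- The validation split holds out a seeded fraction (20%) of hyperedge
  *columns*, not individual cells.  Column-wise holdout keeps the
  objective equivariant under vertex relabeling, a property the test
  suite checks directly.  Worlds with fewer than five hyperedges validate
  on the training columns (degenerate but well-defined).
- Optimization is full-batch Adam (β₁ = 0.9, β₂ = 0.999) with classic L2
  weight decay (5×10⁻⁵) and early stopping (patience 10).  Weights use
  scaled uniform fan-in initialization.  With a constant validation
  loss, training stops exactly `patience` epochs after the initial
  evaluation.  Gradients are derived by hand; everything runs on CPU in
  NumPy.
- A non-finite training loss aborts with a diagnostic rather than
  silently producing NaN embeddings.

`HgnnConfig` defaults are the full-scale settings: 2 layers, 500-dim
embeddings, dropout 0.4, learning rate 0.001, up to 200 epochs.
`PipelineConfig` (the desk-scale orchestrator) defaults to 64-dim
embeddings, 60 epochs, and learning rate 0.01: small worlds produce
small gradients under the bilinear reconstruction loss (all scores start
near sigmoid(0)), and the larger step moves training off that plateau
within the reduced epoch budget.

Disease (hyperedge) embeddings are the unweighted arithmetic mean of
member vertex embeddings, computed after training.

## Pairs, negatives, classifier

A labeled pair set holds (disease, metabolite, label) rows; features are
`[disease ‖ metabolite]` concatenations, disease block first.  Negative
sampling is uniform without replacement over the explicit candidate pool
(materialized when the grid is ≤ 10⁷ pairs, rejection-sampled above):
the disease × metabolite grid minus known positives minus all pairs
joined by a two-hop metabolite–protein–disease path.  The two-hop filter
covers exactly that route; GO-mediated paths are not excluded.  Since
protein–disease links are not a first-class input, they are derived from
hyperedge membership.  Every sampled set is *verified* disjoint from
both exclusion sets — the check is an assertion, not an assumption.
Sampling happens once, globally, before cross-validation splitting; the
per-fold alternative would avoid any shared-negative structure across
folds but does not match the stated train/test ordering of the original
protocol, and is noted here as the known alternative.

The classifier is a leaf-wise gradient-boosted tree ensemble (LightGBM)
with leaf L2 coefficient 0.1 and library defaults otherwise — no
hyperparameter search by design.  It runs single-threaded and seeded for
reproducibility.  Scores ≥ 0.5 map to the positive class (the boundary
itself is positive); raw scores are returned as uncertainty estimates
and drive per-disease candidate ranking, with exact ties broken by
metabolite id.

## Evaluation

ACC, SEN, SPE, PRE, MCC come from integer confusion counts; any zero
denominator yields 0 with the metric named in an `undefined` flag set,
so batch reports stay machine-readable.  AUC is trapezoidal ROC area,
identical (to 1e-12, verified against a brute-force oracle) to the
Mann–Whitney concordance probability with half credit for ties.  AUPRC
is average precision — trapezoidal PR interpolation is optimistically
biased — and every report records the convention.  Folds are stratified
by label (keeps prevalence stable at high negative ratios) and seeded.
Fold SDs use the sample convention (k−1) by default with a population
(k) flag; neither convention is privileged by the published tables,
whose own CI arithmetic is internally inconsistent in one row.  CI
half-widths are `1.96·SD/√k`.

The ratio sweep draws one fresh negative sample per requested ratio
(1:1 … 1:10) and cross-validates each; an infeasible request fails up
front naming the maximum feasible ratio.

## Synthetic worlds

`SynthConfig` defaults describe the study conditions used throughout the
tests: 50 diseases, 300 metabolites, 100 proteins, 160 GO terms in L = 4
modules; association probability 0.1 within module and 0.003 across, for
every link type.  Those densities give ≈3% positive density — the same
order as real curated association data (~1%) — and leave a negative pool
comfortably larger than ten times the positive count, which any 1:10
sweep needs by counting.  Substantially denser worlds are unusable for
negative sampling: the two-hop filter then excludes the entire grid.

Fingerprints plant a fully shared 64-bit module block plus 16 uniform
noise bits (within-module Tanimoto ≈ 0.67, cross ≈ 0); protein sequences
are per-module ancestors with 10% i.i.d. substitutions; the GO hierarchy
is a forest of per-module b-ary trees (branching 3, depth cap 4) under
one shared root.  Multiple parenthood is exercised by a dedicated OBO
fixture rather than the generator, keeping ancestor sets hand-checkable.
Diseases that draw no metabolite are given one uniformly from their
module.  Regeneration from the same config and seed is byte-identical,
and a world survives a write/read round trip through its flat-file
formats unchanged.

What the generator does *not* emulate: realistic chemistry (fingerprints
are abstract bitsets), phylogenetics, scale-free degree distributions,
GO term frequency skew, or database noise/incompleteness.  Passing
benchmarks on planted worlds therefore demonstrates that the machinery
recovers block-structured signal through the full pipeline — not that
real-database performance will match; results on curated data depend on
the databases' own coverage and error properties.

## Problem sizes and reproducibility

Desk-scale runs (tests, acceptance script) use 16–64-dim embeddings,
25–60 training epochs, and the world sizes above; the imbalance-trend
study uses 10 replicates of a 30-disease / 150-metabolite world at
ratios 1:1 and 1:10.  The full-scale bookkeeping check builds the
hypergraph at the published dataset scale (19,442 vertices, 178
hyperedges) with reduced embedding width.  All randomness flows from one
root seed through a deterministic per-stage expansion
(`pipeline.stage_seed`); every CLI output embeds its seed and config
hash.

## Known limitations

- Transductive only: entities absent from the hypergraph have no
  embedding; extending the catalog means recomputing similarities and
  retraining.
- The self-supervised reconstruction objective is this package's own
  choice of structural training signal; other objectives (e.g. contrast
  against degree-matched negatives) are plausible and untested here.
- The two-hop negative filter cannot remove associations mediated by
  pathways outside the modeled tables.
- Exhaustive pairwise alignment scales quadratically; real proteome-scale
  inputs should supply precomputed score tables.
- MCC/PRE flags aside, metrics assume binary hard labels at a fixed 0.5
  threshold; no probability calibration is performed.
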