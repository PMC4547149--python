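# Methods

## Pipeline and data model

The package operates on an `ExpressionDataset` — an entity × sample matrix
of normalized, background-subtracted expression values plus design metadata
(data kind, group membership, pairing). Five input kinds are supported:
paired two-sample, unpaired two-sample, statistics-only (per-entity p and
fold change without a matrix), multisample, and TCGA-style (columns are
barcodes; two datasets are aligned on a configurable barcode prefix, default
length 15). The canonical on-disk dialect is TSV with an id column and a
sample-id header; group and pairing declarations travel in a sidecar config
rather than being inferred, because column naming conventions vary across
facilities. Missing values are rejected rather than imputed. Floats are
written with `%.17g` so write→read round-trips are bit-exact.

Stages run in the fixed order load → filter → predict → visualize. The
statistics-only kind supports filtering and direction logic but no
expression-based scoring (there are no per-sample values to score), and
requesting it raises a capability error.

## Differential statistics and filtering

Two-sample data get a per-entity t-test — paired t on per-pair differences
for paired designs, Welch (unequal variances) otherwise, since the pooled
variance assumption buys little and costs robustness — with two-tailed p.
Fold change uses the signed-ratio convention: FC = m2/m1 if m2 ≥ m1 else
−m1/m2, so |FC| ≥ 1 and the sign is the direction of change; equal means
give +1. A config switch declares the matrix as log2 expression, in which
case FC = sign-preserving 2^|Δmean|. P-values are raw by default (the
filtering convention the case-study workflow uses); a Benjamini–Hochberg
column is available on request.

Zero-variance entities cannot support a t-test: when the group means also
agree the entity is reported with t = 0, p = 1; otherwise it is excluded
with a warning rather than reported at p ≈ 0, which would otherwise flood
the top of the ranking with degenerate probes. Multisample data are filtered
by row mean, which removes poorly expressed entities whose values are mostly
zero.

## Association scores

**Correlation** is the product-moment coefficient; Spearman is Pearson on
average-ranked data. Pairs containing a constant vector are skipped with a
warning (the coefficient is undefined).

**kNN mutual information** uses the Kraskov–Stögbauer–Grassberger
estimator, variant 1: for each point, the Chebyshev distance to its k-th
nearest joint neighbour defines a box, and n_x, n_y count points strictly
inside it marginally; I = ψ(k) + ψ(N) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩ in nats.
Negative estimates are returned as computed — clamping would bias averages.
Default k = 3 balances bias and variance at panel-scale N. The estimator
assumes continuous marginals; microarray ties are broken by a deterministic
jitter of magnitude 1e-10 × value range whose RNG is seeded from a hash of
the input, so results are reproducible bit-for-bit without a global seed.

**MIC** is the maximal information coefficient: over all grid shapes
(p columns × q rows) with p·q ≤ ⌈n^α⌉ and p, q ≥ 2, the maximum over grids
of I(grid)/log₂ min(p,q), log base 2 throughout; defaults α = 0.6, c = 15.
Grid lines fall only between distinct data values, so tied values always
share a cell, and equipartition ties go to the lower bin — both for
determinism. Per shape the search is:

* *exact enumeration* when the shape's search space is small (the number of
  cut combinations times table size is below a fixed budget of 2×10⁶
  cells): all column and row cut positions are enumerated with vectorized
  double-differencing of the cumulative joint count matrix. At the sample
  sizes of expression panels (n ≤ ~30) every admissible shape is exact, and
  the low-resolution shapes (2×2 and neighbours) remain exact at any n;
* otherwise the *clump dynamic program*: one axis is equipartitioned into q
  rows, the other axis's points are collapsed into clumps (maximal x-runs
  within one row, x-ties inseparable) capped at c·p superclumps of roughly
  equal mass, and the optimal ≤ p column boundaries are found by dynamic
  programming — the objective H(P) − H(P,Q) is additive over columns, so
  the DP is exact given the row partition and clump restriction. Both axis
  orientations are tried and the larger normalized value kept.

The hybrid keeps the estimator identical to the definitional exhaustive
search wherever that is affordable — verified in tests against an
independent brute-force enumerator — while scaling like the standard
approximate algorithm elsewhere.

## Variational Bayesian target scoring

For mRNA j with candidate miRNA set C_j:

x_j | s ~ Normal(μ − Σ_{k∈C_j} s_jk γ_k Λ z_k, Σ),  s_jk ~ Bernoulli(π)

with per-miRNA regulatory weight γ_k ≥ 0, diagonal per-sample scaling
Λ ≥ 0, per-sample baseline μ and diagonal noise Σ. The nonnegativity
constraints encode that miRNAs only down-regulate. Inference is mean-field
variational EM with q(s_jk) = Bernoulli(β_jk); β_jk is the posterior
probability the candidate pair is a true target and is the exposed score
(log-odds available as a derived column). π is held fixed (default 0.5)
rather than learned, keeping the prior an interpretable knob.

Every update is an exact coordinate maximization of the ELBO — β
sequentially within each mRNA, then μ, then γ per miRNA, then Λ per sample,
then Σ — so the ELBO is non-decreasing by construction (asserted to 1e-8
slack in every test fit). Negative γ or Λ maximizers are projected to zero.
Convergence is a relative ELBO change below tol = 1e-5, capped at 200
iterations; non-convergence returns the fit flagged with a warning.

Initialization: β = π, γ = 0.01, Λ = 1, Σ = across-mRNA per-sample
variance. μ is initialized to the *grand mean* of mRNA expression rather
than the per-sample mean: with few fitted mRNAs a per-sample mean equals
the data and the EM starts at a degenerate stationary point (zero residual,
β pinned at π); the grand-mean start leaves the per-sample structure for
the regression term to explain, and μ is refined by EM thereafter. When
fewer than two mRNAs are fitted, Σ falls back to the across-sample residual
variance. With ~one free (μ_t, Λ_t, Σ_t) triple per sample the model can
overfit very small mRNA panels; scores are meaningful when the number of
fitted mRNAs comfortably exceeds ~3 per sample-wise parameter, which any
realistic panel does. Profiles are z-scored per entity before fitting by
default (configurable off); candidate sets default to the
sequence-database pairs when provided, else all pairs.

## Selection and combination

Each algorithm's scores pass a direction filter keyed on fold-change signs
(up means FC > +1, down means FC < −1; |FC| = 1 matches no directional
option), then a threshold or top-N cut. Correlation orders ascending (most
negative first — repression is anti-correlation); mutual information, MIC
and β order descending. Ties break on score then (mirna_id, mrna_id)
lexicographically so runs are reproducible across platforms. The direction
filter runs before top-N, so a top-N request returns the N best pairs in
the requested direction; both stages are exposed separately for callers who
want the other order.

Selections are combined by intersection or union over a chosen algorithm
subset; every row of the merged table still records a TRUE/FALSE flag for
*all* supplied algorithms, so the table shows which non-selected algorithms
would have supported each retained pair. Sequence-database results enter as
score-less boolean evidence.

## Network layouts

The interaction table maps to a bipartite network: one edge per row,
support = number of TRUE flags (drives link width in renders). Circular
layout spaces all nodes equally on one circle; force-directed
(Fruchterman–Reingold) and Kamada–Kawai come from networkx; disconnected
components are laid out separately and packed on a grid, then normalized to
the unit square (screen convention: origin top-left, y down).

The modified inverted-SOM layout addresses the hub-and-spoke structure of
miRNA regulation: the core embedding is a seeded inverted self-organizing
map (1500 epochs, BFS neighbourhood radius cooling 3 → 0, learning rate
0.8 → 0.05 geometric — standard SOM-style schedules; the embedding only
needs to be topology-aware since the post-pass is the point). Afterwards
every degree-1 mRNA is re-placed at exactly equal angular spacing on a
circle around its miRNA, radius 0.35 × the distance to the nearest other
miRNA (floor 0.02 in unit coordinates; 0.1 for a single-miRNA network) to
avoid overlap between neighbouring stars. This guarantees strictly distinct
positions for structurally equivalent targets, which a purely
topology-driven embedding cannot.

The treemap converts the network to a two-level hierarchy: each miRNA tile
has area proportional to its target count and encloses one equal-area tile
per target; an mRNA with several regulators is duplicated under each
parent, so leaf count equals edge count. Both levels use squarified tiling
(worst-aspect-ratio row packing, sizes sorted descending with id
tie-breaks), which keeps tiles near-square and label-friendly. Area is
conserved to float precision at both levels.

Fold-change color: white at |FC| = 1, linearly saturating to pure red (up)
or blue (down) at |FC| = cap, default cap 4 (case-study fold changes span
about ±2.5); multisample networks use fixed orange (miRNA) / dark blue
(mRNA) since no fold change exists.

## Synthetic data

The generator emulates the repression model the predictors assume: miRNA
profiles i.i.d. lognormal(μ=1, σ=0.5); mRNA j = lognormal baseline (μ=2,
σ=0.3) − γ_true · Σ over its true miRNAs + N(0, noise_sd²), floored at
1e-3 so fold-change ratios stay defined. Defaults: 50 miRNAs, 500 mRNAs,
10 planted pairs with γ_true = 1 and noise_sd = 0.3, 9 decoy candidates per
true pair, 20 samples (multisample) or 10 sample pairs (paired mode) —
sizes representative of a filtered panel while keeping full test runs in
seconds. In paired mode the two samples of a pair share a per-subject
expression level and differ by planted fold changes (miRNA ×2.5,
mRNA ÷2 in the second condition, applied to true-pair members) times
multiplicative measurement noise (σ = 0.1 log-scale); within-pair
correlation is what gives the paired t-test its power and is the defining
feature of paired profiling. All randomness flows from one seed;
re-generation is bit-identical, including written TSVs.

What the generator does *not* emulate: probe/batch effects, heteroscedastic
microarray noise, miRNA-miRNA correlation, indirect (transcription-factor
mediated) effects, or sequence information. Passing tests therefore
demonstrate correctness of the algorithms under their own model
assumptions, not field performance on real array data.

## Degenerate inputs and numerical choices

Correlation on a constant vector: undefined, pair skipped with a warning.
MIC on a constant axis: 0 (no informative grid exists). KSG with k ≥ N:
parameter error. Empty candidate map: empty fit, no iterations. Empty
interaction table: network construction refuses (an empty network has no
layout). Exactly coincident core layout positions are separated by a
deterministic 1e-4-scale nudge before the modified-layout post-pass.
Variance floors: Σ ≥ 1e-12 in the EM; β clipped to [1e-12, 1−1e-12] inside
entropy terms only.

## Scope and limitations

The package is headless: interactive navigation (zoom/pan, node dragging,
click highlighting, web links out to annotation databases) and enrichment
analysis over web services are out of scope, as are downloading reference
sequence databases or expression repositories and any normalization of raw
arrays — inputs are assumed normalized. Layout stability under parameter
changes is not attempted: layouts are deterministic for a fixed seed but
not stable across different filter settings.
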