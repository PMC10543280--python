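# Methods

## The kinetic model

A gene in a cell is described by the two-state promoter model: the promoter
activates at rate `kon`, deactivates at rate `koff`; while active, mRNA is
synthesised at rate `s` and degrades at rate `d`, fixed at 1 so the other
three parameters are relative rates.  Two generation modes are provided.

**Beta-Poisson.**  The steady-state count distribution of the two-state
model is sampled directly: `y ~ Beta(kon, koff)`, `x ~ Poisson(y·s)`.  The
intrinsic-noise weight `σi ∈ [0, 1]` returns
`σi·x + (1−σi)·s·kon/(kon+koff)`; at `σi = 0` this is exactly the
theoretical mean, at `σi = 1` the full transcriptional-burst noise.  This is
the default mode (fast; spliced counts only).

**Full kinetic model.**  For velocity ground truth, the promoter is stepped
through one cell cycle of length `L = ηL·(1/kon + 1/koff)`, divided into
`m = ceil(L / min(1/kon, 1/koff))` steps (capped at 1000) of size `L/m`.
Per-step switching probabilities are `pon = kon·(L/m)`, `poff = koff·(L/m)`;
both are guaranteed ≤ 1 because `L/m ≤ min(1/kon, 1/koff)` — the only
rendering of the switching rule that yields valid probabilities.  Spliced
and unspliced counts update as

    xs ← xs + (L/m)·(β·xu − d·xs)
    xu ← xu + (L/m)·(s − β·xu)   (on)   /   xu ← xu − (L/m)·β·xu   (off)

with clipping at 0; counts are real-valued during stepping and rounded only
at output (the update rules are continuous).  Per-gene splicing and
degradation rates β, d are drawn from Normal(1, 0.1) truncated at 0.1
(resampling), all exposed.  A cell's initial state is its pseudotime
predecessor's final counts within the same lineage; lineage roots start at
`xs = s·kon·β/(kon+koff)`, `xu = s·kon·d/(kon+koff)`, the closed form whose
initial velocity `β·xu − d·xs` is identically zero.  (This initial form is
kept exactly as stated even though it is not the ODE steady state of the
stepping equations — the zero-initial-velocity identity is the property the
downstream consumers rely on.)

Ground-truth velocity is `v = β⊙xu − d⊙xs`.  For benchmarking, a
Gaussian-kernel kNN average with `k = ncell/50` (bandwidth = mean
k-th-neighbour distance, self-weight 1) followed by per-cell norm
normalisation is provided; zero-norm rows are left unnormalised.

## CIFs, GIVs and the encoding of biological factors

Each kinetic parameter matrix is `CIF @ GIV` with four contiguous segments.

* **non-diff** (width `ncif − round(rd·ncif)`): i.i.d. Gaussian(1, σ_cif).
  The mean is fixed at 1 so raw products sit on a positive location before
  rank-scaling (which erases location anyway).
* **diff** (width `round(rd·ncif)`; `rd` is a ratio of counts): tree
  structure.  A Brownian field is sampled once per parameter along the tree
  — every edge is discretised into ≤ 0.1-length sub-steps with Gaussian
  increments of variance equal to the sub-step length — and each cell reads
  the field at its tree position, plus per-cell Gaussian scatter of sd
  σ_cif.  Tree distances therefore set the between-population separation
  while σ_cif sets the within-population spread; this is what makes small
  σ_cif produce tight, separable clusters and large σ_cif loose ones.
  Discrete populations use only the leaf values of the field (cells assigned
  round-robin); continuous populations distribute cells over root-to-leaf
  lineages proportionally to lineage length with stratified-uniform
  positions.  Because the field is a function of position, cells at the same
  position always share the same diff-CIF — a property the stepwise spatial
  simulation relies on.
* **tf** (width = number of TFs): GRN coupling, `s` only.  Entry i of cell
  t is `x_i/(x_i + mean_TF(x))` computed from the predecessor cell's
  expression (the mean runs over TF genes; an all-zero TF expression yields
  0 — zero expression exerts zero regulation).  Root cells draw the segment
  from Gaussian(1, σ_cif).  For kon/koff the tf-GIV is zero (TFs affect
  synthesis only), so those parameters carry no GRN signal.
* **lig** (width = LR-rows × nnbs): CCI coupling, `s` only, described below.

GIV blocks are zero-inflated Gaussians (zero with probability 0.7, else
Normal(0, 1) by default).  For `s`, the tf block *is* the GRN effect matrix
and the diff block ties targets to their regulators: each TF column carries
exactly two entries at a fixed small value (0.2, configurable; no canonical
value exists), each pure-target column is the TF-block product with its
effect-matrix column, and TF-and-target genes average the two.

**Sequential coupling vs global rank-scaling.**  The tf segment of cell
t+1 needs cell t's expression, but expression needs the globally
rank-scaled `s`.  The non-spatial pipeline resolves the cycle with two
passes: pass 1 computes expression with the root rule (Gaussian tf
segments) everywhere; pass 2 rebuilds every cell's tf segment from the
pass-1 expression of its pseudotime predecessor and re-assembles `s`.
Because expression varies smoothly along pseudotime, one refinement pass
captures the regulator-target correlation structure.

A cell-specific GRN mode evolves the edge set along pseudotime: per cell,
each existing edge is deleted with probability `change_rate` and absent
regulator-target pairs are created at the rate that keeps expected density
stable; the full per-cell series is retained for export.

## Chromatin accessibility and its coupling to expression

Every gene is controlled by 1-3 *consecutive* regions with probabilities
`r = (0.1, 0.5, 0.4)` by default (expected 2.3 regions/gene); regions are
abstract indices forming a contiguous cover.  Accessibility is
`CIF_kon @ RIV` (RIV entries: zero w.p. 0.7, else Normal(0, 1)),
rank-scaled to an accessibility reference, plus Gaussian noise with sd 5% of
the reference sd, clipped at 0.  The bundled reference is a zero-inflated
exponential (zero mass `atac_p_zero = 0.7`, rate from `atac_density`) — a
parametric stand-in; a file hook accepts any empirical sample.

The binary TF-motif map is `Mtr[t, j] = 1` iff TF t regulates a gene of
region j, which guarantees the support identity
`support(Mtr @ Mrg) ⊇ support(Mtg)` relating the motif, region-to-gene and
GRN matrices.

Accessibility feeds `kon`: the candidate `M1' = atac @ Z` has its zeros
(closed chromatin) replaced by the corresponding `CIF@GIV` entries rescaled
globally below the smallest nonzero of `M1'` (keeping closed-chromatin genes
ordered rather than tied), then the normalised ranks of the ATAC-driven and
product-driven pathways are blended convexly with weight `Ea` and
rank-scaled to the kon reference.  `Ea = 0` reduces exactly to the pure
product pathway; larger `Ea` strengthens the expression-accessibility
correlation (about 0.1 / 0.29 / 0.44 mean Spearman over single-region genes
at `Ea` = 0.2 / 0.5 / 0.9 under default conditions, as recomputed by the
acceptance script and tests).

## Kinetic-parameter assembly

Rank-scaling replaces a matrix's values with a sorted i.i.d. draw (with
replacement) from an empirical reference, placed by the stable argsort of
the input — rank order is preserved exactly and the output value multiset
follows the reference, so any strictly monotone transform of the input
yields the same output.  The bundled references are log-normal samples
(log10 kon ~ N(−0.3, 0.6), log10 koff ~ N(−0.3, 0.6), log10 s ~ N(1.2,
0.4); 10⁴ draws, fixed seed): parametric stand-ins on the scale of
two-state-model parameters estimated from single-cell data, replaceable by
single-column text files.

`koff` is the rank-scaled product divided by `10^B`; the same divisor is
applied to `kon`, so the bimodality factor `B` is dimensionless, `B = 0` is
the identity, and larger `B` lengthens dwell times (more bimodal, more
zeros).  `s` is the rank-scaled product times `scale_s` (linear cell-size
control).  The zero-replacement rescale in the kon assembly is global, not
per-gene.

## Spatial simulation and cell-cell interactions

Cells occupy a k×k grid with `k = ceil(sqrt(2.5·ncell))` (250% capacity by
default).  One cell is born per step at the tree root; its developmental
path (a uniformly chosen child branch at each junction, advancing by
`tree depth / ncell` per step) is drawn at birth, so its final type is known
and used for placement affinity: with probability `pn` the newborn settles
on a free slot adjacent to a same-type cell.  `layers` and `islands`
pre-layouts are available (blob growth over sorted types / designated island
types, then 5% of positions shuffled).  After n placement steps the
simulation settles for `tc = 10` further steps.  Neighbourhoods are the up
to `nnbs = 4` nearest occupied positions within the radius (exact
4-adjacency at radius 1; diagonals excluded).

For continuous populations, each branch is subdivided into 2 sections and a
cell's type is its current section; this finer typing keeps the CCI truth
and the same-type-exclusion rule meaningful along trajectories (a linear
trajectory split into 5 global sections is used for the bundled layered CCI
fixture).  Type-level CCI truth samples 3-6 LR rows per unordered type pair
(same-type pairs excluded by default); single-cell truth retains exactly
`round(0.8 × implied edges)` of the (neighbour pair, row) edges implied at
the final state.

At every step, each placed cell's `s` is re-assembled: its tf segment from
its own previous-step expression, its lig segment from the previous-step
expression of its neighbours — entry `x_l/(x_l + mean_ligand(x))` for each
LR row active for the two cells' *current* types (so interactions follow the
developmental state), times the lig-GIV effect at the receptor column.
kon/koff are re-assembled from the current tree positions (their tf/lig
segments are static Gaussian draws).  Expression relaxes toward the current
steady state, keeping a fraction `step_persistence = 0.9` of the previous
step: this finite memory is what lets interaction effects acquired at
earlier developmental stages remain visible in the final snapshot, producing
the characteristic ordering of expression correlations — neighbours with an
active interaction (~0.1) > neighbours without > random non-neighbours (~0)
— measured with the 4-neighbour/4-control procedure that excludes same-type
pairs.  Only the final step is emitted; the final Beta-Poisson draw is
centred on the relaxed expression by rescaling `s`.  Velocity mode and the
spatial mode are mutually exclusive (velocity-grid datasets are simulated
without CCI).

## Technical noise and batch effects

Observed RNA counts: per-cell capture efficiency α ~ Normal(0.1, 0.02)
(binomial thinning), 8 amplification rounds with per-molecule success 0.7,
per-cell depth ~ Normal(10⁵, 3000) allocated multinomially over the
amplified pool; non-UMI reports read counts (default), UMI collapses reads
onto captured molecules with a per-gene molecule-pool approximation
(a molecule is detected with probability `1 − exp(−reads/captured)`).
Depth applies before UMI collapse.  True zeros always remain zero.

Batch effects: cells partition round-robin; for gene j in batch i the count
is multiplied by `exp(u)`, `u ~ Unif(μj − eb, μj + eb)`, `μj ~ N(0, 1)`,
then re-rounded (the multiplicative link is this package's choice; only the
shift-factor construction is canonical).  Observed ATAC keeps each entry
with probability 0.3 by default and receives the same batch shifts without
rounding.  An optional per-gene multiplier list on `s` emulates
highly-expressed (housekeeping-like) genes.

## Evaluation metrics

R² of pseudotime is the squared Pearson correlation; kNN purity the Jaccard
overlap of k = 50 pseudotime neighbourhoods; graph connectivity the mean
over types of the largest within-type connected component fraction (kNN
graphs default to k = 15); batch ASW the mean over types of
`1 − |silhouette|` on batch labels (Euclidean, scikit-learn); velocity
cosine the mean per-cell cosine similarity (zero rows skipped and counted);
AUPRC ratio divides AUPRC by the positive prevalence.  The Bonferroni
correction is `min(p·n, 1)` (a printed `max` in some descriptions of this
correction is a typographical impossibility — an adjustment everywhere ≥ 1
corrects nothing).  Summary statistics for real-vs-simulated comparison:
library size and zero proportion per cell; zero proportion, mean and
variance per gene (plus the zero-vs-mean pairing); ATAC library size, cell
sparsity and peak mean.

## Randomness and reproducibility

A single seed drives everything.  Each stage (cif, giv, atac, kinetics,
expression, spatial, noise, grn_dynamics, fixtures) derives an independent
child stream from the seed through a fixed spawn key, so enabling one stage
never perturbs another's draws; identical config + seed reproduces bundles
bit-for-bit.

## What the generator does and does not emulate

The synthetic data carries the designed causal structure — tree-shaped
populations, GRN-driven co-expression, accessibility-gated activation,
spatially localised ligand-receptor correlation, burst noise, capture/depth
noise and batch shifts.  It does not emulate genomic coordinates or peak
structure (regions are abstract), cell motility, doublets or ambient RNA,
isoforms, or empirically calibrated kinetic/accessibility references (the
bundled references are parametric stand-ins).  Passing tests therefore
demonstrate internal consistency of the generative model and correct
recovery behaviour of methods under its assumptions, not performance on any
particular real tissue.

## Problem sizes

The test suite and acceptance script run desk-scale problems chosen to
estimate each quantity stably: 8 × (500 cells × 200 genes) for the
ATAC-RNA coupling, 3-5 × (500 × 500) spatial runs for the CCI correlations,
10 × (500 × 110) for cluster recovery, 10⁵-draw Monte-Carlo for closed
forms.

## Known limitations

* Group (ii) of the CCI correlation check (neighbours without an active
  interaction) has high run-to-run variance: it is estimated from few pairs
  and inherits quenched randomness from which type pairs the truth leaves
  inactive; the documented ordering holds on averages over replicate runs,
  not per run.
* The spatial mode couples accessibility into the final-step kon ranks only;
  intermediate steps ignore `Ea` for speed.
* The evolving-GRN mode keeps the TF list fixed; TFs cannot appear or
  disappear, only their edges.
* `koff`-side GRN effects ("GRN affects the off rate") are not implemented;
  the tf segment of kon/koff is always noise.
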