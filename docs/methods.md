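# Methods

`celldeconv` estimates the cell-type composition of bulk RNA-seq samples and
spatial transcriptomics capture spots. Its core is a dense neural network
trained on simulated pseudobulk mixtures; around it sit a mixture simulator,
an ontology propagation step, a reference-guided transfer-learning
deconvolver, integrated-gradients attribution, and a synthetic single-cell
corpus generator that makes the whole stack testable offline. This note
records the models, their assumptions, and the design choices made where the
design was genuinely open.

## Pseudobulk mixture simulation

A mixture is defined by (T, N, types, F): total cells T ~ Uniform{1..10,000}
(1..1,000 in the fixture-scale recovery setup, matching the low end of
spatial spot sizes through small bulk samples), number of unique types
N ~ Uniform{1..32} clipped to the catalog, type identities drawn uniformly
*without* frequency weighting — this deliberately oversamples rare classes —
and fractions F from a flat Dirichlet (α = 1), the maximum-entropy choice on
the simplex.

Realization converts T·F to integer per-type counts by **largest-remainder
apportionment** (ties broken by catalog position), guaranteeing the counts
sum to T. Cells are sampled without replacement within each type; when a
type's pool is smaller than its target the whole pool is used. The
ground-truth label is the **realized** fraction vector — the composition of
the cells actually averaged — because the drawn F can be unattainable after
rounding or pool exhaustion. Mixture expression is the arithmetic mean of
the selected cells' depth-log-normalized profiles (mean-of-log; a
linear-space option is flag-gated via `MixerParams.linear_space`).

## Normalization and corruption

Two distinct normalizations:

* **Corpus-level** (`depth_log_normalize`): each cell is scaled to 10,000
  total counts and log1p-transformed. This is the space in which mixtures
  are averaged and references are built.
* **Per-input, at the model boundary** (`model_normalize`): scale to 10,000
  (skipped for inputs already in log space), log2(1+x), z-score across genes
  (population SD), min-max to [0, 1]. The z-score makes the result invariant
  to the upstream log base; the pseudocount 1 handles zeros. A constant
  vector maps to all-zeros so empty spots degrade gracefully rather than
  erroring.

During training each normalized input is corrupted: additive zero-mean
Gaussian noise with SD 0.05 on the [0, 1] scale applied to every entry, then
each entry zeroed independently with probability 0.20 — *without* the
conventional 1/(1−p) survivor rescale (an inverted-dropout flag exists for
parity experiments). The SD = 0.05 reading interprets "a value of 0.8 ranges
roughly 0.75–0.85 after noising" as a ±1σ band; it is configurable.
Corruption is inference-disabled.

## The deconvolution network

Architecture: `n_genes → hidden → n_outputs` dense layers, ELU activations,
softmax head (so predictions live on the simplex by construction), no output
regularization. The full-scale configuration is 28,867 genes,
hidden (8192, 4096, 2048, 1024), 840 outputs — 281,395,016 trainable
parameters by the closed form Σ(fan_in+1)·fan_out over the dense stack. The
tiny preset used by the test suite is (200; 256, 128, 64, 32; 8) with 94,952
parameters.

Loss is a **masked ("sparse") MSE**: squared errors are averaged per sample
over the cell types truly present (truth > 0) only, then over samples. With
a large catalog almost every truth entry is a structural zero and an
unmasked MSE would be dominated by them, biasing training toward predicting
zeros.

Optimization: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7), learning rate 1e-4,
batch size 256, up to 50 epochs, 80/20 train/validation split with
validation loss recorded every 5 epochs. The learning rate halves when the
epoch training loss fails to improve by 1e-4 within 5 epochs; training stops
early when it fails to improve by 1.25e-5 within 4 epochs. Both schedules
monitor the *training* loss (a validation-loss option exists). Weights are
Glorot-uniform initialized from the config seed; all forward/backward
passes, the optimizer and the schedules are implemented directly on NumPy
arrays, which at these layer sizes is fast on a single CPU and keeps the
input-gradient machinery (below) in one place.

Gene alignment at inference is by uppercase symbol: missing model genes are
zero-filled, unknown input genes dropped, and fewer than 10% vocabulary
coverage is an error.

## Ontology propagation

Predicted fractions sit at mixed levels of specificity ("t cell" vs "cd4
t cell"), so raw output mass is propagated up a user-supplied cell-type
ontology (child→parent edge list, any DAG): each node receives the summed
raw mass of itself and its **distinct** descendants, computed in reverse
topological order with de-duplication so diamond-shaped DAGs count each
descendant once. On trees this is exactly subtree summation, and a root
covering the whole catalog accumulates mass 1. Propagated values are
"at-or-below" masses and intentionally not a simplex. Internal nodes carry
raw mass 0; catalog names may map to internal nodes.

## Reference-guided transfer deconvolution

When a labeled reference is available: average it into per-type mean
signatures; push signatures and mixtures through the trained network and
take the two middle hidden layers as cell-state embeddings; per feature
block (each embedding layer, plus the top-2000 signature-variance genes),
clip negatives at zero (ELU embeddings can be negative; a shift-to-min
alternative is flag-gated), fit NMF with deterministic NNDSVD-style
initialization on the reference (k = number of reference types by default,
one factor per state), project mixtures onto the fixed dictionary by
non-negative least squares, and batch-align the two component sets;
concatenate blocks per the `use_blocks` ablation setting; then regress.

**Batch alignment.** The default is a parametric per-component
location-scale adjustment with batch ∈ {reference, mixture} and no
covariates — each batch standardized on its own moments and restored to the
pooled moments, which equalizes per-component batch means exactly.
`shrink_combat=True` substitutes scanpy's empirical-Bayes ComBat, which
shrinks per-component batch effects instead of removing them exactly. Either
way the adjustment assumes the mixture batch is *compositionally varied*; a
batch consisting entirely of near-identical spots confounds "batch effect"
with biology and is collapsed toward the reference mean — a known limitation
of no-covariate two-batch adjustment, not specific to this implementation.

**Regression.** Per mixture sample, the component vector (observations =
components) is regressed on the reference component matrix transposed
(predictors = cell types) by a bagging ensemble of 48 linear nu-SVRs
(ν = 0.5) fit on bootstraps of the component observations. Because the
number of observations is of the same order as the number of predictors, a
near-interpolating fit is wanted: design and response are standardized by
the design's pooled moments (making regularization scale-free) and the SVM
cost is C = 10 with a 2,000-iteration solver cap — bagged coefficient
averages are insensitive to the final digits of each fit, and the cap
bounds runtime. Degenerate bootstraps are redrawn (with a full-design
fallback). Averaged primal coefficients are clipped at zero and renormalized
to the simplex, with a uniform fallback if every coefficient is
non-positive.

## Integrated-gradients attribution

For a target cell type j, attributions accumulate ∂F_j/∂x along the straight
path from the zero baseline to the normalized input, approximated by a
trapezoidal Riemann sum over m interpolation points α_k = k/(m−1)
(default m = 50), and are scaled elementwise by (x − 0) — so unexpressed
genes receive exactly zero attribution. The randomized variant additionally
zeroes each gene at step k with probability 1 − α_k (dropout descending
100%→0% along the path), emulating lower read depth; masks are drawn
independently per step and gene from a fixed seed. Randomization breaks the
completeness axiom, so a deterministic mode exists for axiomatic testing:
on a linear map the trapezoid rule is exact at any m ≥ 2, and on the trained
tiny network the relative completeness gap |Σᵢ aᵢ − (F(x) − F(0))|/|F(x) −
F(0)| falls well below 1% by m = 200. Gradients are taken on the
inference-mode graph (corruption off) with respect to the already-normalized
input; the per-input normalization itself is treated as preprocessing, not
differentiated through.

## Evaluation

Agreement is scored by **Lin's concordance correlation coefficient**,
CCC = 2·cov(x,y) / (var x + var y + (mean x − mean y)²), with population
moments for determinism (a sample-moment flag exists; the difference
vanishes at benchmark n). Unlike Pearson's r, CCC penalizes location and
scale shifts, which matters for fraction estimates. The fully degenerate
pair (both constant) returns 0 from the scalar function; in benchmark
tables, both-constant columns with equal means report 1 with a `degenerate`
flag (the predictions agree exactly), and such columns never arise in the
standard benchmarks.

Sensitivity sweeps perturb one mixing hyperparameter at a time around the
baseline (T = 100 cells, N = 5 types, 0% gene dropout); gene dropout removes
the stated fraction of each sample's *expressed* genes before the model's
per-input normalization. Spatial downsampling assigns cells to square bins
by floor(coord/bin), averages member depth-log-normalized profiles per bin
("mean-of-log", consistent with the mixer), and reports per-bin type-count
fractions as truth; every cell lands in exactly one bin.

## The synthetic corpus

The generator emulates what matters for recovery testing: per-type mean
signatures with disjoint marker blocks (default 8 types × 10 markers among
200 genes, marker fold-change 8 over a base mean of 2), negative-binomial
counts (Gamma–Poisson with overdispersion α = 0.3, var = μ + αμ²), and
per-cell depth resampled to a uniform target in 1,000–5,000 counts by
multinomial thinning, independently of type — so depth cannot confound type
recovery. Spatial fixtures place cells on a jittered grid (default 10 µm
spacing) and draw each cell's type from its Voronoi niche's
Dirichlet-sampled composition. Disjoint marker blocks make ground truth
unambiguous; an optional `leakage` parameter (default 0) introduces shared
signature structure.

What the generator does **not** emulate — ambient RNA, doublets, batch
effects, realistic gene-gene correlation, and the extreme dimensional
redundancy of a ~29k-gene transcriptome — bounds what passing tests show
about real data. In particular, robustness to input-gene dropout at full
scale rests on that redundancy (thousands of correlated non-canonical
markers, and inputs dominated by structural zeros that anchor the per-input
normalization); a 200-gene fixture with 10 markers per type cannot exhibit
it, and its accuracy under heavy gene dropout degrades much earlier than a
full-scale model's would.

## Problem sizes in the standard runs

The test suite and the acceptance script train the tiny preset on 5,000
mixtures (seconds on one CPU), benchmark the transfer model on 200 mixtures
of 100 cells against a disjoint-half reference, run sweeps at 200 replicates
per grid point, and use 300 held-out mixtures for the base-model score —
sizes chosen so the full pipeline, including three transfer ablation modes,
completes in well under a minute while keeping Monte-Carlo noise on mean
CCCs at the ±0.01 level.

## Known limitations

* Checkpoints store dense weights in HDF5; no quantization or sharding.
* The ontology is user data; no OBO parsing and no reconciliation that
  redistributes mass downward.
* ComBat-style alignment assumes compositionally varied mixture batches
  (see above).
* Early stopping monitors training loss; with heavy corruption the epoch
  loss is itself noisy, so the delta thresholds act on a moving target.
* The CLI holds everything in memory; it targets fixture-to-moderate scales,
  not million-cell corpora.
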