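# Methods

This note documents the model implemented by `slicealign`, its
assumptions, the parameters that matter, the synthetic study conditions,
and the numerical choices made where the design was genuinely open.

## Model and assumptions

The package treats slice alignment as matching between two attributed
spatial graphs. The assumptions, in order of importance:

* **Shared molecular structure.** The two slices measure overlapping
  feature sets (or arrive as embeddings in a common space). The
  cross-dataset SVD (`X1 = U_{1:M}Σ^{1/2}`, `X2 = V_{1:M}Σ^{1/2}` from
  `G̃1G̃2ᵀ = UΣVᵀ`) keeps only covariation present in *both* slices, which
  is what makes it a batch correction: slice-private technical axes do not
  survive the cross-product. It is linear; strong nonlinear batch effects
  are out of scope (use an external integration embedding instead).
* **Spatial coherence.** Cells that are neighbours in one slice tend to
  have matching partners that are neighbours in the other. This is encoded
  twice: by the LGCN (multi-scale neighbourhood averages as features) and
  by candidate sets restricted to the spatially nearest `K` cells after
  rigid registration.
* **Partial correspondence.** Slices need not overlap fully. Dynamic
  clipping (keep the fraction `c` of cells per slice the critic ranks
  closest across slices) means only putative anchors drive the Wasserstein
  term, and the empirical-null p-value lets any cell end up unmatched.
* **Rigid geometry.** Coordinate registration fits rotation + translation
  (+ isotropic scale). Non-rigid deformation is absorbed by the embedding
  space and the width of candidate sets, never by warping coordinates.

## Parameters

| name | default | meaning / why |
| --- | --- | --- |
| `preprocess.svd_dim` (M) | 30 | shared embedding width; enough for tens of cell types |
| `preprocess.target_sum` | 1e4 | library-size target before `log1p`; ecosystem convention |
| `preprocess.scale_clip` | 10 | cap on z-scores; guards single outlier spots |
| `graph.K` | 50 | spatial neighbours per cell; `K1`/`K2` may differ to balance unequal resolutions |
| `lgcn.L` | 3 | propagation depth; block ℓ averages ~ℓ-hop neighbourhoods |
| `model.embed_dim` (P) | 50 | alignment-space width |
| `model.embed_hidden` | 2048 | projector hidden width |
| `model.hidden` | 256 | critic/reconstructor hidden width |
| `model.alpha` | 0.5 | adversarial vs reconstruction weight; symmetric default, exposed prominently |
| `model.clip_ratio` (c) | 0.6 | anchor fraction; performance depends only weakly on it (tested 0.4–0.8) |
| `model.lr` | 1e-4 | Adam step size for all three networks |
| `model.steps` | 500 | full-batch generator steps, 1 critic step each; early-stops on plateau |
| `model.weight_clip` | 0.1 | critic weight bound (Lipschitz control) |
| `coords.n_starts` | 12 | ICP initial rotations (30° grid) |
| `match.K` | = graph K | candidate-set size; independent override available |
| `match.n_null` | 1000 | null pairs for the empirical p-value |
| `match.threshold` | 0.05 | acceptance p-value cut |

Units: coordinates are dimensionless planar positions (consistent within a
slice; no unit conversion); angles are degrees; counts are raw integers.

## Training and numerical choices

* **Networks in NumPy.** `f_Z`, `f_D`, `f_R` are two-layer perceptrons
  (LeakyReLU 0.2, He-style init, float32) with hand-written
  forward/backward passes and full-batch Adam. At the package's design
  scale (up to a few thousand cells per slice) full-batch dense matmuls
  are fast, simple, and bit-reproducible given the seed; there is no
  minibatching, so dynamic clipping always sees critic scores for *all*
  cells, matching the definition of the anchor sets exactly.
* **Lipschitz control by weight clipping.** The Wasserstein critic must be
  bounded; we clip its weights to ±`weight_clip` after each update. The
  clipping bound interacts with `lr` only weakly at these scales; the
  alternative (a gradient penalty) needs second-order derivatives that the
  explicit-backprop design would have to derive by hand, for no observed
  benefit on this problem class.
* **Alternation.** Each step: one critic ascent on `α·L_W` over the anchor
  sets (recomputed from current critic outputs on all cells), then one
  generator descent on `α·L_W + (1−α)·L_R` with critic parameters frozen.
  `ablate="no_discriminator"` sets `α = 0` (reconstruction only);
  `ablate="no_lgcn"` forces `L = 0` upstream.
* **Determinism.** One `numpy` PCG64 generator per stage, all derived from
  the global seed via `SeedSequence` in a fixed order (`synth, model,
  null, icp, bench`). Repeated runs are byte-identical (single-threaded
  BLAS or not, on the same platform). SVD sign ambiguity is fixed by
  making the largest-|entry| of each left singular vector positive.
* **Ties.** k-NN distance ties break toward the lower cell index (exact
  via stable argsort up to ~2k points, KD-tree order beyond);
  dynamic-clipping ties likewise; best-match ties break by smaller
  p-value, then larger cosine, then lower index.
* **Degenerate inputs.** All-zero cells must be filtered (`min_counts`,
  default 1 — whether such spots should be dropped silently is genuinely
  ambiguous, so it is an explicit flag). Zero-variance features scale to
  0. Isolated graph nodes keep a self-loop through `Â`, so propagation is
  always defined. Collinear point sets in the Procrustes fit warn and
  return the SVD solution. `floor(c·N)` with a minimum of 1 sizes the
  anchor sets.
* **ICP.** Multi-start (12 rotations) because a 60° offset is outside the
  identity basin; each start alternates NN correspondence with the
  closed-form Umeyama fit; the RMS residual is monotone under this
  alternation, which is the convergence measure. Clouds above 5,000 points
  are subsampled once, seeded, for the correspondence search.
* **Empirical p-values.** Add-one estimator `(r+1)/(n+1)` of the
  exceedance probability — never exactly 0, in (0, 1], and calibrated:
  under permuted embeddings the acceptance rate at 0.05 is ≈ 5%. One null
  (1,000 uniform cross-slice pairs, dedicated seed) is shared by all
  cells; per-cell nulls would cost 1000·N draws for little gain at this
  threshold.

## Synthetic study conditions

`slicealign.synth` generates everything the benchmarks need; no downloads.
A structured slice tiles a 1.5×1.0 rectangle into a 2×2 grid of regions
with unequal cell fractions (0.35/0.30/0.20/0.15 — the asymmetry gives
rigid registration a unique optimum), draws each cell's type from its
region's composition (three types shared by all four regions with
different mixing — i.e. types are spatially interlaced), gives each type a
log-normal expression profile over 200 genes, and samples counts from a
negative binomial via the Gamma–Poisson mixture (`mean μ`, inverse
dispersion `θ`; variance `μ + μ²/θ`). Defaults: 500 cells, `θ = 10`,
duplicates rotated 60°.

What this emulates: labelled types nested in labelled regions, overdispersed
counts, rigid misorientation, partial slices (splits). What it does not:
spot-lattice geometry (Visium), segmentation errors, spatially smooth
expression gradients within a region, contamination/doublets, and real
batch effects beyond count noise. Passing tests therefore demonstrate the
mechanics and calibration of the method under controlled conditions, not
performance on any particular tissue or platform.

Benchmark protocols run at reduced problem sizes chosen to keep the full
grid of repeats comfortably desk-scale: 300-cell slices, SVD dim 20,
`K = 20`, 120 training steps, narrower networks (these are the package's
benchmark defaults in `config["benchmark"]`; the headline self-alignment
run uses the full 500-cell defaults). Eight repeats with different seeds
for stochastic tasks, three for the ablation and clipping comparisons.
The LGCN ablation is evaluated with *global* candidate sets (`K = N2`) and
heavy noise (`θ = 1`): with spatial candidate filtering active, coordinate
proximity alone would mask the embedding difference being measured.

## Known limitations

* The cross-SVD requires overlapping features; disjoint modalities must
  arrive as precomputed joint embeddings (`is_embedding=True`).
* Weight clipping caps critic capacity; with very wide critics or extreme
  `lr` the Wasserstein estimate can saturate. The defaults avoid this.
* The edge score is reported but intentionally not trusted as a primary
  metric: pairings that swap structurally equivalent groups tie the
  correct pairing (reproduced as a test); prefer ground-truth or label
  accuracies.
* Exact k-NN only (KD-tree); fine to ~10⁶ cells, no approximate-NN path.
* ICP fits a single global rigid motion; mirrored sections (reflections)
  are detected by the Procrustes determinant guard but not corrected
  automatically.
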