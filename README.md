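# slicealign

Graph-adversarial alignment of spatially resolved omics slices.

Spatially resolved transcriptomics measures molecular profiles of cells or
spots together with their 2-D tissue positions. Comparing two slices — a
consecutive section, a technical replicate, a different developmental stage
or even a different modality — requires matching cells *across* slices so
that labels, states and structures can be transferred. `slicealign`
performs this matching for cell/spot-resolution data by combining molecular
similarity with spatial context, and is aimed at analysts who need
per-cell cross-slice matches with a confidence measure, not just a global
overlay of coordinates.

## Method

Each slice is a dataset `D = {(g_i, s_i)}` of omics features `g_i ∈ R^G`
and planar coordinates `s_i ∈ R^2`. The pipeline runs:

1. **Joint embedding with batch correction.** With log-normalised, scaled
   matrices `G̃1 (N1×G)`, `G̃2 (N2×G)` over shared features, the SVD
   `G̃1 G̃2ᵀ = U Σ Vᵀ` yields `X1 = U_{1:M} Σ_{1:M}^{1/2}` and
   `X2 = V_{1:M} Σ_{1:M}^{1/2}` (default `M = 30`). Covariation shared by
   both slices dominates the leading components, suppressing batch effects.
   Precomputed cross-modality embeddings can be substituted.
2. **Spatial graphs.** Per slice, a K-nearest-neighbour graph over
   coordinates (default `K = 50`, union-symmetrised; radius graphs
   supported), with the normalised operator
   `Â = D̃^{-1/2}(A + I)D̃^{-1/2}`.
3. **Lightweight graph convolution.** The holistic representation
   `X̃ = Concat(X, ÂX, Â²X, …, Â^L X)` (default `L = 3`) stacks the cell's
   own profile with its microenvironment and coarser positional context —
   no learned weights, no nonlinearity.
4. **Adversarial alignment.** A shared MLP projector `f_Z` maps `X̃1, X̃2`
   to `Z1, Z2 ∈ R^{N×P}`. A Wasserstein critic `f_D` is trained to maximise
   `L_W = mean_{V1'} f_D(z1) − mean_{V2'} f_D(z2)` where the anchor sets
   `V1', V2'` retain only the fraction `c` of cells (default `c = 0.6`)
   judged closest across slices by the critic itself — *dynamic clipping*,
   which prevents forcing structurally distinct regions onto each other.
   The generator minimises `α·L_W + (1−α)·L_R`, where the reconstruction
   loss `L_R` (an MLP `f_R` decoding `Z` back to `X`) prevents embedding
   collapse.
5. **Coordinate registration.** A rigid(+scale) affine transform is
   estimated landmark-free with multi-start ICP (or supplied manually) and
   applied as `S2' = S2·M`.
6. **Probabilistic matching.** For each slice-1 cell, the `K` spatially
   nearest slice-2 cells (in the registered frame) are scored by embedding
   cosine similarity; significance is assessed against an empirical null of
   1,000 random cross-slice pairs, and candidates with `p < 0.05` are
   accepted.

Evaluation utilities cover ground-truth accuracy for duplicated slices,
cell-type/region contingency and joint accuracy, micro/macro F1, Procrustes
rotation recovery, and the (gameable) neighbourhood edge score. A synthetic
module generates all benchmark inputs: structured labelled slices,
negative-binomial noisy duplicates, random splits, subsamples and graph
corruptions.

## Worked example

```python
import numpy as np
from slicealign import SynthConfig, make_structured_slice, duplicate_with_noise
from slicealign.pipeline import align_pair, evaluate_alignment, load_config

s = make_structured_slice(SynthConfig(seed=1))          # 500 labelled cells
dup = duplicate_with_noise(s, theta=1e6, rotate_deg=60, seed=2)
res = align_pair(s, dup, load_config({"seed": 1}))
m = evaluate_alignment(res, s, dup, truth=np.arange(s.n_cells),
                       applied_rotation=60.0)
print(m["ground_truth_accuracy"], m["rotation_error_deg"], m["joint_accuracy"])
```

prints

```
1.0 0.0 1.0
```

every cell's best match is its true duplicate (`ground_truth_accuracy`),
the 60° artificial rotation is undone exactly by the recovered corrective
angle (`rotation_error_deg`, degrees), and each matched partner carries the
correct cell type and spatial region (`joint_accuracy`). At heavier count
noise (inverse dispersion `theta = 1`) accuracy degrades gracefully to
roughly 0.86 on the same conditions.

The same pipeline is available from the shell:

```bash
slicealign synth -o slice1.h5ad --n-cells 500 --seed 1
slicealign align slice1.h5ad slice2.h5ad -o run/ --seed 1
slicealign benchmark --task duplicate -o duplicate.tsv
```

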