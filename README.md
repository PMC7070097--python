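# toporsa

Representational similarity analysis (RSA) between brain regions and
convolutional network layers, including *topographical correlation
maps*: spatially resolved brain–model comparisons with nonparametric
cluster inference.

## The scientific problem

Regions along the human ventral visual stream prefer both particular
categories (faces in the fusiform gyrus, scenes in parahippocampal
cortex) and particular parts of the visual field (foveal vs peripheral
bias). Convolutional networks trained for object/scene categorization
retain a spatial layout in their feature maps, which makes the
analogous question testable in a model: do units at central image
positions carry representations that match centrally biased brain
regions, and peripheral units match peripherally biased ones?

`toporsa` implements the full analysis pipeline for this question:

1. **RDMs.** For each system, responses to `n` stimulus conditions are
   vectorized into condition × feature pattern matrices and summarized
   by a representational dissimilarity matrix with entries
   `d_ij = 1 − r(p_i, p_j)` (Pearson correlation across features).
   fMRI beta patterns are first noise-normalized: `P ← P Σ^(−1/2)`,
   with Σ the voxel noise covariance estimated from GLM residuals by a
   shrinkage estimator.
2. **Layerwise RSA.** Subject ROI RDMs are compared with whole-layer
   RDMs by Spearman's ρ on the lower triangles; group summaries report
   mean ± SEM over subjects, one-sided sign-flip significance
   (Bonferroni-corrected over the layer × ROI family) and leave-one-out
   noise ceilings.
3. **Topographical maps.** Within a layer's `H × W × D` activation
   tensor, each grid position `(x, y)` contributes a depth-vector
   pattern per condition, hence a local RDM; correlating each local RDM
   with an ROI RDM yields an `H × W` correlation map per subject,
   upsampled (bilinear) to image resolution for display.
4. **Group inference.** Two-sided sign-flip permutation tests (random
   ±1 flips of whole subject maps) give pointwise p-values; clusters of
   cells below the cluster-defining threshold (CDT 0.01) are tested
   against the permutation null of the maximum cluster size anywhere on
   the map, controlling the familywise error at α = 0.05
   (1000 permutations at full scale).
5. **MDS.** Classical (Torgerson) multidimensional scaling embeds the
   conditions of any RDM in 2-D for visualization.

Because the underlying fMRI data and network weights are not
redistributable, the package ships a first-class synthetic generator
that emulates the study design — 156 conditions in 5 categories
(faces, animal bodies, people, objects, scenes), 15 subjects, beta
patterns with AR(1)-correlated voxel noise and matching residuals, and
layer tensors whose channels carry the same latent category code under
a center- or periphery-weighted spatial gain — so every stage is
testable end-to-end with known ground truth.

## Worked example

```python
from toporsa import get_profile, run_pipeline, make_report

config = get_profile("ci", seed=1)   # 40 conditions, 8 subjects, 13x13 grids
manifest = run_pipeline(config, "out/demo")
make_report("out/demo")
```

This writes, among other artifacts, `out/demo/layerwise.csv`; the
fusiform-analog rows from the run above are:

```
 layer  mean_rho      sem  p_corrected  significant  ceiling_lower  ceiling_upper
layer1  0.124753 0.013132     0.078125        False       0.469714       0.623602
layer2  0.247434 0.013010     0.078125        False       0.469714       0.623602
layer3  0.275013 0.008988     0.078125        False       0.469714       0.623602
layer5  0.258657 0.007164     0.078125        False       0.469714       0.623602
```

`mean_rho` is the across-subject mean Spearman correlation between
each subject's noise-normalized ROI RDM and the layer RDM; the noise
ceiling `[0.47, 0.62]` bounds what any model could reach given
between-subject variability. With only 8 subjects the exhaustive
sign-flip floor is 2⁻⁸, so the Bonferroni-corrected p cannot drop
below 0.078 — layerwise stars appear only at larger N (the `paper`
profile uses 15 subjects, floor 3.05e−5). Cluster inference on the
topographical maps is not limited this way: the same run finds e.g.
3 significant clusters for `layer1 × fusiform_analog`
(`clusters_layer1_fusiform_analog.csv`), and the grayscale
`topomap_*.png` images show where in image space each layer matches
each ROI.

The same pipeline is available from the shell:

```sh
toporsa run --profile ci --seed 1 --out out/demo
toporsa report --run-dir out/demo
```

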