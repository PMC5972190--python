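# otomorph

Denoising and automatic segmentation of osmium-tetroxide contrast-enhanced
micro-CT volumes of the human inner ear.

OsO₄ staining binds unsaturated lipids, so myelinated neural tissue —
spiral-ganglion neurons, nerve fiber bundles, nerve crossings — appears
hyperdense inside the far less radiodense decalcified temporal bone.
Rendering that anatomy in 3-D requires removing two kinds of noise without
blurring micrometre-scale structures: voxel-level sensor noise, and small
bright unconnected specks that clutter a volume rendering. `otomorph`
implements two deterministic processing chains for this task, plus a
synthetic phantom so that every stage can be verified quantitatively
without access to scan data.

## The algorithms

**2-D visualisation chain** (slice viewing):

1. *Histogram matching* — every slice's empirical intensity distribution is
   remapped onto a chosen reference slice through the monotone quantile map
   F<sub>ref</sub>⁻¹∘F<sub>k</sub>, cancelling intensity drift along the
   scan axis.
2. *Iterated edge-preserving smoothing* — 4 repeats of the triplet
   (guided filter, bilateral filter, guided filter), i.e. 12 nonlinear
   filter applications. The self-guided **guided filter** (r = 1, ε = 1)
   fits a local linear model per 3-D box window: a = σ²/(σ²+ε),
   b = (1−a)·μ, output q = ā·I + b̄. The **bilateral filter**
   (σ = 1 voxel, μ = 0.00017) weights each neighbour by
   G<sub>σ</sub>(‖x−y‖)·exp(−(I(x)−I(y))²/2μ).
3. *Sharpen* — unsharp masking, q = I + α(I − G(I)).

**3-D visualisation + automatic segmentation chain**:

1. guided filter (r = 1, ε = 1);
2. **white top-hat** with a 3-D cross structuring element of radius 64 —
   input minus its morphological opening, extracting bright structures
   narrower than the SE from the slowly varying background;
3. **binarise** at the absolute threshold 0.035 (intensities are normalised
   by the 16-bit type maximum, so the threshold has a fixed physical
   meaning);
4. **geodesic opening** of size 15 — erosion by a 31³ box followed by
   morphological reconstruction under the mask: connected components too
   small to survive the erosion are deleted entirely, survivors are
   restored voxel-identically;
5. **closing** (box, radius 2) and **dilation** (cross, radius 1) pad the
   mask;
6. **image multiply** — the mask times the top-hat output is the
   render-ready segmented volume. An optional manual mask is intersected
   with the automatic one.

All morphology by cross and box SEs runs through 1-D line min/max filters
whose cost is independent of the radius, so the radius-64 top-hat is as
cheap as a small one.

## Worked example

```python
from otomorph import (PhantomSpec, PipelineConfig, generate_phantom,
                      run_pipeline_3d, score_segmentation,
                      count_components_overlapping, LABELS)

vol, truth = generate_phantom(PhantomSpec(seed=42))   # 160^3 phantom
denoised, mask, segmented, report = run_pipeline_3d(vol, PipelineConfig())
score = score_segmentation(mask, truth, LABELS["nerve"], boundary_tolerance=1)
print(f"dice={score.dice:.3f} recall={score.recall:.3f}")
print("surviving speckles:",
      count_components_overlapping(mask, truth.labels == LABELS["speckle"]))
```

prints

```
dice=0.892 recall=1.000
surviving speckles: 0
```

The phantom injects 60 bright speckle blobs plus a connected nerve network
(trunk + fibers); the chain recovers the nerve with Dice 0.89 at a 1-voxel
boundary tolerance, keeps it as one component with full recall, and deletes
every speckle — the behaviour the chain exists for.

The same run from a shell:

```sh
otomorph phantom --size 160 --seed 42 --out phantom.nrrd --truth-out truth.nrrd
otomorph segment3d phantom.nrrd -o run/
otomorph eval --pred run/mask.nrrd --truth truth.nrrd --label 3
```

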