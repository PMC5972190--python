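# Methods

## Scope and data model

`otomorph` operates on 3-D scalar volumes in normalised intensity units.
Integer samples are divided by their **type maximum** (65535 for 16-bit),
never the observed maximum: the segmentation chain applies one absolute
binarisation threshold (0.035), and per-volume rescaling would silently
change its meaning. Floating-point inputs are clipped to [0, 1]. The axis
order is `(z, y, x)` with `z` the acquisition/stack axis; slice `k` of a
TIFF stack is `data[k]`. Voxel spacing (µm) is carried as metadata and is
descriptive only — every filter is defined in voxel units. Missing spacing
metadata is replaced by (1, 1, 1) µm with a warning, never an error.

## Filters

**Guided filter (self-guided).** For each 3-D box window *w* of half-width
*r*: `a = var(I_w) / (var(I_w) + eps)`, `b = (1 - a) * mean(I_w)`; the
output at a voxel averages `(a, b)` over all windows containing it and
evaluates `q = A*I + B`, clipped to [0, 1]. The guide equals the input —
no separate guide volume exists in this setting. Borders are handled by
reflecting the volume by `2r` voxels so that window statistics near faces
are well defined; window means are computed with separable uniform filters
in float64 (agreement with direct window enumeration is ~1e-13, bounded at
1e-8 in tests). Window variance is clamped at 0 to absorb one-pass
cancellation error. With `eps = 1` on normalised data (variance ≤ 0.25)
every `a ≤ 0.2`, making the filter a strong but edge-aware smoother.

**Bilateral filter.** Exact (non-approximated) weighted mean over a cubic
support of half-width `ceil(2*sigma)` (2 voxels at the default
`sigma = 1`), reflect-padded. The range kernel is `exp(-d^2 / (2*mu))`
with `mu` read as a **variance** of normalised intensity — `mu = 0.00017`
corresponds to a range std of ≈ 0.013, i.e. ≈ 850 grey levels of a 16-bit
volume. Weights are strictly positive, so the output is a convex
combination of neighbourhood values and needs no clipping. At very large
`mu` the filter provably degenerates to a normalised truncated Gaussian
blur; a test pins this limit at 1e-6.

**Sharpen.** Unsharp masking `q = clip(I + amount*(I - G_sigma(I)))` with
`amount = 1`, `blur_sigma = 1` as declared defaults (the operating point
published for this step names no parameters).

**Histogram matching.** Per slice, the monotone quantile map
`F_ref^-1 ∘ F_k` interpolated piecewise-linearly between 1024 quantile
knots (configurable); an exact per-value mode (sort/cumulative matching via
scikit-image) is available for integer-sourced data. The reference slice
defaults to the middle slice `nz // 2`. A constant reference slice leaves
the map undefined and raises an error — except when the entire volume
equals that constant, in which case the volume passes through unchanged
(the chain must be the identity on constant volumes).

## Morphology

Structuring elements are **cross** (offsets with at most one nonzero
coordinate — three axis-aligned segments through the origin, the 3-D
analogue of a 2-D cross matrix), **box** (full cube) and **ball**
(Euclidean). Erosion/dilation by crosses is the pointwise min/max of three
1-D line filters; boxes are separable into three sequential line filters.
The 1-D filters use a moving-window algorithm whose cost is independent of
the radius (the van Herk/Gil–Werman contract; a test bounds the r = 64 /
r = 8 runtime ratio at 2 on a 128³ volume), and both decompositions are
bit-identical to direct offset enumeration.

Grayscale operators pad by edge replication (avoids darkening at volume
faces); binary operators pad with background, so a component touching a
face can be eroded from that side — documented and configurable via
`border_value`. Binary **closing** is computed on a grid extended by the SE
radius and cropped back: composing the two background-padded primitives
directly would violate extensivity (`input ≤ closing`) at the faces,
whereas for box SEs the extended-grid computation equals the ideal closing
(a closing by a convex SE never leaves the input's bounding box) and is
idempotent.

**Binarisation** uses `>=` at the threshold: a voxel exactly at 0.035 is
foreground (a declared tie-break).

**Geodesic opening** of size *s*: the marker is the erosion of the mask by
`box(s)`; the result is the morphological reconstruction by dilation of the
marker under the mask. It is implemented by connected-component
bookkeeping — keep exactly the components containing a marker voxel — which
is equivalent and exact; tests verify it against an independent
reconstruction implementation (scikit-image) and its idempotence. The
"Closing 2" and "Geodesic opening 15" steps name sizes without shapes; box
SEs of half-widths 2 and 15 are used, since integer-radius morphology in
the original processing environment is box-ranged, and "cross" appears only
where a cross matrix is named explicitly. Reconstruction connectivity
defaults to 26 (preserves thin diagonal fiber paths), configurable to 6.

## Pipelines

Both chains are deterministic end to end: same input and config give
bit-identical output. "12 iterations" of the two nonlinear filters is
interpreted as 12 total filter applications = 4 repeats of the triplet
(guided, bilateral, guided); the alternative reading is selectable by
setting `block_iterations = 12`. Histogram matching runs once, first.
In the 3-D chain the final mask multiplies the **top-hat output** (the
processed volume), not the raw input; a manual mask, when supplied, is
ANDed with the automatic mask, since manual segmentation in this workflow
excludes circumjacent structures rather than adding any. Per-stage wall
times and output statistics are recorded in a report (JSON); timings are
hardware-dependent and never asserted.

## Phantom

The generator emulates the image content the chains act on, not cochlear
anatomy or CT physics: a solid trunk ball with thin curved fibers fanning
out of it (label *nerve*, one connected component), a helical membrane
wall, a spherical bone shell, and mutually unconnected bright speckle
blobs, followed by Gaussian partial-volume blur (σ 0.7 voxel), a linear
slice-to-slice intensity ramp (amplitude 0.05) and additive Gaussian sensor
noise (σ 0.02). Default class intensities are background 0.02, bone 0.15,
membrane 0.25, nerve/speckle 0.55 — plausible stand-ins encoding the
contrast ordering of an OsO₄-stained scan, not measurements. Geometry
scales with the volume edge (trunk radius 0.2125·N, etc.) so the default
160³ phantom admits the 31³ box the geodesic opening requires inside the
trunk, while the classes stay ≥ 6 voxels apart so blur and noise cannot
connect them; speckles (60 by default at 160³, each of radius 1–3) are
rejection-sampled at that clearance. Truth labels are recorded **before**
blur and noise, so scoring uses a 1-voxel boundary tolerance implemented
with Euclidean distance transforms. All randomness flows through numpy's
PCG64 generator seeded from the spec, making generation bit-reproducible.

What passing on the phantom does *not* show: robustness to beam hardening,
blooming, ring artifacts, anisotropic resolution, or staining gradients of
real micro-CT; and the phantom's noise is stationary Gaussian, unlike CT
reconstruction noise. Results on the phantom validate the algorithmic
contracts, not clinical performance.

## Metrics

Dice, precision and recall are computed on voxel counts with a boundary
band (default 1 voxel, always reported) excluded from FP/FN. Component
counts split the prediction's connected components into those overlapping
the target label and the rest. Region contrast is
`|mean_a − mean_b| / sqrt((sd_a² + sd_b²)/2)` with population (ddof = 0)
standard deviations; a zero pooled sd is flagged degenerate rather than
raised, so sweeps over noiseless inputs do not abort.

## Problem sizes and numerical choices

The test suite and the acceptance script use the 160³ phantom, a 128³ flat
noise block, 8³/6³ oracle volumes (20 seeds each) and 16³–48³ morphology
volumes — sizes at which every brute-force oracle is exact and the whole
suite completes in well under a minute, while still exercising the r = 64
top-hat at full radius. Filter arithmetic is float64 throughout;
morphological min/max involves no arithmetic and is exact. Oracle
tolerances: guided 1e-8, bilateral 1e-10, bilateral large-μ limit 1e-6,
morphology bit-identical.

## Known limitations

* No DICOM or vendor projection formats; no out-of-core processing —
  volumes must fit in memory (the multi-GB scans this method targets need
  ~10× their size in RAM with float64 arithmetic).
* Only cross/box/ball SEs; no grayscale reconstruction or watershed.
* The bilateral filter is exact, hence O(support³) per voxel; no bilateral
  grid or other fast approximations.
* TIFF spacing round trips rely on ImageJ-style tags; exotic resolution
  units are ignored.
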