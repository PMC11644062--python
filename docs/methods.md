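# Methods

This note documents the models, parameter choices and numerical conventions
behind `canopyseg`, and what the synthetic-scene validation does and does
not demonstrate.

## Reflectance calibration

Reflectance is computed per pixel and band as `R = (I − B) / (W − B)` from a
raw capture `I`, a white-reference capture `W` and a dark-current capture
`B` of identical geometry. Entries with `W − B ≤ ε` (default `ε = 1e-6`)
cannot be normalised; they are set to 0 and recorded in an explicit boolean
validity mask instead of being propagated as NaN/Inf, so gray-level
histograms and region means downstream remain well defined. Negative
reflectances (sensor noise below the dark level) are clipped to 0; values
above 1 (specular or overexposed pixels) are retained because they carry
real scene structure that thresholding must cope with. Calibration is
per-pixel throughout: the references are not spatially averaged, since the
elementwise form is what the defining formula states and it preserves any
spatial non-uniformity of the illumination into the references.

## File format

Cubes are exchanged as an ENVI-style text header plus raw binary payload.
The dialect is deliberately small: BSQ/BIL/BIP interleaves, little-endian
float32 and uint16, wavelengths in nm in the header. The reader validates
that payload size matches the declared dimensions and fails loudly
otherwise; the writer emits BSQ/float32 by default. Round-trips are
value-exact for the supported dtypes.

## Spectral-ratio wavelength selection

Per-region mean spectra are arithmetic means of the full spectral vectors
over the region's valid pixels. Ratio curves divide the leaf mean by each
background mean, flooring the denominator at `1e-4` so the ratio stays
finite where a background reflectance vanishes. The background set defaults
to {stage, soil, pot}; shadowed leaf is treated as part of the target (it
is merged into the canopy at the end), with an option to include it as a
ratio reference.

Peak picking returns the `n = 2` highest *local* maxima per curve (a strict
local maximum beats both neighbours; a flat plateau strictly above both
flanks counts once, at its centre, ties to the lower index). On empirical
curves the region means carry noise — with the default scene parameters
roughly 0.5–1% per band relative on the darker backgrounds, dominated by
impulse pixels — which decorates broad ratio maxima with spurious wiggle
maxima. The end-to-end selector therefore applies two standard peak-finding
guards, both configurable: a minimum topographic prominence (default 5% of
the curve's range) and a minimum separation between returned peaks (default
6 bands). The low-level `top_peaks` function defaults to permissive values
(prominence 0, separation 1) and then implements the strict local-maximum
contract exactly.

Pooled picks are pruned greedily in descending ratio order: a pick survives
only if the Pearson correlation between its band image and every
already-kept band image stays below `r_threshold`. The default is 0.999,
i.e. pruning removes only *effectively duplicate* measurements — the same
peak wavelength found from two different background curves (correlation
exactly 1), or the same peak straddled by two adjacent bands. A markedly
lower threshold is not usable here: in piecewise-constant scenes all
informative band images share one dominant canopy-versus-background
contrast axis, so even spectrally distant, genuinely complementary bands
correlate at 0.7–0.95, and a 0.95 threshold would collapse distinct
features unpredictably. The surviving picks are truncated to the `k`
highest ratios (ties to the lower wavelength); if fewer than `k` survive,
the result is returned short with a warning flag rather than padded.

## Enhancement, fusion, PC1

The 3×3 median filter uses edge-reflection padding so no artificial dark
rim biases the threshold search. Fusion is the plain elementwise sum of the
three characteristic-wavelength images — summed reflectances, no rescaling
— which pulls the (dark, mutually similar) background classes into one gray
population while stretching leaf contrast; a normalised mean is available
behind a flag. The comparison baseline projects each pixel's 3-vector onto
the leading eigenvector of the across-image covariance (PC1), sign-fixed so
the projection correlates positively with the mean image (bright-canopy
convention). Order of operations follows the method being reproduced:
band images are median-filtered *before* summation, whereas PCA runs on the
unfiltered band images and its PC1 image is median-filtered afterwards.

## Threshold segmentation

Gray images are quantized linearly over their own min–max range into
`L = 256` levels; the same quantization function is reused when thresholds
are applied, so level assignment is always consistent (and is verified by
re-counting the histogram). With class probabilities `P_i`, class mean
levels `μ_i` and global mean `μ₀ = Σ i·p_i` over the full range, the
between-class variance is `σ² = Σ P_i (μ_i − μ₀)²`, summed over classes
with positive mass; empty classes contribute zero rather than being
disallowed, keeping the search space rectangular. Two conventions deserve
note: the global mean is always the full-range mean (not a partial sum),
and the squared deviation is used in the multi-class criterion exactly as
in the two-class one — both follow the verbal definition of the criterion.
The search is exhaustive: a vectorized scan for `k = 1`, a prefix-sum
accelerated scan over all `t₁ < t₂` pairs for `k = 2` (the intended use),
and combination enumeration beyond. Ties are broken to the
lexicographically smallest threshold vector for determinism. Degenerate
histograms (fewer occupied levels than classes) raise an error — the image
is not segmentable at that `k`.

Post-processing: pixel labels count the thresholds strictly below the
pixel's level (labels monotone in gray value); the named leaf classes are
merged into a binary canopy mask; morphological opening with a square
element of side `2r + 1` (default `r = 1`) removes speckle; the mask can be
applied to the cube, zeroing background pixels and updating the validity
mask.

## Evaluation metrics

`AOM = |S1∩S2| / |S1∪S2|` and `ME = (|S1∪S2| − |S1∩S2|) / |S1|`, with `S1`
the algorithm mask and `S2` the manual mask. ME's denominator follows the
formula as conventionally printed (the algorithm region); because the
verbal description of the numerator — misclassified pixels over manually
segmented pixels — suggests `|S2|`, a `denominator="manual"` option exposes
that reading. ME is therefore not symmetric and can exceed 1 when `S2` is
much larger than `S1`; AOM is symmetric and bounded in [0, 1]. Two empty
masks are identical segmentations: AOM 1, ME 0. An empty algorithm mask
makes ME undefined and raises. Batch summaries report max, min, mean, and
both the sample standard deviation and the sample variance under their own
names, since dispersion columns in published tables are sometimes labelled
ambiguously; neither is asserted against external values.

## Synthetic scenes: what they emulate, and what not

The generator emulates the *structure* of an overhead potted-crop capture:
a dark stage, a pot annulus with soil inside, a canopy of overlapping
ellipses centred in frame, and shadowed-leaf patches covering ~25% of the
canopy; spectrally, a vegetation-like leaf curve (green peak at 553 nm, red
absorption minimum near 670 nm, logistic red edge, NIR maximum near 772 nm),
a shadowed-leaf curve that is a fixed scale factor (default 0.5) of the
leaf curve, and dark background curves. Radiometrically it applies one
smooth multiplicative illumination field across all bands (default
amplitude ±20%), i.i.d. Gaussian noise (default sd 0.01 reflectance) and
0.2% salt-and-pepper impulses — the artefact class the median filter
exists to remove. A consistent raw/white/dark trio (flat references at
0.02/0.97) is emitted so the calibration path can be exercised end-to-end.

Background curves are shaped to *plant* recoverable selection targets:
soil's monotone ramp steepens sharply near 750 nm (leaf/soil ratio peak
near 733 nm), the pot has a sharp reflectance step at 718 nm (leaf/pot peak
near 708 nm), the stage is flat (leaf/stage peak at the leaf NIR maximum
near 772 nm), and all ratio curves share a secondary green peak. The
planted-peak wavelengths are computed from the analytic curves on the
actual grid and recorded in the library, making wavelength selection a
parameter-recovery experiment. The three backgrounds remain close to each
other in reflectance at the planted peaks, so their fused gray levels
cluster well below the shadowed-leaf level — the premise of the fusion
stage.

Scene defaults (128×128×176, noise sd 0.01, illumination amplitude 0.2,
shadow fraction 0.25, impulse fraction 0.002) are fixed study conditions
chosen so the three gray populations (background / shadowed leaf / normal
leaf) are separable but not trivially so; the batch experiments in the test
suite run 12–20 such scenes, which keeps the full suite well under a minute
per experiment on one core.

Deliberate non-realism: no radiative transfer, no leaf BRDF or specular
highlights, no continuous within-canopy shading (shadow is a single scale
factor), no band-dependent illumination, no real lettuce morphology. Two
consequences matter for interpreting green tests. First, because classes
are piecewise constant, segmentation of the fused image is nearly perfect
at the default noise level — the batch experiment demonstrates that the
pipeline's stages compose correctly, not that the method reaches any
particular accuracy on real canopies. Second, the canopy ground truth is
regularized at generation time to a joint fixed point of the 3×3 binary
median and 3×3 opening, so that in the zero-noise, flat-illumination limit
the pipeline must reproduce it *exactly* (AOM = 1, ME = 0): without that
regularization the median filter legitimately flips convex-corner boundary
pixels and exactness is unattainable for any shape with sub-template
boundary structure. Real manual masks have no such property; on real data
boundary-pixel disagreement at this scale is expected.

## Numerical conventions and degenerate inputs

- Band lookup is nearest-neighbour with a tolerance of one nominal band
  spacing; no spectral interpolation.
- Constant images quantize to a single level (histograms remain valid);
  constant image stacks make PC1 undefined and raise.
- Zero-variance band images count as perfectly correlated during pruning
  (they carry no distinguishing information).
- Monotone ratio curves have no interior maximum; the selector falls back
  to the global maximum and flags the pick.
- All randomness flows through `numpy.random.default_rng(seed)`; layouts
  and renders are bit-reproducible for a fixed seed.

## Known limitations

- The exhaustive threshold search is O(L²) for `k = 2`; for `k ≥ 3` the
  combination enumeration is exponential in `k` and intended only for tiny
  `L`.
- Correlation pruning at its default effectively removes only duplicate
  bands; scenes with textured classes (where informative bands decorrelate)
  may warrant a lower `r_threshold`.
- The leaf-class indices after multi-thresholding are scene-dependent on
  real data; the CLI therefore requires an explicit `--leaf-labels` choice
  rather than guessing.
- ENVI support covers the dialect written by this package (plus BIL/BIP and
  uint16 on read); exotic headers (offsets, BILs with band-dependent gain,
  big-endian) are out of scope.
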