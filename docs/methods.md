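# Methods

This note documents the model implemented by `vesselseg`, its parameter
defaults, the synthetic data used to validate it, and the numerical choices
made where the design was genuinely open.

## The filtering model

A vessel is an elongated, locally straight, dark structure on a brighter
retinal background. After green-channel extraction, CLAHE and FOV masking,
the pipeline inverts the image so vessels are bright, then applies two
bar-selective COSFIRE filters.

**DoG sub-filters.** The center-on difference of Gaussians uses inner std
0.5σ and outer std σ; the kernel is sampled on a (2⌈3σ⌉+1)² grid and
DC-corrected (discrete mean subtracted) so constant regions yield exactly
zero response, as the continuous band-pass does. Responses are half-wave
rectified; convolution uses reflective boundary padding.

**Configuration.** The filter structure is read off a synthetic prototype:
a vertical bar of width 3 px (full height for the vessel-selective
*symmetric* filter, lower half only for the ending-selective *asymmetric*
one). The prototype's DoG response is sampled on circles of radius ρ at 1°
steps with bilinear interpolation; angular local maxima above 0.2× the
circle maximum become tuples (σ, ρ, φ), maxima closer than 10° are merged
to the larger (ties to the smaller angle). A width-3 bar keeps the DoG
ridge on the bar axis for both filter scales, so the symmetric filter
configures paired tuples at φ = 90°/270° and the asymmetric filter
single-sided tuples at 270° — wider prototypes (≳ 2σ) split the ridge in
two and are not used as defaults.

**Blur and shift.** Each sub-response is blurred by a Gaussian-weighted
maximum (unit-peak weights) over a ±3σ′ window with σ′ = σ₀′ + αρ, then
translated so the sampled point lands on the filter center. Two
implementation details matter:

- Shifts are rounded to whole pixels (the convention of the reference
  B-COSFIRE implementation); with integer shifts the optimized
  blur-then-shift factorization is exactly equal to the literal per-pixel
  definition, which the test suite verifies to < 1e−9 against a brute-force
  re-derivation.
- The blur is evaluated on a domain zero-padded by the tuple radius before
  shifting: a pixel whose shifted read falls just outside the frame still
  collects response from in-image pixels inside its tolerance window.
  (Reads genuinely beyond the window see zero.)
- Because the rectified response is non-negative and the Gaussian weight
  factorizes, the 2-D weighted maximum separates into two 1-D passes; one
  DoG convolution per distinct σ and one blur per distinct (σ, ρ) are
  computed per image and shared across all orientations.

**Combination.** The weighted geometric mean with ωᵢ = exp(−ρᵢ²/2σ̂²),
σ̂ = max(ρ)/3 by default, normalized by 1/Σωᵢ, is an AND-type operator:
a zero anywhere in the tuple set zeroes the output. An optional fraction
`t` suppresses responses below t·max per orientation (default 0; the final
manual threshold does the selection). Rotation tolerance is the pointwise
maximum over orientations spaced π/n; the asymmetric filter sweeps the full
circle (2n orientations) because a vessel ending has a direction, not just
an orientation. The two rotation-tolerant maps are min-max normalized over
the FOV and summed; summation (rather than max) lets the ending detector
reinforce terminal segments without suppressing the interior detector.

## Parameter defaults

| key | default | meaning |
|---|---|---|
| filter.symmetric.sigma / rho_max / rho_step | 2.4 / 8 / 2 px | vessel filter scale and support |
| filter.asymmetric.sigma / rho_max / rho_step | 1.8 / 22 / 2 px | ending filter scale and support |
| filter.sigma0_prime, filter.alpha | 3 px, 0.7 | blur rule σ′ = σ₀′ + αρ |
| filter.n_orientations | 12 | 15° orientation spacing |
| filter.weight_sigma | auto = max(ρ)/3 | tuple weighting σ̂ |
| filter.t | 0 | response-stage threshold fraction |
| clahe.tiles / clip_limit / n_bins | 8×8 / 0.01 / 256 | standard retinal preprocessing values |
| segment.se_size | 11 px (7 in the synthetic preset) | top-hat square element |
| segment.threshold | preset (synthetic: 0.22) | manual threshold on the FOV-normalized response |
| postprocess.min_area | 20 px | inclusive small-component cutoff |
| fov.method / erode_px | otsu / 0 | FOV mask source and rim erosion |

The filter scales and blur constants are the established B-COSFIRE values
for DRIVE-resolution imagery (vessels 1–8 px wide) and are exposed in the
config rather than re-derived. The manual threshold is, by design of the
method, a per-dataset choice; the shipped preset values were selected on
the synthetic fixtures and are starting points, not database-calibrated
values. The top-hat element bounds the width of structures that survive
enhancement: 11 px exceeds the maximum vessel diameter at DRIVE scale,
while the synthetic preset uses 7 px, which measured best on the denser
desk-scale geometry.

## Synthetic data: what it emulates and what it does not

`generate_synthetic_fundus` draws, per seed: a bright disc (radius 85 px in
a 200×200 frame) on a dark border; a smooth background texture (Gaussian
noise low-passed at σ = 8 px, ±0.03 amplitude) over level 0.78; three
vessels as cubic-spline curves crossing the disc with per-vessel width
uniform in [1, 8] px, drawn as intensity dips of Gaussian cross-section
(std = width/4) and contrast 0.45, darkest in the green channel; and
i.i.d. Gaussian pixel noise of std 0.02 per channel. "Width" means the
full visible diameter: the gold mask marks pixels within width/2 (±2 std)
of the centerline, so the labeled vessel coincides with the visible one.
Three vessels put the vessel-pixel fraction of the FOV near 9–10%
(band 0.06–0.15 over seeds), matching the density of real fundus
databases (~9% in DRIVE).

The generator reproduces the features the pipeline actually exploits —
FOV geometry, green-channel contrast, curvilinearity, width variation,
crossings, noise — but not pathology (exudates, hemorrhages), the optic
disc, central vessel reflexes, or inter-image illumination drift. Passing
the synthetic recovery tests therefore demonstrates that the implementation
realizes the method correctly at realistic geometry and noise; it does not
certify clinical performance, which must be measured on real databases
with per-dataset thresholds.

On this generator the pipeline averages (seeds 1–10) sensitivity 0.750,
specificity 0.960, accuracy 0.938, MCC 0.674 inside the FOV — the
`scripts/acceptance.py` output. Residual errors are structural: the
response ridge across a vessel has a near-constant width set by the blur
floor σ₀′ and the top-hat element, so detections are slightly fat on 1–2 px
vessels and slightly thin on 8 px ones.

## Numerical and design choices

- **DoG sign.** The printed subtraction order of the two Gaussians would
  give a negative center; the filter is implemented center-on (narrow minus
  wide), matching the verbal "positive central region, negative surround".
  `dog.sign=as_printed` preserves the literal form for audit.
- **Blur std.** The blur uses σ′ from the tolerance rule, not the tuple's
  σᵢ — otherwise the rule would be dead code.
- **Recovery rule.** A candidate region is re-admitted only if the
  8-connected component count strictly decreases. Accepting equal-count
  candidates would admit the 1-px dilation ring around every vessel (the
  ring touches its vessel, so the count never changes) and systematically
  fatten the output; only a strict decrease evidences a reconnected
  bifurcation or crossing.
- **Stabilization.** Thin → 3×3 dilate → fill isolated single-pixel holes,
  iterated to a fixpoint with a cap of 10 iterations (the iteration can
  2-cycle on some geometries; the last iterate is used with a warning).
- **Small components.** The ≤ 20 px rule is inclusive: a 20-px component is
  removed.
- **Ties and determinism.** Configuration maxima closer than 10° merge to
  the larger value, ties to the smaller angle; recovery candidates are
  processed in raster order of first pixels; there is no randomness
  anywhere in the inference path, so identical inputs give bit-identical
  outputs.
- **Degenerate inputs.** A constant luminosity plane raises a mask error;
  a structureless prototype raises a configuration error; a constant
  response inside the FOV binarizes to an empty map with a warning; metric
  denominators of zero raise errors naming the metric.
- **Evaluation.** Metrics are restricted to FOV pixels (whole-frame
  evaluation is available via `metrics.fov_only=false`); dataset aggregates
  are unweighted means of per-image metrics, not pooled counts.

## Limitations

- Single-scale filters: very wide vessels (> ~10 px) respond weakly at the
  default σ; no multi-scale bank is provided.
- The manual threshold is global per dataset; images with atypical dynamic
  range shift along the Se/Sp trade-off.
- The post-processing recovery assumes breaks are 1–2 px; larger gaps are
  not re-bridged.
- Timing claims of the underlying method are hardware-specific and are not
  reproduced; this implementation targets correctness and testability.
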