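# Methods

This note records the models, numerical choices, and limitations behind
`wmhkit`. It documents what the code computes; every empirical number quoted
here is produced by the test suite or `scripts/acceptance.py`.

## The segmentation model

White-matter hyperintensities (WMH) appear as bright regions relative to
surrounding brain tissue on T2-weighted/FLAIR MRI. The classical detection
chain implemented here treats segmentation as an intensity-statistics
problem:

1. **Class statistics.** For each tissue class C (brain B, vessel V,
   definite WMH T, suspected WMH), the sample mean μ_C, *population*
   standard deviation σ_C (divisor N_C), the class maximum, and an intensity
   histogram realizing the class PDF. The PDF is formally a Dirac-delta
   mixture over observed intensities; it is discretized as a normalized
   histogram with a configurable bin count (default 256) because the delta
   form is not directly computable. The modal intensity N_PDF of a new image
   is the center of the maximal histogram bin, ties broken toward the
   lowest-intensity bin; it is therefore accurate only to half a bin width.
2. **Contrast stretch.** Reference means are shifted by N_PDF − N_max^B to
   align the new image with the calibration scale, giving the window
   [μ_T′ − 3σ_T, μ_V′ + 3σ_V]. Intensities inside the window map affinely
   onto [1, 255]; everything else maps to 0. The printed formula
   (×254 + 1) yields [1, 255] although the surrounding prose says
   "0 to 255"; the formula is implemented. Note the window presumes vessels
   are the *brightest* class (they form the upper anchor) and lesions the
   lower anchor; the phantom's default class means respect this ordering.
3. **Calibration source.** The reference class statistics (μ_T, σ_T, μ_V,
   σ_V, N_max^B) come from a labeled calibration volume supplied once. The
   pipeline generates this calibration phantom with noise level
   max(noise_sd, 1): a strictly noise-free calibration would make
   σ_T = σ_V = 0, collapsing the 3σ margins of the stretch window to zero,
   where the half-bin inaccuracy of N_PDF can push entire classes out of the
   window. Calibrating on a realistic noisy volume keeps the margins
   physical.
4. **Denoising.** A 3³ median filter (the smallest edge-preserving choice)
   with an optional separable discrete Gaussian (default σ = 0.5 voxels,
   truncated at 3σ, kernel normalized to unit sum); both replicate edges.
   The median filter erodes the surface shell of small blobs: on digital
   spheres it removes enough boundary voxels that near-perfect recovery of
   lesions requires radii of roughly 5 voxels and above. This is why the
   recovery tests use large confluent lesions — small punctate lesions are
   attenuated by the very filter the chain prescribes.
5. **Normalization.** Z-score over the brain mask followed by min-max
   scaling of the whole volume to [0, 1]. Because a global min-max follows,
   the affine z-score cancels in the output; the z-score statistics still
   matter to any consumer of μ_B, σ_B themselves. The optional 2nd–95th
   percentile clip restricts which masked voxels contribute to μ_B and σ_B.
6. **Candidate detection.** Adaptive threshold T_WMH = μ_B + k·σ_B with
   μ_B, σ_B recomputed on the image at hand over the brain mask (the symbol
   is reused across stages without qualification; recomputation is the
   consistent reading). Candidates are opened with a ball structuring
   element (radius in voxels) to remove small noise clusters and thin
   vessels; a custom element (e.g. a 3³ box) may be passed where exact shape
   preservation matters, since a ball/cross element legitimately shaves cube
   corners.

Default search ranges: k ∈ [0.5, 4.0], opening radius ∈ {1, 2} — spanning
punctate-to-confluent regimes on phantoms.

## The phantom

The phantom is an ellipsoidal "brain" (80 % of each axis) of class B
containing spherical/blobby definite-WMH lesions with a 1-voxel suspected
rim of intermediate intensity, plus thin (1-voxel) random-walk vessels.
Default class means (background 0, brain 100, suspected 120, definite 150,
vessel 170) make lesions hyperintense to brain and vessels the brightest
class, matching the assumptions of the contrast-stretch window; the
hyperintensity ordering is asserted at configuration time.

Voxel intensity is `mean_c · bias + noise_sd · sd_c · N(0,1)`: `noise_sd`
is a global multiplier on per-class standard deviations, so `noise_sd=0`
renders exact class means (useful for analytic tests) while `noise_sd=1`
reproduces the configured spreads. The bias field is multiplicative,
1 + amplitude·b with b a smooth unit-peak combination of three random
low-order cosine modes (default amplitude 0.05). Noise is Gaussian by
default with a Rician option; the Gaussian suffices for pipeline testing.
Lesion centers are rejection-sampled inside an eroded brain mask so lesions
and rims never touch the brain boundary, keeping morphological tests
unambiguous. A single seeded generator drives every stochastic step.

What the phantom does *not* emulate: anatomy (no gyrification, atlases, or
tissue interfaces), partial-volume effects, scanner-specific noise
correlation, or multi-sequence contrast. Tests passing on phantoms therefore
demonstrate the correctness of the computational chain, not clinical
segmentation accuracy on real FLAIR data.

## Fusion and super-resolution

Fusion operates on non-overlapping 8×8 blocks in the orthonormal 2-D DCT-II
domain (`scipy.fft.dctn(norm="ortho")`); the orthonormal pair round-trips
exactly and satisfies Parseval, and block choice depends only on *relative*
AC energies, so the normalization convention does not affect the winner.
Block quality is H/(L + ε) with L the summed squared coefficients at JPEG
zigzag indices 1–31 and H at 32–63, the DC coefficient zeroed inside the
quality computation only (the fused block keeps the winner's full
coefficients, DC included — discarding DC would destroy luminance).
ε = 1e-12; BQ is capped at 1e12; ties select the first image. The boolean
decision map is smoothed by a 3×3 majority vote with replicated edges
(consistency verification); this deliberately flips isolated dissenters, so
content blocks at the edge of a textured region can be overridden by their
neighbourhood — the per-block quality ordering itself is exact, as the
fusion tests verify against a from-the-definition DCT and a literal zigzag
table. Images not divisible by 8 are replicate-padded and cropped after
reconstruction. 10×10 patches route by variance (strictly greater than the
threshold → SR path; flat patches → bicubic upsampling); Sobel enhancement
is used for selection only, never for constructing outputs.

The SR mapping is the standard three-block form: ReLU f₁×f₁ representation
filters, ReLU 1×1 non-linear mapping, linear f₃×f₃ reconstruction, all
same-padded so output shape equals input shape. Its loss is the mean over
training pairs of the sum of squared residuals. Training is by particle
swarm over the flattened filter banks and is deliberately restricted to ≤ 50
free parameters: swarm search does not scale to real filter banks, and this
trainer exists to exercise the optimizer/loss plumbing at desk scale, not to
learn a deployable SR model.

## Particle swarm optimizer

Constant-inertia PSO: v′ = θv + αε₁(g* − x) + βε₂(x* − x) with ε₁, ε₂
uniform in [0, 1] drawn per dimension per update, then x′ = x + v′Δt.
Defaults α = β = 2.0, θ = 0.7, Δt = 1. Velocity components clamp to
[−v_max, v_max]: a non-negative velocity range cannot explore in both
directions, so the symmetric clamp is used. Positions reflect at finite
bounds (fold-and-mirror), which keeps particles feasible without zeroing
velocity. Particles initialize uniformly over the bounds with v(0) = 0.
Iteration stops at max_iter or when relative global-best improvement stays
below `tol` for 15 consecutive iterations. Everything is reproducible from
the config seed. A non-finite objective value aborts with the offending
position attached.

The segmentation adapter tunes (k, opening radius) by minimizing the Dice
loss of threshold + opening against a reference mask; the radius coordinate
is continuous in the swarm and rounded to the nearest integer within its
bounds at evaluation. The Dice-loss weight map is optional and defaults to
uniform weights when no definite/suspected decomposition of the reference
is supplied. A search space degenerate to a single point is evaluated
directly and returned with its loss.

## Metrics

- **Dice loss** 1 − (1/C) Σ_c 2Σpg/(Σp² + Σg²); the weighted variant
  multiplies per-voxel weights inside both numerator and denominator (the
  printed placement of the weight is ambiguous; per-voxel placement is the
  reading that actually changes voxel emphasis). A class empty in both
  prediction and truth contributes zero loss.
- **Weight map**: 2 on definite-WMH voxels; 1 + f(dis) on suspected voxels
  with f = 1 − dis/dis_max, dis the Euclidean distance in mm to the nearest
  definite-component *centroid* (26-connected components) and dis_max the
  maximum such distance over suspected voxels; 1 elsewhere, including
  background. If the only suspected voxel coincides with a centroid
  (dis_max = 0), f := 1, honouring f(0) = 1 without a 0/0.
- **DSC** 2|G∩P|/(|G|+|P|); both-empty is defined as 1 (a vacuous
  agreement should not crash batch evaluation). DSC equals the F1 computed
  from the same voxel counts — tested as a property on random mask pairs.
- **HD95**: boundary voxels are the mask minus its erosion; directed
  distances via a KD-tree in physical mm; the 95th percentile is the
  nearest-rank K = ⌈0.95·N⌉ order statistic; symmetric max of the two
  directions. Undefined (flagged) when either mask is empty.
- **Precision/recall/F1**: voxel-level; zero-denominator cases are flagged
  undefined and reported as 0. Lesion-level recall counts a 26-connected
  truth component as detected if the prediction overlaps it by ≥ 1 voxel.
- **AVD** |A − B|/B × 100 %; an error for zero truth volume.
- **PSNR/MSE** with k_max = 255 by default; MSE 0 reports PSNR = +inf.
- **SSIM** over uniform sliding windows (default 8), restricted to fully
  supported windows and averaged; c₁ = (0.01·L)², c₂ = (0.03·L)² in the
  conventional k₁/k₂ parameterization with L the dynamic range. Negative
  values are possible for anticorrelated windows and are reported as
  computed. Cross-checked against scikit-image's implementation within 0.02
  on noisy pairs (conventions differ slightly in variance estimators).
- **UQI** (global mode): correlation × mean-similarity × contrast-similarity
  using population statistics; exactly 1 on identical non-constant images
  and exactly −1 against the pointwise reflection 2·mean − image. Undefined
  (flagged) for constant images. A windowed mode averages the product over
  sliding windows, skipping zero-variance windows.

## Problem sizes and defaults

Phantoms default to 64×64×48 voxels at 1 mm isotropic spacing with 4
punctate + 2 confluent lesions (radius 1.5–4 mm), 3 vessels, noise_sd 1,
bias 0.05. Recovery tests use 3 confluent lesions of radius 5.5–7 mm on a
noise-free phantom (the separable regime) with a 12-particle, 30-iteration
swarm; the end-to-end pipeline demo uses 48×48×32 with a 6-particle,
8-iteration swarm. These sizes complete in seconds on one CPU while leaving
every code path exercised.

## Known limitations

- The chain is a classical stand-in for the deep components of a full
  system: the feature-extractor stage is a pluggable callable and no
  pretrained backbone ships with the package.
- The median filter's erosion of small structures bounds achievable Dice on
  punctate lesions; real pipelines mitigate this with smaller kernels or
  edge-aware filters.
- The contrast-stretch window assumes the vessel class tops the intensity
  scale; sequences where that fails need reordered anchors.
- HD95's nearest-rank percentile on very small boundaries (< 20 points)
  degenerates to the maximum distance.
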