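# Methods

This note documents the models and numerical choices behind `nssfuse`, the
defaults and why they were chosen, what the synthetic fixtures do and do not
emulate, and the known limitations.

## The nonsubsampled contourlet transform

The NSCT cascades two nonsubsampled stages. The multi-scale stage (a
nonsubsampled pyramid) applies a two-channel filter bank whose kernels are
a-trous-upsampled by `2^j I` at scale `j`; the directional stage splits each
band-pass scale with a tree of two-channel fan banks upsampled by quincunx,
dilation and shear matrices. Because no stage resamples the signal, every
band keeps the source size and the transform commutes exactly with circular
shifts. Perfect reconstruction needs only the Bezout identity
`H0 G0 + H1 G1 = 1` per stage — an identity preserved under *any* integer
upsampling matrix, which is what makes the whole tree invertible regardless
of how the directional wedges are carved.

**Filter construction.** Both families are built with the McClellan
transform `cos ω → (cos ω₁ + cos ω₂)/2`, which maps a 1-D halfband pair to a
2-D diamond-complementary pair and keeps polynomial identities exact:

* `"9-7"` (pyramid, default): the CDF 9/7 biorthogonal pair (from
  PyWavelets' `bior4.4`, rescaled to DC gain 1) is lifted to 2-D; the
  high-pass kernels are the (π, π)-modulated low-pass kernels of the other
  side. Since the 1-D product `P(ω) = H0 G0` is an exact halfband
  (`P + P(ω+π) = 1` after rescaling), the 2-D Bezout residual is at machine
  precision (~1e-12 on a 64×64 grid). A separable 2-D quadrature pair cannot
  satisfy the 2-D identity, which is why the lift is non-separable.
* `"maxflat"` (pyramid, secondary): same construction from the 5/3
  (linear-spline) pair.
* `"pkva"` (fan, default): the published PKVA-12 ladder interpolation
  coefficients define the halfband `1/2 + Σ v_k T_{2k−1}(cos ω)`; the
  McClellan diamond is row-modulated into a fan prototype `F` with
  `F + (1−F) = 1` and `F(0,0) = 1/2` exactly. The quad
  `(f, δ−f, f, δ+f)` then satisfies `F² + (1−F)(1+F) = 1` identically.
* `"dmaxflat"` (fan, secondary): same pipeline from the 6-point
  maximally flat interpolating halfband.

**Directional tree.** Stages 1–2 use the fan pair directly and upsampled by
the quincunx matrix `D = [[1,−1],[1,1]]` (|det| = 2), giving four quadrant
wedges. Stage 3 uses `diag(1,2)` / `diag(2,1)`; deeper stages solve for an
integer (usually unimodular shear) matrix whose two fan boundaries are the
midpoint line and one edge line of the parent wedge, subdividing slopes
uniformly — the standard directional-filter-bank partition. Channel order
within a level follows the tree, not angle. Measured dominant orientations
of the 16-channel bank tile 0–180° approximately uniformly.

**Boundaries.** The transform itself is periodic (exact reconstruction and
shift invariance). The pipeline's `boundary="symmetric"` default pads the
sources by reflection (`boundary_pad = 32` px) before decomposition and
crops after reconstruction, which avoids wrap-around artifacts on natural
images while keeping the transform exact; `"periodic"` skips the padding.

## Low-pass fusion

Patches are 8×8 (stride 1), vectorised column-major and mean-removed; the
patch means are re-attached after coding. Dictionary learning pools the
patches of both low-pass bands, clusters them with k-means (k-means++
initialisation, fixed seed, k = 8 by default), and keeps per cluster the
smallest `p` leading eigenvectors of the cluster covariance whose
eigenvalue mass fraction reaches δ = 0.95. Reading the selection rule as
*retained* mass is the conventional interpretation of a δ-energy criterion
and matches the stated intent of keeping the minimum number of atoms that
still represent the cluster. Eigenvectors are sign-fixed (first nonzero
component positive) and ties broken by eigenvalue order, so the dictionary
is byte-reproducible for a fixed seed. Clustering runs on a seeded random
subsample of at most `max_train_patches = 20 000` patches — at stride 1 a
256×256 pair yields ~200 k patches, and k-means gains nothing from the
duplicates — while coding always visits every patch.

SOMP codes each co-located patch pair over a *shared* support: the greedy
step picks the atom maximising `|φᵀr_A| + |φᵀr_B|`, coefficients are
per-signal least squares on the support (batched normal equations with a
1e-12 ridge; residuals are evaluated explicitly to avoid cancellation), and
coding stops when both residual norms are ≤ ε or `max_atoms = 16` is
reached. The default ε = 0.01·√n = 0.08 for n = 64-pixel patches bounds the
representation error on [0, 1] data while keeping codes sparse. The Max-L1
rule selects a whole input code, never a blend; ties select source B (the
literal "otherwise" branch), which matters only for exactly tied codes —
`fuse(I, I)` exercises it everywhere and is covered by tests. Overlap-add
divides each pixel by its coverage count; pixels a stride > 1 grid never
covers fall back to the two-source mean.

## High-pass fusion

The modified Laplacian uses second differences with spacing `step = 1` and
symmetric extension; SML sums the *squared* ML over a (2P+1)×(2Q+1) window
with P = Q = 1 (the standard 3×3 choice; the window size is exposed in the
config, as is a `sml_squared` flag for the unsquared variant found in parts
of the focus-measure literature). Fusion copies the coefficient with the
larger SML; the tie (`≥`) goes to source A. The directional bands produced
by the decomposition are used directly — they already are the per-level,
per-direction coefficients, so no second directional decomposition is
applied. Selection is verified per-pixel against an independently coded
brute-force evaluation on random bands.

## Colour images

The underlying method is defined on one channel, so colour handling is a
documented convention, not part of the model: `luma` mode (default)
converts to YCbCr, fuses Y, and copies each pixel's chroma from the source
that won the majority of the low-pass patches covering it; `per_channel`
fuses R, G, B independently. Replicated grayscale inputs reduce to the
grayscale result in both modes.

## Synthetic fixtures

`make_multifocus_pair` renders a textured scene (band-limited filtered
noise over a checkerboard, bars, or blob phantom), blurs it with a Gaussian
(σ = 3 by default) inside a half-plane or disk for one source and outside
it for the other, and returns the sharp scene as ground truth. Band-limited
texture is used because focus measures respond strongly to it.
`make_multimodal_pair` renders one blob phantom under two disjoint
intensity mappings so each structure is visible in exactly one source.
Everything is bit-reproducible from the spec and seed.

What these fixtures do *not* emulate: sensor noise statistics, modality-
specific physics (CT beam hardening, MR bias fields), mis-registration, or
natural-image statistics. Passing the fixture-based tests demonstrates the
algorithmic contracts (invertibility, selection rules, recovery when the
degradation model matches the fixture), not clinical-grade performance.

## Metrics

`mutual_information` returns `MI(A;F) + MI(B;F)` from 256-bin joint
histograms over [0, 1], in bits, with no normalisation (the raw summed
form). `q_abf` is the gradient-preservation index with the published
sigmoid constants (Γ_g = 0.9994, κ_g = −15, σ_g = 0.5; Γ_α = 0.9879,
κ_α = −22, σ_α = 0.8), Sobel gradients, and the convention that entirely
flat sources score 0. `q_y` switches between a variance-weighted mean of
the local SSIMs (where the sources agree, SSIM(A,B) ≥ 0.75) and their
maximum (where they disagree), on 7×7 uniform windows. Tsallis-entropy,
phase-congruency, perceptual-contrast and visual-information-fidelity
metrics are reserved fields in the report schema but not implemented.

## Problem sizes and determinism

The test-suite and acceptance-script problem sizes — 64×64 for transform
properties (50 random images), 128×128 for identity-fusion PSNR, one
256×256 multi-focus scenario, 100 trials for the SOMP and SML oracles —
were chosen so the full verification run completes in about a minute on a
single core while exercising every configuration the defaults use. All
randomness flows through explicit seeds; fixed seeds give byte-identical
dictionaries and fused images.

## Known limitations

* Fusion of exactly two sources (the framework extends to more, the API
  does not); registration is the caller's responsibility.
* Directional wedge shapes for 8+ directions are approximate near the
  ±45° corners, a known property of shear-based partitions; reconstruction
  is exact regardless.
* The per-pair dictionary is retrained for every call unless a saved
  dictionary is supplied (`--dictionary`), which trades reproducibility
  for speed when batch-processing similar scenes.
* Subsampled contourlets, wavelet baselines, K-SVD/DCT dictionaries and
  GPU execution are out of scope.
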