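# Methods

`nsctfuse` fuses two co-registered 2-D medical images by transforming both
into a shift-invariant multiscale, multidirectional subband representation
(the nonsubsampled contourlet transform, NSCT), choosing every subband
coefficient from whichever source a pulse-coupled neural network (PCNN)
judges more salient, and inverting the transform. This note records the
model, the numerical choices, and what the synthetic test bed does and does
not establish.

## The transform

**Structure.** The NSCT cascades two undecimated two-channel filter banks.
The pyramid stage (NSPFB) splits the running lowpass into lowpass +
bandpass at each scale `j`, with the analysis/synthesis kernels à trous
upsampled by `2^j·I` (zeros inserted between taps instead of decimating the
signal). The directional stage (NSDFB) splits each scale's bandpass image
through a binary tree of fan filters into `2^d` wedge-shaped directional
subbands. Nothing is ever downsampled, so every band keeps the source
shape and the whole transform commutes with translations.

**Filters.** Exact invertibility of an undecimated two-channel bank is the
Bezout identity `h0*g0 + h1*g1 = δ`, which survives à trous upsampling of
all four kernels by any nonsingular integer matrix. The shipped pyramid
bank (registered under the conventional name `pyrexc`) is derived from the
1-D maxflat halfband filter `[-1, 0, 9, 16, 9, 0, -1]/32` via the McClellan
transform with the diamond kernel, giving the zero-phase 7×7 lowpass
`h0 = δ/2 + 3t/4 − t³/4` (DC gain 1), with `h1 = δ − h0*h0` (DC gain 0),
`g0 = h0`, `g1 = δ`. All taps are dyadic rationals, so the identity holds
*exactly* in float64, and it is re-checked at construction time — the
identity, not any particular published tap table, is the correctness
contract. The fan bank (`vk`) is the same construction modulated by
`(−1)^n₁`, which moves the diamond passband onto the complementary fan
pair; modulation commutes with convolution, so the identity is inherited.

**Directional tree matrices.** Depth 1 uses the fan pair directly; depth 2
upsamples it by the quincunx matrix `Q = [[1,1],[1,−1]]` (fan → quadrant
supports); depth `l ≥ 3`, channel `c`, uses `2^(l−3)·Q·R[c mod 4]` with the
four unimodular shears `R`. Perfect reconstruction and shift invariance
hold for *any* nonsingular integer matrices — the specific choice only
shapes the wedge passbands — and a test verifies the two depth-1 channels
respond very differently to an oriented grating.

**Boundary handling.** Default is `periodic` (circular convolution via
FFT): reconstruction, linearity and shift invariance are then exact to
machine precision (~1e-15 observed). A `symmetric` (half-sample mirror)
mode avoids wrap-around artifacts on real images, but mirror extension
commutes with the filter tree only for axis-symmetric kernels; the
quincunx-upsampled fan kernels are not axis-symmetric, so symmetric-mode
reconstruction is exact in the interior (< 1e-6 beyond a 16-pixel margin
at 64×64) while border pixels deviate (~1e-1). Periodic is therefore the
default, and the mode every exactness guarantee refers to.

## The PCNN and the fusion rule

Each subband pixel drives one neuron. Per iteration, in order: feeding
`F = S` (stimulus); linking `L(n) = e^{−α_l}L(n−1) + v_l Σ w·Y(n−1)`;
modulation `U = F(1 + βL)`; firing `Y = [U > H(n−1)]` (strict — ties do
not fire); threshold `H(n) = e^{−α_h}H(n−1) + v_h·Y(n)`. All state starts
at zero, so any neuron with `U > 0` fires at step 1. The accumulated count
`T = Σ Y` over `N` iterations is the salience score.

Parameter defaults (`link_arrange = 3`, `β = 3`, `α_l = 1`, `v_l = 1.8`,
`α_h = 0.2`, `v_h = 20`, `N = 100`) are the reference experimental setting.
Choices made where the model is underdetermined:

- **Feeding channel**: the pure-stimulus simplification `F = S` is the
  default (the reference setting lists no feeding constants); the full
  leaky recurrence `F(n) = e^{−α_f}F(n−1) + v_f Σ m·Y(n−1) + S` is
  available by setting `alpha_f`/`v_f`.
- **Linking decay** acts on the linking state (the printed recurrence that
  decays the feeding state inside the linking channel is treated as a
  transcription slip), and the **threshold recharge** uses the current
  output `Y(n)`: recharging from the previous step's output would let a
  neuron fire on two consecutive steps right after recharging, destroying
  the refractory behavior the rule depends on.
- **Coupling weights** `m = w = ` inverse-distance kernel `1/√(p²+q²)`
  with zero self-weight; neighborhood sums are zero-padded at the border.
  Consequence: boundary neurons receive slightly weaker linking, and over
  many iterations the deficit propagates inward as a synchronization wave,
  so a uniform stimulus yields a dihedrally symmetric but not perfectly
  constant count map; tests assert symmetry plus near-uniformity.
- A useful closed trace: an uncoupled unit-stimulus neuron under the
  defaults fires at steps 1, 17, 34, 51, 68, 85 (the leaky threshold
  keeps a ~1.0 residual at each refire, which stretches the later
  intervals from 16 to 17 steps), total `T = 6` at `N = 100`; the test
  suite pins the implementation to an independently hand-stepped scalar
  recurrence.

**Stimulus normalization.** Highpass bands are signed detail coefficients:
the stimulus is `|band|` scaled by the band maximum (all-zero band stays
zero). Lowpass bands are min-max rescaled to [0, 1]; a constant band maps
to uniform 0.5 so that equal constants tie rather than one side winning.

**Selection.** Each band pair is fused independently (one PCNN run per
band per source): output pixel = A's coefficient where `T_A > T_B`, else
B's. Ties go to B, which makes `fuse(A, A) = A` an identity up to the
(exact) transform round trip. The rule copies, never blends — a property
asserted per band before reconstruction. Baseline rules `average` and
`max_abs` replace the selection for comparisons; by linearity of the
transform, the `average` rule reduces exactly to the pixel average.

**Color path.** For anatomical-gray + functional-color pairs the color
image is taken to YIQ, its luminance is fused with the gray image, and the
original chrominance is recombined. This luminance-substitution scheme is
an interpretation (the mechanism is not standardized); chrominance is
preserved exactly wherever the recombined RGB stays inside [0, 1], and
clipped otherwise. Output images are written as `round(255·clip(F, 0, 1))`;
metrics are computed on the pre-quantization float image.

## The metric suite

All metrics consume [0, 1] floats and evaluate on the 8-bit convention
(×255; 256-bin histograms for the information measures). `0·log 0 := 0`
throughout.

- **EN** — histogram entropy of the fused image, bits ∈ [0, 8].
- **MI** — `MI_AF + MI_BF` from 256×256 joint histograms.
- **Q^AB/F** — Sobel edge strength `g` and orientation `α = atan(g_y/g_x)`
  per image; per-pixel preservation = product of sigmoids in the strength
  ratio `min/max` and the orientation agreement `1 − |Δα|/(π/2)`, with the
  conventional constants (0.9994, −15, 0.5) and (0.9879, −22, 0.8), each
  sigmoid normalized by its value at perfect preservation so that
  `Q(A,B,F=A=B) = 1` exactly; weighted by source edge strength. Returns 0
  for edge-free sources.
- **PSNR** — `10·log10(255²/MSE)`; `inf` sentinel at zero MSE. Fusion has
  no single noise-free reference, so the reported value is the mean of the
  two single-source scores.
- **SD** — population standard deviation (contrast), 0–255 units.
- **AG** — average gradient, mean of `sqrt((dx² + dy²)/2)` with forward
  differences over the (M−1)×(N−1) valid region (the printed formula's
  parenthesization is ambiguous; this is the standard reading).
- **Q_ncie** — nonlinear correlation coefficients are computed in the
  uniform-marginal normalization, `NCC(X,Y) = I(X;Y)/log₂256` from the
  256×256 joint histogram. The raw "2 − joint entropy" form coincides with
  this for uniform marginals (the construction the original metric obtains
  by rank-transforming its inputs) but is unbounded for non-uniform
  images, so the normalized form is used. The score is
  `1 + Σ (λᵢ/3)·log₂₅₆(λᵢ/3)` over the eigenvalues of the 3×3 matrix with
  unit diagonal and pairwise NCC off-diagonal: 1 for identical images,
  ≈ 0.80 for independent ones.

Every metric is validated against an independently written brute-force
implementation (explicit loops, dict histograms) to 1e-10 (1e-6 for
Q^AB/F) on 50 random triples, plus closed-form cases.

## The synthetic test bed

Phantom pairs emulate the one property the method exists for:
complementary contrast. Both modalities share an elliptical skull ring
and soft-tissue interior; ellipse structures inside the head are bright
(0.85) in exactly one modality and plain tissue (0.25) in the other;
seeded Gaussian noise (σ = 0.01 default) is added and the result clipped
to [0, 1]. Ground-truth masks are returned for assertions. The functional
generator adds a smooth pseudo-colored uptake map whose luminance equals a
smooth baseline where activity is zero. Pairs are bitwise-reproducible
functions of (spec, seed).

Not emulated: partial-volume blur, bias fields, scanner noise statistics,
misregistration, anatomy more complex than ellipses. Passing tests
therefore demonstrate the *mechanism* — complementary structures are
selected into the fused image, selection preserves contrast that averaging
halves — not clinical image quality on real CT/MR/PET data.

## Problem sizes

Test and acceptance runs use 64×64–256×256 images, 1–4 levels, and the
full N = 100 PCNN iterations; the acceptance script fuses the default
256×256 pair (the conventional slice size for this kind of evaluation) in
a few seconds. All computations are deterministic given the seed.

## Known limitations

- Periodic boundary can wrap content across edges; use `symmetric` for
  display-quality fusion of real images and accept interior-only exactness.
- The NSDFB shear choice above depth 4 is untested territory (defaults go
  to depth 3).
- Q^AB/F and Q_ncie internal models are field-standard interpretations;
  absolute values are comparable within this package, not necessarily
  across other implementations with different constants or normalizations.
- The color path assumes the functional image's information is carried by
  chrominance + low-frequency luminance; saturated colormaps that encode
  activity purely in hue survive best.
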