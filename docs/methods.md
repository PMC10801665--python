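# Methods

This note records the models, numerical choices, and open design decisions
behind `hdrneedle`, in the order the pipeline runs.

## Synthetic phantom

The generator emulates the imaging situation of CT-guided interstitial HDR
brachytherapy of the pelvis, not CT physics. A soft-tissue ellipse
(Gaussian noise, mean 40 HU, sd 12) sits in air (−1000 HU) on a grid of
0.8 × 0.8 mm voxels and 5 mm slices — the default test grid is 64 × 64 × 16
(51 × 51 × 75 mm) so CPU suites run in minutes; full 512 × 512-class grids
are a config change. Needles are tubes of radius 0.75 mm (1.5 mm diameter
trocar) around per-needle analytic centerlines

    x(z) = x0 + b_x z + c_x z (z − z_tip),   y(z) analogous,

i.e. degree-2 polynomials with a linear tilt (default ≤ 5° from the slice
axis, exposed as config since insertion geometry varies by practice) and a
quadratic bow vanishing at entry and tip (default peak ≤ 1.5 mm). Voxels
whose in-plane center lies within the tube radius at the slice's z are
labeled; needle cores get 3000 HU. Tips end at a random depth between 70%
and 95% of the axial extent, so tip positions are *not* aligned to slice
centers — deliberately, because tip quantization by 5 mm slices is the
dominant clinical error source. Entry points keep a configurable minimum
separation (default 3 mm; 0 permits touching/crossing needles, the hard
case). The HR-CTV is an ellipsoid inflated until it strictly contains
every needle voxel; bladder-like and rectum-like ellipsoids sit anterior
and posterior, made mutually disjoint by construction.

Streak artifacts are angular cosine lobes around each needle cross-section
with a 1/(1+r) falloff, linear in their strength parameter, and never
touch needle-core voxels. They exercise robustness plumbing; they are not
beam-hardening physics. Consequences for interpretation: passing tests
show the pipeline recovers geometry from bright, tube-like, z-monotone
structures under noise, touching needles, and synthetic streaks — they say
nothing about contrast regimes where needles are not the brightest
structure, about couch/bone metal, or about real scatter textures.

## Segmentation network

A 3D encoder–decoder U-Net, channel-first without a batch axis (the recipe
is batch size 1). Per level: two 3×3×3 convolutions (zero padding), each
followed by group normalization (4 groups) and ReLU; 2× max pooling
between encoder levels; stride-2 transposed convolution + ReLU in the
decoder; skip concatenation; 1×1×1 convolution + sigmoid head. Group
normalization is applied in encoder *and* decoder by default;
`gn_encoder_only` restricts it to the encoder (both are tested). Depth and
width are configurable; the CPU test scale is depth 3 / 8 base channels.
Under the counting convention "3×3×3 convolutions plus up-convolutions,
excluding the 1×1×1 head", a depth-5 network has 2·5 + 3·4 = 22
convolutional layers; `conv_layer_count` documents this.

The additive attention gate on each skip connection computes, with x the
encoder skip feature and g the next-coarser decoder feature upsampled to
x's grid by trilinear interpolation,

    q = ψᵀ ReLU(W_x x + W_g g + b_xg) + b_ψ,   α = sigmoid(q),

all maps being 1×1×1 convolutions, and scales x voxelwise by α before
concatenation. The intermediate channel count is F_int = C_x/2 (minimum
1), a standard additive-attention sizing. The trilinear ×2 upsampling is
implemented as separable 1-D matrices so its adjoint in the backward pass
is exact (verified by a dot-product identity test).

Everything is implemented on numpy arrays with hand-written backward
passes; the 3×3×3 convolutions are direct numba kernels (forward and
input-gradient) plus a flat-offset BLAS formulation for the weight
gradient. Correctness rests on float64 central-difference gradient checks
over every parameter tensor and a per-voxel loop oracle for the gate.

Initialization is He-normal; the head bias starts at −4 so the initial
sigmoid output (~0.018) matches the extreme background prior of thin
needles — with the soft Dice loss this keeps the denominator small and the
early foreground gradient strong, which at toy scale is the difference
between converging in tens versus hundreds of steps. Optimization is Adam
(lr 5×10⁻⁴, β = 0.9/0.999, batch 1); the loss is soft Dice with ε = 10⁻⁴.
Prediction thresholds the sigmoid at 0.5.

## Training recipe

Inputs are scaled by a fixed 1/1000 (metal ≈ 3, tissue ≈ 0.04). Paired
augmentation applies the identical in-plane transform to image (linear
interpolation) and mask (nearest neighbor): rotation about the slice axis
(±15° default), horizontal/vertical flips, isotropic in-plane scaling
(0.9–1.1). Ranges are config knobs, not claims; rotations are in-plane
only because needles are near-axial and out-of-plane resampling would
break the slice-wise digitization contract. Central in-plane cropping
updates the origin so world coordinates of retained voxels are unchanged.
All randomness (shuffling, augmentation draws) derives from one seed;
repeated runs are bit-identical on one device.

The packaged learning benchmark (acceptance tests and
`scripts/acceptance.py`) trains depth-3/8-channel networks for 50 epochs
on 10 phantoms and evaluates 3 held-out phantoms, with augmentation off:
synthetic training data is i.i.d. and unlimited, so augmentation (an
anti-overfitting measure for scarce real data) adds cost without changing
what the benchmark demonstrates. Augmentation itself is covered by its own
unit and property tests.

## Digitization

Per-slice unweighted centroids of each 26-connected component (components
under 5 voxels discarded as noise) form the central trajectory — valid
because needles are z-monotone in this anatomy. An in-plane centroid jump
above 2× the needle diameter between consecutive slices flags the
component as a touching-needle merge; flagged needles are excluded from
error statistics with a warning rather than split, since no reliable
splitting rule exists at 5 mm slices. Least-squares polynomials x(z), y(z)
(default degree 3, fitted on centered/scaled z for conditioning) smooth
the quantization; the tip is the fitted point extrapolated half a slice
beyond the last mask slice, because a tube whose true tip lies anywhere
within a slice produces the same last mask slice — half a slice is the
unbiased correction and bounds the tip error by half the slice thickness.
Arc length uses trapezoid quadrature on 4096 samples; dwell positions
invert the cumulative table by interpolation (resolution ≪ 0.01 mm),
walking from the tip toward entry at the configured step (default 2.5 mm,
offset 0 — values a clinic would set per protocol). Prediction↔truth
needle matching minimizes mean in-plane curve distance over the z-overlap
with the Hungarian algorithm.

## Geometric metrics

DSC and Jaccard on voxel sets (empty-vs-empty defined as 1.0, with a
warning); Hausdorff as the exact symmetric maximum over voxel centers
scaled by the anisotropic spacing, in mm. Tip error is the mean absolute
difference of needle *lengths* along the fitted curves, which captures how
far along its own channel a digitized tip sits — the quantity that shifts
dwell positions; the Euclidean tip-to-tip distance is reported alongside
as a clearly-labeled diagnostic. Shaft error averages the in-plane distance
between the two fitted curves at z-slices present in both trajectories;
slices present in only one are excluded. The paired t-test is the classic
two-sided test on per-case differences; zero variance is an error, not a
p-value.

## Dose engine and DVH

The 1-D point-source TG-43 specialization is deliberate: the line-source
geometry factor and 2-D anisotropy F(r, θ) live in commercial systems and
are out of scope, while the point-source form with pluggable g(r)/φ_an(r)
tables is closed-form testable — unity tables reduce it to the
inverse-square law exactly. The bundled generic Ir-192 table (Λ = 1.109
cGy h⁻¹ U⁻¹, r₀ = 10 mm) is rounded from published consensus data and is
not a commissioning dataset; sources are input data, and no result here
depends on a specific commercial source. Distances clamp at 0.5 mm (tables
are undefined at r → 0; voxel centers can fall arbitrarily close to a
dwell); table extrapolation is an explicit opt-in (dose grids enable it,
point queries do not).

DVHs use exact voxel accounting (no sampling): the cumulative curve is
binned at 0.01 Gy, Dx% inverts it with linear interpolation, D100 is the
exact minimum, and D2cc takes the hottest 2 cm³ by voxel volume
(structures under 2 cc report D2cc as undefined). The pipeline's
manual-vs-automatic comparison holds dwell times fixed between plans and
normalizes them so the manual plan delivers the prescription (default
6 Gy) to HR-CTV D90 — dose is linear in time, so this is a single scale
factor applied to both plans, mirroring the clinical convention that only
the geometry differs between the two digitizations.

## Problem sizes and tolerances

The packaged study runs at 64 × 64 × 16 with 10 training and 3 validation
phantoms, depth-3/8-channel networks, 50 epochs, 3 seeds for the learning
medians — sizes chosen so the whole suite exercises every stage on one
CPU in well under half an hour. Numerical tolerances that matter:
soft-Dice ε = 10⁻⁴; group-norm ε = 10⁻⁵; gradient checks pass at 10⁻⁴
relative in float64; arc-length/dwell inversion is accurate to ≪ 0.01 mm;
metric oracles agree to 10⁻¹⁰ or exactly.

## Known limitations

- The phantom's intensity model (bright tubes + additive streaks) cannot
  probe failure modes of real metal artifacts or low-contrast needles.
- The per-slice-centroid centerline assumes z-monotone needles; strongly
  oblique or looping catheters would need a true 3-D centerline method.
- Touching-needle merges are flagged and excluded, not resolved.
- The dose engine is 1-D TG-43; no line-source geometry, no optimization
  of dwell times, no heterogeneity corrections.
- DICOM-RT and vendor plan dialects are out of scope; the JSON plan schema
  is the interchange format.
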