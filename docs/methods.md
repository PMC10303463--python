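# Methods

This note documents the models behind `steersim`, the parameters that
matter, and what the synthetic study does and does not demonstrate.

## Phantom model

A phantom is a 3D label volume on an isotropic grid with codes ordered by
radiological risk — 0 background, 1 skin, 2 adipose, 3 dense, 4 lesion —
plus a per-voxel lesion weight. The ordering is load-bearing: the
ground-truth operator is a *maximum* projection of the codes, so the most
suspicious tissue on each ray wins.

**Outline.** The compressed breast is parametric: a super-ellipse (exponent
2.5) in the axial plane with a flat chest-wall face, posteroanterior
semi-axis equal to the chest-wall-to-nipple distance (CND), extruded between
flat compression surfaces separated by the compressed breast thickness
(CBT), with the rim rounded near the paddles (rounding depth
min(CBT/2, CND/4)). A skin shell of configurable thickness (default 1.5 mm,
a typical mammographic value) wraps every surface except the chest-wall
face, built by Euclidean-distance dilation of the interior; the shell is
kept at least one voxel thick so it remains closed under face adjacency at
coarse grids. Outline generation is deterministic; randomness enters only
through parenchyma and lesions. A principled statistical shape model of
compressed breasts would require patient outline data this package does not
depend on; the parametric outline preserves the only properties the rest of
the pipeline consumes (CBT, CND, interior/skin masks).

**Parenchyma.** Interior voxels are split adipose/dense by thresholding
octave-summed 3D gradient-lattice (Perlin) noise at the empirical quantile
`1 − target_vbd` of the interior noise values, which makes the realized
volumetric breast density (VBD) match the target up to ties. Low octaves
provide coarse tissue compartments and high octaves texture, so a separate
coarse-tissue stage is unnecessary. Defaults: 6 octaves, base frequency
1/40 mm⁻¹ (structures at the ~4 cm scale of breast compartments),
persistence 0.5, lacunarity 2.0, independent seeded permutation per octave.
These are stated defaults, not fitted to patient texture statistics.

**Lesions.** Model I is a 7×7×7 mm³ ellipsoid with dense-tissue weight
w = 0.20; models II–IV are spiculated, 9×8×3, 10×14×4, 15×15×4 mm³ at
w = 0.35. A spiculated mask is an ellipsoidal core at 0.7 of the nominal
semi-axes plus 8–16 randomly oriented conical spicules (tapering to a floor
half-width of 0.75 voxel so tips survive voxelisation) and six axis-aligned
spicules that guarantee the bounding box spans the nominal dimensions; the
mask is clipped to the nominal-dimension ellipsoid. Insertion is
voxel-additive: covered parenchyma voxels take the lesion code and carry w,
interpreted at projection time as a (1−w)/w adipose/dense attenuation
mixture. Two lesions per phantom at uniformly drawn left–right /
posteroanterior positions, craniocaudal centre fixed at mid-thickness;
placements must lie fully inside parenchyma and keep centre separation of at
least the sum of bounding-sphere radii (rejection sampling, with per-phantom
failure recorded rather than aborting the cohort).

**Cohort splits.** Strata are (VBD tercile × lesion-shape combination × CBT
tercile). Split assignment is a controlled rounding of the stratum × split
proportionality table: each cell gets the floor or ceiling of its exact
share, reconciled by a max-flow so global split sizes match the ratio
exactly (7:1:1:2 gives 168/24/24/48 at 264 phantoms; the demo 4:1:1:2 gives
8/2/2/4 at 16) while no stratum deviates from proportionality by more than
one record. Every phantom is reproducible bit-for-bit from its manifest row.

## Projection model

The central projection places a point source on the normal through the
chest-wall detector edge midpoint at the source–image distance (738.01 mm),
with the phantom resting on a 25 mm air gap above an ideal photon-counting
detector. Attenuation is monoenergetic at an effective 20 keV with
representative soft-tissue coefficients (mm⁻¹): air 8·10⁻⁵, adipose 0.054,
skin 0.080, dense 0.084 — ordered µ_air < µ_adipose < µ_skin ≤ µ_dense and
editable via `MaterialTable`. Polyenergetic spectra, scatter, detector blur
and electronic noise are out of scope; the segmentation task consumes
relative contrast, not dosimetry.

Line integrals use Siddon's exact ray–grid traversal. Two implementations
share the geometry: a pure-numpy per-ray path (`siddon_raypath`, returns
voxel/length pairs; the reference used in tests) and a numba kernel that
accumulates ∫µ dl for all detector pixels. The mean pixel signal is
`I₀·exp(−∫µ dl)`; with a noise seed, pixels are independent Poisson draws.
The AEC surrogate sets `I₀ = target·exp(µ_eff(vbd)·cbt)` with µ_eff the
VBD-weighted adipose/dense mixture, so the transmitted count behind the
breast centre stays near the target (default 200 photons/pixel, a low-dose
scout level at the demo pixel size) and is monotone in thickness and
density, which is all the downstream stages rely on.

## Ground truth

Risk maps take the per-column maximum label along the compression axis
(orthographic; computed on the full label volume, the five codes folding to
four classes with skin → background). The phantom-grid map is resampled to
the detector grid by nearest neighbour through the cone magnification of the
phantom mid-plane (CBT/2 above the support) — mid-plane magnification
minimises worst-case in-plane misalignment, and nearest neighbour cannot
invent classes. Image/label pairs are cropped on the nipple side to the
cohort's largest magnified posteroanterior extent (default 20 % row
reduction) and resampled — images by local-mean averaging, labels by nearest
neighbour — to the training grid (96×64 demo, 600×360 full scale). At the
coarse demo grid a thin spiculated lesion can fragment into several
ground-truth clusters; finding-level metrics count clusters, not lesions,
which is the consistent convention on both sides of the match.

## Segmentation

The segmenter is a 2D encoder–decoder with skip connections: per level two
3×3 same-padded convolutions with ReLU, 2×2 max-pool between levels,
nearest-neighbour upsampling with skip concatenation on the way up, 1×1
softmax head over the four classes. Default capacity is deliberately small
(3 levels, 8–16 base channels) so CPU training is practical. Forward,
backward and the Adam optimiser are implemented on numpy arrays (im2col
convolutions); the backward pass is verified against numerical gradients in
the test suite, and everything is deterministic given the seed. Training
minimises class-weighted cross-entropy (weights default to inverse pixel
frequency on the training split, normalised to mean 1, addressing the
extreme rarity of lesion pixels), batch size 6 (4 at demo scale), learning
rate 3·10⁻⁴, early stopping on validation loss with patience 20 (10 demo)
up to 250 (40 demo) epochs, restoring the best-validation weights. Inputs
are log-transformed (`ln(1+counts)`) and standardised by training-set
statistics, which removes most of the exposure-level variation the AEC
introduces across breasts.

A multinomial logistic regression on per-pixel neighbourhood features
(log-signal, 3×3/9×9 box means, 9×9 standard deviation, normalised
posteroanterior coordinate) ships as a fast convex baseline for exercising
the calibration and evaluation stages.

## Dirichlet calibration and calibration error

The calibration map is `µ̂(q; W, b) = softmax(W ln q + b)` on each pixel's
probability vector, clamped at 10⁻¹² before the logarithm; (I, 0) is exactly
the identity. Fitting minimises the mean multinomial negative log-likelihood
on the calibration split (pixels treated as independent instances) by
L-BFGS from the identity, with analytic gradients; optional off-diagonal/
intercept L2 (ODIR-style) regularisation is available but off by default.
Up to 2·10⁵ pixels are used, subsampled with per-class stratification. (W, b)
are identifiable only up to per-column shifts of ln-space, so recovery tests
compare maps in probability space. If the optimiser cannot improve on the
identity, the identity is returned — the fitted map never has higher
calibration-split NLL than no calibration.

Reliability tables bin one-vs-rest probabilities into m equal-width bins
(default m = 10; the last bin is right-closed so p = 1 lands in bin m), and

    classwise-ECE = (1/k) Σⱼ Σᵢ (|B₍ᵢ,ⱼ₎|/N) · |ȳⱼ(B₍ᵢ,ⱼ₎) − s̄ⱼ(B₍ᵢ,ⱼ₎)|

averages the bin-weighted gaps over all k = 4 classes (the background class
included; configurable). Empty bins contribute nothing.

## Evaluation

Pixel metrics pool all test pixels: one-vs-rest ROC per class with
trapezoidal AUC; the operating point minimises the Euclidean distance to
(FPR, TPR) = (0, 1), where TPR/TNR/PPV/NPV are read off; Dice and Jaccard
on the argmax class maps (ties break to the lower, safer code), pooled
rather than per-image-averaged, with Jac = Dice/(2 − Dice) holding
identically. Finding metrics use 8-connected components of the lesion
class: per ground-truth cluster TP/FN by any-overlap, one FP per
non-overlapping predicted component (a predicted component covering several
truth clusters yields that many TPs and no FP); TP + FN equals the number
of truth clusters at every threshold. The FROC sweeps thresholds 1.00 to
0.00 in 0.01 steps (101 points); sensitivities at 2 and 5 FP/image are read
by linear interpolation. FP/image is not mathematically monotone in the
threshold under component counting — at very low thresholds FP components
merge with overlapping ones — which is a property of the counting rules,
not of this implementation.

## Scale choices

The default ("demo") study — 16 phantoms at 1 mm voxel pitch split 8/2/2/4,
~2.5 mm detector elements, 96×64 training images, a 3-level 8-channel net —
was chosen so the complete pipeline runs in about a minute on one CPU core,
making the end-to-end behaviour testable; `paper_scale_config()` exposes the
full-scale study (264 phantoms at 0.5 mm pitch split 168/24/24/48, native
85 µm detector, 600×360 images), which needs workstation-class compute. At
demo scale the segmenter is weak in absolute terms; what the pipeline
demonstrates — robustly across seeds — is the *directional* effect of
Dirichlet calibration: large reductions in classwise-ECE and in
false-positive suspicious findings at the operating threshold, with the
NLL on the calibration split never increasing.

## What the synthetic data does not show

Perlin-threshold parenchyma lacks ductal/vascular anatomy and skin-line
texture gradients; the monoenergetic, scatter-free, blur-free projection is
cleaner than any real scout image; ground truth is derived from the same
phantom that generates the image, so there is no observer noise or
inter-reader ambiguity in the labels. Passing tests therefore validate the
pipeline's algorithms and their contracts, not clinical segmentation
performance; transferring the segmenter to real low-dose projections would
require domain adaptation and clinical fine-tuning, which are outside this
package's scope.
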