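# Methods

## Texture model

Each tissue label *l* ∈ {CB, GM, PV, WM, BG} carries a mean μ_l, a
conditional variance β_{l,00} (> 0, intensity² units on the [0,1]
normalized scale) and ten symmetric neighbour weights β_{l,j}
(dimensionless), one per ±offset pair of the 20-neighbour lattice system
(squared radii 1, 2, 4, 5; offsets sorted by radius then angle from the
+x axis, y downward; slot 0 is the horizontal pair, slot 1 the vertical).

The field is a conditional autoregression: given its neighbours, a pixel
is Gaussian with mean μ_i + Σ_j β_{l,j}(x_j − μ_j) and variance β_{l,00},
where each neighbour's mean comes from that neighbour's current label and
background or off-lattice neighbours drop out of the sum. Equivalently,
the joint precision has Q_ii = 1/β_{l,00} and Q_ij = −β_{l,j}/β_{l,00};
the package normalizes the parameterization this way because it is the
unique reading under which (a) the pseudo-likelihood estimator's
"residual variance" target for β00 is exactly the model's conditional
variance, (b) the Mahalanobis feature d = residual²/β00 is a squared
z-score, and (c) the per-pixel conditional agrees to machine precision
with analytic conditioning of the assembled joint Gaussian (the test
suite verifies this on 5×5 lattices to 1e-8). On multi-label boundaries
the assembled joint symmetrizes the off-diagonal across the two labels;
the sampler always uses the centre pixel's own label parameters.

The background label is pinned at μ = 0, β00 = 1e-30, β = 0. Masked-out
pixels are exactly 0 after normalization, so the near-delta density makes
BG effectively certain there and effectively impossible for tissue
pixels; BG pixels outside the mask are additionally frozen during
sampling.

## Label estimation

Labels are proposed from [p(x_i | N_i, l) · γ_l]^{1/t}, normalized over
the current label set, with prior proportions γ = [0.010, 0.045, 0.030,
0.061, 0.854] for [CB, GM, PV, WM, BG] by default (a cohort-level prior
from late-recovery scans; it mainly prevents empty labels). The
temperature schedule is t(n) = ln4/ln(3+n) for n ≤ 253 — t(1) = 1,
t(253) = 0.25 — and t = 0 for n = 254..258, where the update degenerates
to the conditional argmax (iterated conditional modes). The iteration
count is fixed by the schedule; no extra convergence test is applied.
Argmax ties break toward the lower index in [CB, GM, PV, WM, BG].

Pixels are updated simultaneously within 3×3-block coding sets: no two
pixels congruent mod (3, 3) are neighbours under the 20-neighbourhood
(all offsets have |dy|, |dx| ≤ 2 and none is ≡ (0,0) mod 3), so nine sets
form the minimal valid partition. Sampling uses the Gumbel-max trick on
the tempered log-probabilities; all likelihood arithmetic stays in the
log domain because γ^{1/t} underflows at small t. A single integer seed
expands into per-sweep substreams (numpy SeedSequence.spawn), which makes
every run bit-reproducible.

Parameters are re-estimated after every sweep (the tightest coupling of
the two alternating steps; it converges on all fixtures): μ̂_l is the
in-label mean; the β̂_{l,j} regress the centered pixel value on the ten
symmetric-pair neighbour-deviation sums over in-label pixels (least
squares, no intercept); β̂00 is the mean squared residual. Labels with
fewer than 50 pixels fall back to β = 0 with β00 the in-label variance
(warned); empty labels keep their previous parameters. The 5-label GMM
initialization fits the full frame so the point mass of masked-out zeros
forms the BG component, and maps components to [BG, WM, PV, GM, CB] by
ascending mean — the T2 brightness ordering of these tissues.

## Simulation

`simulate_field` draws textures from a fitted model by Gibbs sampling the
same conditionals in coding-set order, starting from the label means.
The default 200 sweeps was chosen by a burn-in stability check (summary
moments move < 5% between 200 and 400 sweeps at fixture parameters).
Values are clipped to [0, 1] only on output so the chain keeps exact
Gaussian conditionals; at the default parameters the tissue means sit
many conditional standard deviations inside the unit interval, so
clipping is a tail safeguard rather than a distortion.

## Metric learning

Per tissue pixel the three Mahalanobis quantities d_WM, d_GM, d_CB are
computed exactly as the squared precision-scaled residual (the squared
form is used as printed in the source formulation; a square-root variant
is available via `feature_maps(..., squared=False)` for sensitivity
analysis). The MRI-side landmark of a tissue is the mean (d_WM, d_GM,
d_CB) triple over its pixels — the only tissue-mean construction that
lives in the distance space itself. The histology-side landmarks are the
per-tissue (myelin, cellularity) staining means, either fitted by the
histology GMM or the published defaults WM (0.735, 0.230), GM (0.333,
0.666), CB (0.341, 0.785); inter-landmark distances on that side are
Euclidean, which makes the two spaces commensurable. One positive scale
per distance channel is fitted by Nelder-Mead (start (1,1,1), relative
tolerance 1e-6, max 2000 evaluations, one restart from the optimum) to
minimize the RMS mismatch of the 3×3 distance tables. Multilateration
minimizes Σ_l (‖p − anchor_l‖ − s_l d_l)² from the anchor centroid with
the same settings; anchors are sorted internally so anchor order cannot
perturb the floating-point path. PV pixels receive features (they are
tissue); BG pixels do not. Identical distance triples are memoized, which
makes whole-image multilateration cheap on label-homogeneous regions.

When a metric-space step needs exactly three anchors, the PV label is
dropped first: its prior mass is renormalized over the remaining labels
and its pixels are reassigned by the t = 0 proposal argmax evaluated in
the pre-drop neighbour context.

## Supervised comparators

Segmentation regression predicts the response per segmented label from
the pixel intensity and its ten neighbour-pair intensity sums. The MAE
loss uses median (τ = 0.5 quantile) regression per label; the RMSE loss
uses least squares with per-subject fixed-effect intercepts (averaged at
prediction time for unseen subjects) — a deliberate simplification of a
random-effects formulation, adequate for a comparator whose role is an
upper-reference for the unsupervised feature. Manual lesion masks can
override the segmentation as an extra label. The additive model is the
identity-basis (linear) case only, in three nested variants: intensity
alone, + neighbour terms, + lesion dummy with its intensity interaction;
spline bases are deliberately out of scope (they are an off-the-shelf
black box in the original comparison). Supervised models are scored by
leave-one-subject-out cross-validation with per-fold R², Pearson r and
residual correlation; the latter is defined here as the Pearson
correlation between residuals and the true response (a documented choice
— the quantity is not pinned down by the source material, so it is kept
out of any acceptance-grade claims).

## Evaluation

Confusion matrices count non-excluded (by default non-BG) pixels; the
per-mille presentation rounds half-up, and the printed-table accuracy
helper divides the diagonal by the nominal 1000 because rounded tables
need not sum to exactly 1000. Accuracy intervals are Clopper–Pearson
(the conservative exact binomial). Pearson intervals use the Fisher z
transform. AUC uses the midrank Mann-Whitney formulation with DeLong
variance for intervals and the paired DeLong test for comparisons —
written in-house since no installed package exposes the covariance
estimator. The Mann-Whitney wrapper is exact for small tie-free samples,
asymptotic with tie correction otherwise, and returns p = 1 for fully
degenerate (all-tied) inputs.

## Synthetic phantom

The phantom emulates a masked transverse spinal-cord slice at the MRI
scale (64×64 default): an elliptical cord in empty background, an
H-shaped grey-matter region, WM surround, two small CB blobs at the
dorsal horn tips standing in for the substantia gelatinosa, an optional
1-pixel PV ring at the WM/GM interface, and an optional ventral lesion
disc pooled into CB. Geometry is parametric, not an anatomical atlas —
only the statistical structure matters for testing. MRI is drawn from the
GMRF model itself (per-tissue means 0.30/0.45/0.60/0.82 for
WM/PV/GM/CB, conditional sd 0.03/0.06/0.10 for the high/medium/low
contrast presets, WM pair weights 0.10 horizontal and 0.05 vertical);
histology channels are per-tissue Gaussian noise (sd 0.10) around the
published staining means, with PV given the WM/GM midpoint staining. The
`dark_core` flag makes the lesion core darker than WM — the documented
failure mode in which core pixels are misread as GM — for regression
tests of that limitation.

Because MRI textures come from the generative model, simulate→estimate
round trips are exact by construction, and segmentation tests measure
algorithmic, not modelling, error. What passing phantom tests do **not**
show: robustness to coil bias fields, partial-volume physics beyond a
labelled ring, staining artifacts, cross-modality misregistration, or
real anatomical variability — real-data performance claims are outside
what this fixture can support. On the high-contrast phantom the GMM
initialization is already near ceiling, so the GMRF's improvement is
small there by design; its advantage is larger at lower contrast.

## Numerical choices and degenerate inputs

Min–max normalization over a degenerate (constant) range maps to 0 and
constant masked MRI regions raise instead of silently producing flat
images. Zero-total RGB pixels get zero shares. GMM covariances are
regularized by 1e-6 on the diagonal; an all-identical sample set raises.
Collinear multilateration anchors raise (triangle-area tolerance 1e-9
relative). Estimated β00 is floored at 1e-12. Down-sampling uses k
levels of the classic 5-tap binomial kernel with reflect boundaries and
requires an exact power-of-two size ratio (pad into a uniform canvas
first).

## Problem sizes

Default test and validation runs use 64×64 lattices, 258 annealing
iterations, 200 simulation sweeps, and 20-seed replication for parameter
recovery — sizes at which every property in the test suite is stable
under seed changes while the whole suite stays fast enough to run on
every commit.
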