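# gmrftex

Unsupervised estimation of **myelin** and **cellularity** content from
standard T2-weighted MRI, built around Gaussian Markov random field
(GMRF) texture segmentation and Mahalanobis-distance metric learning,
with supervised regression comparators and a fully seeded synthetic
spinal-cord phantom for validation.

## The problem

Myelin integrity is central to demyelinating disease (e.g. multiple
sclerosis), but conventional T2-weighted MRI is pathologically
non-specific: signal intensity alone does not quantify myelin. Histology
(eriochrome cyanine for myelin, neutral red for cell nuclei) does, but
only *ex vivo*. This package implements an analysis chain that learns a
mapping from MRI texture to histology staining units without pixel-wise
supervised training, for researchers working with co-registered
MRI–histology data from small-animal demyelination models.

## The model

Tissue texture is modelled as a GMRF over the 20 nearest lattice
neighbours (10 unique symmetric parameters). Conditionally on its
neighbours, a pixel with tissue label *l* is Gaussian:

    x_i | x_N(i)  ~  N( μ_l + Σ_j β_{l,j} (x_j − μ_j) ,  β_{l,00} )

with per-tissue mean μ_l, conditional variance β_{l,00} and pair weights
β_{l,j}. The hidden label field over {CB, GM, PV, WM, BG} is estimated by
annealed Gibbs sampling — proposals ∝ [p(x_i | N_i, l) γ_l]^{1/t(n)} with
prior tissue proportions γ and temperature t(n) = ln4 / ln(3+n) decaying
to 0.25 at n = 253, then five iterated-conditional-modes sweeps —
alternating with pseudo-likelihood least-squares parameter re-estimation.
A Gaussian-mixture fit of the T2 intensities initializes the labels.

Feature estimation then computes, per pixel, Mahalanobis distances to the
WM, GM and CB tissue models,

    d_il = ( (x_i − μ_l) − Σ_j β_{l,j}(x_j − μ_j) )² / β_{l,00},

scales the three distance channels by Nelder-Mead to best match the
inter-landmark distances of the histology (myelin, cellularity) tissue
means, and multilaterates each pixel against those anchors. The resulting
coordinates *are* the myelin and cellularity estimates, in histology
staining units.

Supervised comparators (per-label segmentation regression with RMSE or
median/MAE loss, and identity-basis additive models with optional
neighbour-texture and lesion-dummy terms) plus evaluation utilities
(confusion matrices with exact binomial CIs, Fisher-z Pearson intervals,
DeLong AUC, Mann-Whitney, cohort median maps) round out the pipeline.

## Worked example

```python
import numpy as np
import gmrftex as g

ph = g.make_phantom(seed=1)                      # 64x64 cord phantom
init = g.gmm_initialize_mri(ph.mri, seed=1)      # 5-label GMM init
labels, model = g.segment(ph.mri, init, seed=1)  # annealed GMRF

mask = ph.mri.mask
print("GMM  accuracy:", (init.labels[mask] == ph.labels.labels[mask]).mean())
print("GMRF accuracy:", (labels.labels[mask] == ph.labels.labels[mask]).mean())

labels4, model4 = g.drop_label_renormalize(labels, ph.mri, model, "PV")
_, landmarks = g.segment_histology(ph.hist_blue, ph.hist_red, seed=1)
fmap = g.feature_maps(ph.mri, labels4, model4, landmarks)

sel = np.isfinite(fmap.myelin) & mask
print("myelin r:", g.pearson_ci(fmap.myelin[sel], ph.hist_blue.values[sel]))
```

prints

```
GMM  accuracy: 0.9960159362549801
GMRF accuracy: 0.9970119521912351
myelin r: (0.8404460058444488, (0.8210893399164176, 0.8581074980593734))
```

The GMRF refines its mixture-model initialization (99.6% → 99.7% of
masked pixels correct against the phantom's generating labels — on this
high-contrast phantom the initialization is already near ceiling), and
the unsupervised myelin map correlates r = 0.84 (95% CI 0.82–0.86) with
the phantom's blue staining channel; the cellularity map reaches r = 0.88
against the red channel. The fitted WM texture on this phantom is
μ = 0.297, β00 = 9.2e-4, with the horizontal pair weight β01 = 0.06 —
the generating values are μ = 0.30 and β01 = 0.10 (the conditional
variance shrinks and weights attenuate slightly because estimation is
per-sweep on the evolving label field).

The same pipeline is available from the shell:

```sh
gmrftex phantom --seed 7 --out p
gmrftex segment --image p/mri.tif --mask p/mask.png --seed 7 --out s
gmrftex features --image p/mri.tif --mask p/mask.png --labels s/labels.png --out f
gmrftex evaluate --truth p/truth_labels.png --pred s/labels.png --out e
```

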