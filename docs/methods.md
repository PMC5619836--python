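# Methods notes

## Model and assumptions

The package treats a heterogeneous image collection as points
x_1, …, x_{l+u} in a feature space describing the common channel, with a
target variable (a molecular channel's pixel values, or time) observed
only on a labeled subset Ω.  The estimate for the unlabeled points is
the harmonic extension: the unique minimiser of the graph Dirichlet
energy Σ_ij w_ij‖f_i − f_j‖² with the observed values clamped,
equivalently the solution of the discrete Laplace equation with the
labels as boundary data, f_u = (D_u − W_uu)⁻¹ W_ul Y.

Two assumptions carry all the weight:

- **Low intrinsic dimension.** The process is driven by few latent
  parameters (here essentially one, developmental progression), so the
  images populate a low-dimensional manifold in feature space.
- **Smoothness.** Every target variable is a smooth function of that
  latent parameter; morphologically similar images then have similar
  target values, so clamped neighbourhood averaging is a consistent
  estimator.

When these fail — reporters of intrinsically stochastic processes,
branching dynamics with no single common variable — the harmonic
estimate degrades gracefully (it always stays inside the label range, by
the maximum principle on connected graphs) but is no longer meaningful.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| local-scale neighbours k | 10 | points | self-tuning kernel bandwidth; mean distance to the 10 nearest neighbours adapts σ_i to sampling density |
| canonical size | 100 | px | working resolution after resize |
| occupancy | 0.8 | fraction | specimen's major diameter relative to the frame |
| renorm σ | 10 | px | Gaussian scale of the local-average intensity flattening; larger than a nucleus, smaller than the specimen |
| logistic gain / midpoint | 10 / 0.5 | — | per-dataset contrast parameters on the renormalised (≈1-centred) scale; overridable per dataset in the YAML config |
| averaging scale | 64 | px | scattering low-pass 2^J; J = 6 dyadic wavelet scales |
| orientations L | 8 | — | Morlet orientations over π |
| scattering order | 2 | — | first order discards too much texture; third adds little |
| CV fold rule | ~20 held out per fold | points | K = round(l/20), clamped to [2, l] |
| outlier factor | 2 | — | drop points (for plots only) whose nearest-neighbour distance is ≥ 2× the median |

Spiral generator defaults: a = 1, b = 4π (two turns), c = 1, d = 50,
e = 0.5 (one interior signal bump), coordinate noise sd 0.02, t uniform
on [0, 1].  These are package choices producing a curve with ~2 turns
and a single smooth signal peak; all are overridable.

## The scattering implementation

The 2-D scattering transform is implemented in-package with numpy FFTs:
Morlet filters built in the Fourier domain (envelope σ_j = 0.8·2^j,
centre frequency 3π/4·2^(−j), slant 4/L for angular selectivity,
periodised over the grid, zero-mean by construction) and a Gaussian
low-pass at σ_J = 0.8·2^J.  Second-order paths are restricted to
j2 > j1.  Coefficients are read out at a coarse grid of stride ~2^J
(four positions for 100-px images at scale 64), so the feature dimension
is (1 + J·L + L²·J(J−1)/2) × n_positions — 4036 at the defaults.  The
dimension is determined by this filter-bank convention and asserted as
such; other toolboxes' conventions give different totals for nominally
identical settings.  Measured behaviour at the defaults: a 2-px
translation changes the feature vector by <0.1% in relative Euclidean
distance (vs ~50% in pixel space), and the relative feature distance
grows monotonically and boundedly over deformation amplitudes 1–4 px.

## Numerical choices

- **Solver.** (D_u − W_uu) is symmetric positive definite on graphs
  connected to the labeled set; a Cholesky factorisation is shared by
  all right-hand-side columns of a modality (the Euclidean objective
  decomposes per column).  On a numerical failure the solve retries with
  Tikhonov regularisation ε = 10⁻¹⁰·tr(A)/n.
- **Connectivity.** Before solving, a connected-components check on the
  graph thresholded at w > 10⁻¹² reports which components have no
  labeled point, instead of producing garbage.
- **Local scales.** The self-distance is excluded from the k nearest
  neighbours (it would bias every σ down); ties break by index for
  determinism; a zero σ (k-fold duplicates) is replaced by the smallest
  positive σ with a warning.
- **Dense W.** n ~ 10²–10³ makes the dense matrix and direct solves
  cheap; no k-NN sparsification is applied.
- **Renormalisation floor.** The local-average denominator is floored at
  10⁻⁶ × image max so background pixels cannot divide by ~0.
- **Preprocessing order.** register → resize → renormalize → logistic.
  Registration and centring precede intensity operations; resizing
  before renormalisation keeps the renorm σ meaningful in canonical
  pixels.
- **Foreground.** Otsu threshold on a smoothed image (σ = side/32, so
  granular nuclei merge), largest connected component; interpolation is
  bilinear throughout.
- **Coordinates.** Row-major grids, origin top-left, angles ccw from +x
  with +y up; the registration reference direction is −π/2 (ventral
  pointing down).  The ventral-most point is a manifest annotation, not
  a detector — inventing an unvalidated detector was deliberately
  avoided.

## Cross-validation design

Genuinely unlabeled points stay in the graph while labeled folds are
artificially hidden: the error then reflects the semi-supervised
setting, and measurably decreases as unlabeled points are added (on the
spiral: ~0.9% at u = 0 vs ~0.5% at u = 300, 100 repetitions).  The
signal range for normalisation is computed over the entire labeled set
of the channel; per-pixel errors of image modalities are averaged over
all pixels before reporting.  Repetition r draws its partition from
seed + r; dispersion is the standard deviation across repetitions.  A
channel stained in several fixed datasets is used as-is by default; an
optional per-dataset rescaling of labels to a common [0, 1] range exists
for batch-effect-ridden data but is off, since it changes the units of
the completed values.

## Diffusion maps

Convention: diffusion time t = 1; coordinates are the leading
non-trivial right eigenvectors of D⁻¹W, unit-normalised and scaled by
their eigenvalues.  On a densely sampled connected curve all leading
Markov eigenvalues approach 1, so ratios of eigenvalues are
uninformative about dimensionality; the package's operational test of
"effectively one-dimensional" is the Laplacian gap ratio
(1 − λ₁)/(1 − λ₂) < 0.5 (measured ≈ 0.05 on the synthetic study).
Outlier filtering is exposed only for plotting and never removes points
from the fusion graph, which the API enforces by keeping the two code
paths separate.

## Synthetic generators: what they do and do not emulate

The **spiral** reproduces the three-modality toy setting exactly
(coordinates/signal/time, invertible latent parameterisation).  The
**synthetic study** emulates the structure of a live + fixed imaging
campaign: a latent pseudo-time drives a deforming nuclear ring (linear
ventral invagination plus a linear aspect change, so the deformation
rate never vanishes and every pseudo-time is morphologically
distinguishable) and five molecular channels with smooth angular
expression domains and smooth temporal amplitudes; the generator reports
a per-channel Lipschitz constant in pseudo-time.  It does **not**
emulate nuclear division cycles, stochastic reporters, per-embryo
anatomical variability, staining batch effects, or 3-D geometry —
passing tests therefore demonstrate correctness of the machinery under
the method's assumptions, not performance on real microscopy.

## Problem sizes used by the test suite

The suite favours sizes that keep a full run around a minute of compute
while preserving the claimed effects: the spiral benchmark at its native
420 points and 100 CV repetitions; the noiseless end-to-end study at 40
live frames + 2×15 fixed images of 100×100 px; the noise sweep and unit
tests on reduced studies (64-px images, averaging scale 32, 24–32
images).  The pipeline caches scattering features on disk keyed by a
content hash of the preprocessed pixels and filter-bank settings, so
re-runs with unchanged inputs skip extraction and reproduce identical
outputs.

## Known limitations

- Estimated times of fixed snapshots are on the live movie's clock only
  as far as the graph geometry constrains them; multiple live movies are
  not mutually aligned.
- The harmonic estimate is a point estimate; no per-pixel uncertainty is
  attached.
- The movie-coloring blend (per-channel [0, 1] rescaling by training
  range, additive RGB with clipping) is a display convention, monotone
  in the channel values but not radiometrically meaningful.
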