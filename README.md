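# trajfuse

Fusing heterogeneous imaging datasets — live movies and fixed, stained
snapshots — into one continuous multivariable trajectory.

## The problem

Imaging studies of developing tissues produce complementary but
incomplete views of the same dynamical process.  Live imaging gives
morphology (say, nuclear positions) as a function of time but is limited
to a few reporters; fixed-and-stained samples reveal molecular patterns
— protein phosphorylation, transcription-factor localisation, mRNA
expression — but carry no timestamp, and each staining protocol covers
only a subset of the channels of interest.  Arranged as a matrix whose
columns are images and whose rows are variables (morphology, each
molecular channel, time), the data form a matrix-completion problem:
every column has the common morphology channel, and the rest of its
entries must be estimated from the other columns.

`trajfuse` solves this by graph-based semi-supervised learning.  It is
aimed at quantitative biologists who have a collection of cross-section
images sharing a nuclei (or equivalent) channel and want a "colored
movie": every live frame annotated with estimates of every molecular
channel, with cross-validated error bars.

## The method

1. Every image's common channel is normalised (registration to the
   annotated ventral-most point, resize so the specimen fills 80% of a
   100 × 100 frame, local-average intensity renormalisation, logistic
   contrast) and mapped to a second-order **scattering transform**
   vector (Morlet wavelets, averaging scale 64 px) — a representation
   locally invariant to translation and stable to small deformations.
   Per-dataset point clouds are centred separately.
2. Pairwise similarities use a self-tuning Gaussian kernel,
   `w_ij = exp(−‖x_i−x_j‖² / (σ_i σ_j))`, with each local scale σ_i the
   mean distance to the point's 10 nearest neighbours.
3. For each target variable with labels y on the index set Ω, the
   missing values minimise the graph Dirichlet energy
   `Σ_ij w_ij ‖f_i − f_j‖²` subject to `f_i = y_i` on Ω.  This
   **harmonic extension** has the closed form
   `f_u = (D_u − W_uu)⁻¹ W_ul Y`, solved once per modality for all label
   columns (pixels) simultaneously.
4. Accuracy is quantified by repeated K-fold cross-validation on the
   labeled points (K chosen so ~20 points are held out per fold), scored
   by the **normalized absolute error** — mean |prediction − truth|
   divided by the channel's signal range.

Diffusion-map embeddings of the affinity graph are provided for
inspecting the latent one-dimensional geometry, and two synthetic
generators (a noisy planar spiral with a scalar signal, and an
embryo-like study whose pseudo-time drives both morphology and molecular
patterns) make every stage testable without any downloads.

## Worked example

```python
from trajfuse import GraphFusionModel
from trajfuse.datasets import generate_study
from trajfuse.features import ScatterConfig
from trajfuse.prep import PrepConfig

study = generate_study(
    n_live_frames=24,
    fixed_design=[(10, ("dpERK", "Twi")), (10, ("Dl", "rho"))],
    image_size=64, noise_sd=0.0, seed=0)

model = GraphFusionModel.from_study(
    study, prep_cfg=PrepConfig(canonical_size=64),
    scatter_cfg=ScatterConfig(averaging_scale=32))
results = model.fit()
print(results.summary())
print(results.cross_validate(repetitions=5, seed=0).to_string(index=False))
```

prints

```
Graph fusion results
============================================================
observations: 44    feature dim: 2724
metric: euclidean    local-scale neighbours: 10
affinity: dense 44x44, sigma in [0.00803, 0.0233]
------------------------------------------------------------
modality     labeled estimated       min       max      cv NAE
Dl                10        34  5.03e-16      0.98      0.0109
Twi               10        34  3.03e-23     0.975      0.0066
dpERK             10        34  1.58e-18     0.901      0.0118
rho               10        34  5.45e-34     0.931      0.0026
time              24        20         0         1      0.0496
============================================================

modality  K  repetitions  mean_nae       sd
      Dl  2            5  0.010919 0.002945
     Twi  2            5  0.006605 0.002315
   dpERK  2            5  0.011785 0.002631
     rho  2            5  0.002646 0.000592
    time  2            5  0.049592 0.011024
```

Each molecular channel was observed on only 10 of the 44 images, yet its
per-pixel pattern is recovered on the remaining 34 with a
cross-validated error of ~0.3–1.2% of the signal range; the live
timestamps propagate to the 20 fixed snapshots ("time" row), placing
each stained image on the movie's clock.  `results.trajectories` holds
the completed per-pixel matrices, and `trajfuse.color.colorize_frames`
blends them over the live frames to produce the colored movie.

The same workflow is available from the shell:

```bash
trajfuse simulate --n-live 24 --fixed 10:dpERK,Twi --fixed 10:Dl,rho --out study/
trajfuse fuse --study study/ --out run/ --seed 0
trajfuse embed --study study/ --out embedding.csv
```

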