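# gpmaps

Inference, epistasis summaries and visualization of **complete
genotype–phenotype maps** over combinatorial sequence spaces.

A genotype–phenotype map assigns a phenotype f(x) to every length-ℓ
sequence x over an α-letter alphabet — a vector of α^ℓ values (262,144 for
9 nucleotides). MAVE experiments measure noisy phenotypes for a subset of
sequences; collections of natural sequences provide counts shaped by
function. `gpmaps` turns either kind of data into a complete map with
calibrated uncertainty, quantifies its genetic interactions, and embeds it
for visualization, all with matrix-free linear algebra that never builds an
α^ℓ × α^ℓ matrix:

* **Minimum-epistasis interpolation (MEI)** — complete a partially observed
  map by minimizing the mean squared local epistatic coefficient
  fᵀΔ(P)f/s, with exact interpolation of noiseless data and Gaussian
  uncertainty from the precision-form posterior.
* **Variance-component (VC) regression** — Gaussian-process regression with
  the prior covariance K = Σ_k λ_k P_k diagonal in interaction order; λ is
  estimated by kernel alignment of the empirical distance–covariance
  function, and posterior means/contrast variances are computed with
  conjugate gradients.
* **SeqDEFT** — sequence probability density estimation from counts:
  π_i ∝ e^(−φ_i) with a multinomial likelihood and an improper prior
  penalizing local epistasis of the latent field φ; the prior strength a is
  chosen by cross-validation between the empirical (a = 0) and
  independent-sites (a = ∞) limits; Laplace-approximate uncertainty for
  contrasts of φ.
* **Epistasis decompositions** — RMS local epistatic coefficients and
  mutational effects; exact orthogonal decomposition of phenotypic variance
  by interaction order, by site subset U (via the projections P_U), and
  site/pair summary tables.
* **Diffusion-axis visualization** — a reversible weak-mutation
  substitution chain Q(i,j) = S/(1−e^(−S)), S = c·Δf, with stationary
  distribution π ∝ e^(cf); its rescaled subdominant eigenvectors embed
  genotypes so squared distances approximate evolutionary commute times
  H(i,j) + H(j,i).
* **Thermodynamic Shine–Dalgarno model** — expected log(GFP) as
  register-summed Boltzmann occupancy of the 16S rRNA footprint,
  μ = log(β₀ + Σ_p e^(−E_p/RT)) with an additive 8-position binding-energy
  matrix (27 free parameters), fitted by maximum likelihood.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate a landscape from a variance-component prior, refit it from noisy
partial observations, and embed it:

```bash
gpmaps simulate --alphabet dna --length 3 --lambdas 0,1,0.1,0.01 \
    --fraction-observed 0.8 --noise-var 0.01 --seed 1 --outdir sim
gpmaps vc-fit --alphabet dna --length 3 --data sim/observations.csv --outdir vc
gpmaps visualize --alphabet dna --length 3 --landscape vc/posterior_mean.csv \
    --target-mean 0.5 --outdir viz
```

The `vc-fit` log prints the kernel-aligned variance components, here

```
lambdas: [0.     0.6814 0.1193 0.0073]
```

— the prior variance per interaction order (order 0 is fixed at zero;
compare the generating values 1, 0.1, 0.01: most signal is additive, a
little pairwise). `visualize` calibrates the selection scale so the
stationary mean phenotype hits the target and prints

```
calibrated c = 4.04105
relaxation times: [0.6262 0.4538 0.41  ]
```

— c is the scaled selection coefficient per unit phenotype, and each
relaxation time −1/λ_k exceeding the neutral value 1/4 marks a slow
evolutionary barrier; `viz/nodes.csv` holds the diffusion-axis coordinates
and stationary probabilities per genotype, with a static plot in
`viz/embedding.png`.

The same steps are available as a library (`gpmaps.sample_vc_landscape`,
`gpmaps.vc_regression`, `gpmaps.diffusion_axes`, ...), plus
`gpmaps.mei`, the `seqdeft` commands/functions for count data, and
`thermo-fit`/`thermo-predict` for the occupancy model. A minimal MEI call:

```python
>>> import gpmaps
>>> space = gpmaps.SequenceSpace("01", 2)
>>> data = gpmaps.ObservedData(space, [0, 1, 2], [0.0, 1.0, 1.0])
>>> gpmaps.mei(data, P=2).mean
array([0., 1., 1., 2.])
```

— observing three corners of the binary square forces the fourth to the
additive completion (the single epistatic coefficient is driven to zero).

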