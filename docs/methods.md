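# Methods

`gpmaps` infers, summarizes and visualizes complete genotype–phenotype
maps: functions assigning a scalar phenotype to every length-ℓ sequence
over an α-letter alphabet, represented as vectors of length α^ℓ indexed by
a mixed-radix encoding (leftmost site most significant, alphabet order as
configured; DNA `ACGT`, RNA `ACGU`, protein alphabetical).

## Epistasis measures

Two complementary summaries are implemented.

**Local epistatic coefficients.** The classical coefficient
ε = (f_aBC − f_ABC) − (f_abC − f_AbC) generalizes to the P-th order finite
difference of f over a 2^P sub-hypercube (one P-subset of sites, one
unordered allele pair per chosen site, one background elsewhere). The sum
of squared coefficients is the quadratic form fᵀΔ(P)f; the number of
coefficients is s = C(ℓ,P)·(α(α−1)/2)^P·α^(ℓ−P), and the reported
statistic is the root mean square √(fᵀΔ(P)f/s), in phenotype units,
compared against the RMS single-mutation effect over Hamming edges.
Summing the rank-one row contributions factor-by-factor gives
Δ(P) = Σ_{|T|=P} ⊗_p (αI−J if p∈T else I), hence Δ(P) has eigenvalue
α^P·C(k,P) on the order-k interaction subspace; this exact spectral form
is what the operator uses, and the test suite validates it against
brute-force row enumeration on small spaces.

**Variance components.** f decomposes orthogonally (under the uniform
measure on genotypes) across interaction orders, f = Σ_k P_k f, and more
finely across site subsets U, with
P_U(x,x′) = α^(−ℓ)·Π_{p∈U}[(α−1) if x_p = x′_p else −1]
(a Kronecker product of centered/averaging α×α factors). Variance masses
v_U = ‖P_U f‖²/α^ℓ aggregate exactly: Σ_{|U|=k} v_U = v_k and
Σ_{k≥1} v_k = Var(f). Site and pair tables report percentages of total
variance; the higher-order pair table is additionally reported as a
fraction of the total order-≥3 mass, since both normalizations are in use
and column names make the choice explicit. Full subset enumeration is
capped at ℓ ≤ 12 (4096 subsets).

## Matrix-free computation

No α^ℓ × α^ℓ matrix is ever formed. The Hamming-graph Laplacian L is
applied in O(ℓα^ℓ) through the tensor view of f (axis sums), and has
eigenvalue αk on the order-k subspace. Every Hamming-distance-based
operator (P_k, kernels K, Δ(P)) is a degree-ℓ polynomial in L; P_k is
applied as the Lagrange selection product Π_{j≠k}(L − αj)/(α(k−j)) —
ℓ Laplacian products per application, numerically stable because each
factor is applied sequentially rather than through expanded polynomial
coefficients. Subset projections use the Kronecker (axis-by-axis) route.
Kernel distance profiles use the closed form
P_k(d) = α^(−ℓ) Σ_q (−1)^q (α−1)^(k−q) C(d,q) C(ℓ−d,k−q).
Linear systems are solved with conjugate gradients (relative-residual
tolerance 1e-8 for covariance solves, 1e-10 for interpolation; max
iterations 10√n; non-convergence raises rather than returning silently,
which is also how singular systems from improper priors surface). All
operator applications are tested against dense materializations at 1e-10
on spaces up to 4096 genotypes.

## Gaussian-process inference

Measurements y on a subset x of genotypes carry known Gaussian noise
variances σ_x². Two prior families over f are supported:

* **Δ(P) precision priors** C = (a/s)Δ(P): improper — interactions of
  order < P are unpenalized (null-space dimension Σ_{k<P} C(ℓ,k)(α−1)^k,
  which the data must pin down; the fit refuses fewer observations than
  that). With σ_x² = 0 the posterior mean is the exact constrained
  minimizer of fᵀΔ(P)f subject to f_x = y — minimum-epistasis
  interpolation — and is independent of a; the posterior covariance scales
  as s/a. With noise the posterior solves
  ((a/s)Δ + RᵀD⁻¹R)f̂ = RᵀD⁻¹y; `mei()` then defaults to a = s, i.e. unit
  weight on the mean squared epistatic coefficient against the
  noise-normalized residuals, a scale the user can override.
  Mixed zero/positive noise variances are rejected rather than guessed at.

* **Variance-component priors** K = Σ_k λ_k P_k (λ_k ≥ 0): proper, with
  prior covariance depending only on Hamming distance. The posterior mean
  is f̂ = ȳ + K_{·x}(K_xx + D)⁻¹(y − ȳ) — y is centered by its
  inverse-variance-weighted mean before fitting and the mean restored
  afterward, so the improper flat mean is never conflated with λ_0.
  Contrast variances use Var(wᵀf) = wᵀKw − vᵀ(K_xx+D)⁻¹v with v = (Kw)_x,
  one CG solve per contrast (negative round-off clamped at zero).

**Kernel alignment.** λ is estimated by matching the prior's distance
profile to the empirical distance covariance: for each Hamming distance d,
c_d is the mean of (y_i−ȳ)(y_j−ȳ) over observed pairs (exact all-pairs up
to 20,000 observations, a seeded pair subsample beyond). The d = 0 class
estimates the signal variance, so the mean known noise variance is
subtracted there (flagged in the output). λ̂ minimizes
Σ_d n_d (c_d − Σ_{k≥1} λ_k P_k(d))² under λ ≥ 0, a small nonnegative
weighted least-squares problem solved by an active-set method
(deterministic); λ_0 is fixed at zero because alignment is done on
centered covariances. An additive-only fit (orders truncated at 1) serves
as a baseline model.

**Evaluation.** Held-out R² and interval calibration: coverage at level q
is the fraction of test measurements within f̂ ± z_q·√(posterior variance
+ test noise variance), reported at q ∈ {0.5, 0.8, 0.9, 0.95, 0.99}.

## Sequence density estimation

For counts N_i of natural sequences (N_T total), the distribution
π_i = e^(−φ_i)/Σ_j e^(−φ_j) is estimated by combining a multinomial
likelihood with the improper prior log p(φ|a) ∝ −(a/2s)·φᵀΔ(P)φ (default
P = 2). The negative log posterior
(a/2s)φᵀΔ(P)φ + Σ_i N_i φ_i + N_T log Σ_j e^(−φ_j)
is convex and minimized by L-BFGS with log-sum-exp stabilization, warm
started from the a = ∞ solution and continued along the grid from large to
small a. The limits are computed exactly: a = 0 gives empirical
frequencies (zero-count sequences get π = 0, flagged); a = ∞ gives the
maximum-entropy model in the Δ(P) null space — for P = 2 the
independent-sites model in closed form (product of observed site
marginals), for P > 2 by likelihood maximization constrained to the null
space via projected gradients.

The strength a is chosen by k-fold cross-validation (default 5) over a
24-point log-spaced grid, with the two limits always included as reference
rows. Folds split individual observation draws, not genotypes, matching
the multinomial sampling model. The grid range is auto-scaled so the top
penalty curvature (a/s)·α^P·C(ℓ,P) spans 10⁻³–10³ times the likelihood
curvature scale N_T — wide enough that the endpoints behave like the
limiting models; this bracketing rule is this package's choice. Held-out
sequences with π̂ = 0 (possible only at a = 0) score −∞, not an exception.

Uncertainty for linear functionals wᵀφ uses the Laplace approximation:
Var = wᵀH⁻¹w with H = (a/s)Δ(P) + N_T(diag(π̂) − π̂π̂ᵀ) at the MAP, solved
by CG. H annihilates constant fields — the gauge direction of φ — so only
contrasts (Σw = 0) are gauge-invariant; other weight vectors trigger a
warning and have their constant component projected out.

## Evolutionary visualization

Weak-mutation (origin–fixation) dynamics: substitution rate
Q(i,j) = M(i,j)·S/(1−e^(−S)) for neighbors, S = c(f(j)−f(i)), diagonal
minus the row sum. The S/(1−e^(−S)) form is forced by three requirements:
positivity of rates, the neutral limit Q → M at S = 0, and detailed
balance Q(i,j)/Q(j,i) = e^S with the stationary distribution
π_i ∝ π_M(i)e^(cf(i)). M defaults to 1 on every edge (time in units of
inverse mutation rate, uniform π_M); a symmetric per-edge rate matrix is
accepted. Setting f = log π* with c = 1 makes the chain stationary at an
estimated sequence distribution π* exactly. Otherwise c is calibrated by
bracketed root finding on the strictly increasing map c ↦ E_π[f], which
can reach any target in (mean(f), max(f)).

Diffusion axes are computed from the symmetrized generator
D_π^{1/2} Q D_π^{−1/2} (Lanczos with a seeded start vector; dense solve on
request for small chains). The trivial zero eigenvalue is discarded; each
right eigenvector r_a is normalized to r_aᵀD_π r_a = 1, scaled by
(−λ_a)^{−1/2}, and sign-fixed (largest-magnitude coordinate positive). At
full rank, squared embedding distances equal commute times
H(i,j) + H(j,i) exactly — verified against hitting times obtained by
direct linear solves with an absorbing state — and truncations
under-approximate them. Relaxation times −1/λ_a flag axes decaying more
slowly than neutral (1/α for uniform alphabets with unit rates). Tied
eigenvalues are flagged: axes within a tie are an arbitrary orthogonal
basis of their eigenspace.

## Thermodynamic model of Shine–Dalgarno function

Expected log(GFP) of a variable 9-nt ribosome binding region is modeled as
μ(x) = log(β₀ + Σ_p e^(−E_p(x)/RT)) under the low-occupancy approximation,
where the sum runs over all 8-nt windows (registers) of the sequence
extended by fixed flanks (CCG upstream, UGAG downstream — 9 registers for
the default configuration, a configurable subset otherwise), and
E_p = θ₀ + Σ_i ΔΔG[i, base at footprint position i]. Rows of ΔΔG sum to
zero (gauge fixed; 8·(α−1) + 3 = 27 free parameters for RNA including θ₀,
β₀ and an extra log-scale noise variance σ²); RT = 1.9872×10⁻³·310
kcal/mol. θ₀ is a single composite offset absorbing the mean binding
energy and the bound-state translation rate; predictions depend only on
the composite, so it is not decomposed. For export, the energy matrix can
be shifted so the strongest binder scores zero.

Fitting maximizes a Gaussian likelihood on the log scale (per-sequence
known variance plus σ², both kept positive by softplus transforms) with
Adam at learning rate 0.02 in 1500-iteration blocks until the gradient
norm converges (capped at 12,000 iterations). The register sum makes the
likelihood approximately invariant under shifting the whole energy matrix
by one footprint position, creating phase-shifted local optima; after the
base fit, re-optimizations started from ±1-row-shifted solutions are run
and the best likelihood kept — the analogue of column-shift moves in motif
discovery. Refits from different seeds then agree in μ to r > 0.999 even
where raw parameters differ within the gauge.

## Synthetic data

All tests and the acceptance script run on generated data; every generator
takes an explicit seed and is bit-reproducible.

* Landscapes are drawn from variance-component priors by projection
  coloring, f = Σ_k √λ_k P_k z (Cov(f) = Σ λ_k P_k exactly). Study-scale
  experiments use a decaying spectrum — order fractions
  (0.60, 0.25, 0.10, 0.04, 0.01) of unit total variance on the 4⁵ DNA
  space — reflecting the empirically typical dominance of additive and
  pairwise variance in regulatory-sequence maps, with measurement noise
  variance 0.058, the pooled replicate variance typical of log-fluorescence
  sort-seq readouts.
* Observations are uniform genotype subsamples plus Gaussian noise with
  truthfully recorded variance; train/test splits are disjoint.
* Count data are single multinomial draws from a specified π; the
  pairwise-structured test distribution uses π ∝ e^(−φ) with φ drawn from
  a pure order-2 prior.
* Thermodynamic training data are uniformly drawn distinct sequences with
  μ computed under known parameters plus log-scale noise.

What the generators do not emulate: the read-level MAVE generative process
(sorting bins, sequencing counts), phylogenetic relatedness among natural
sequences (counts are treated as i.i.d. draws), genuinely non-Gaussian
measurement error, and global nonlinearities between the modeled latent
phenotype and the measurement scale. Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not robustness
to these real-data complications.

## Numerical choices and limitations

* Space budget 4¹² genotypes for vectors; dense oracles only ≤ 4096;
  full-spectrum embeddings and hitting-time oracles ≤ 256 states.
* CG failure and eigensolver non-convergence raise; posterior variances
  are clamped at zero against round-off; log-sum-exp guards all
  exponentials (occupancy sums, SeqDEFT normalization, stationary
  distributions via max-shift).
* Kernel-alignment estimates are point estimates: predictive intervals
  inherit no hyperparameter uncertainty, so slight undercoverage can occur
  on unlucky draws.
* Ties in eigenvalues (e.g. neutral chains) make individual axes
  non-unique; only the spanned eigenspace is meaningful there.
* Duplicate measurement rows are an error unless replicate merging is
  requested (means averaged, variances pooled as σ²/n); pooled replicate
  variance is Σ SS_i / Σ(n_i − 1) over genotypes with n_i ≥ 2.
* DNA and RNA are distinct alphabets; U/T conversion happens only under an
  explicit flag.
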