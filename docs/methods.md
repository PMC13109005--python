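# Methods

This document describes the statistical models implemented in
`multistudyfa`, the assumptions each one makes, the numerical choices taken
where the literature leaves details open, and the known limitations.

## Setting and notation

Data are `S` studies measuring the same `P` variables: study `s` is an
`N_s × P` matrix `Y_s`, rows independent. All estimators decompose each
study's covariance into some subset of

* a **common** low-rank part `Σ_Φ = Φ V Φ'` shared by all studies
  (`Φ` is `P × K`),
* a **study-specific** low-rank part `Σ_{Λ_s} = Λ_s Λ_s'`
  (`Λ_s` is `P × J_s`), and
* a diagonal **idiosyncratic** part `Ψ_s`.

All models assume continuous data, centred within study (the CLI and the
examples centre by default; MOM-SS is the exception because it models
means explicitly). Factors and residuals are Gaussian.

## Estimators

### Stack FA

A single Bayesian factor model fitted to the row-wise concatenation of all
studies: `Σ = Φ Φ' + Ψ`. The multiplicative gamma process shrinkage (MGPS)
prior on `Φ` lets an over-specified `K` collapse to the supported rank.
Assumes no study-specific structure at all; anything study-specific is
absorbed into `Φ` or `Ψ`.

### Ind FA

The same factor model fitted independently per study:
`Σ_s = Λ_s Λ_s' + Ψ_s`. Assumes no sharing; the common structure is
re-estimated `S` times.

### BMSFA (Bayesian multi-study factor analysis)

`Σ_s = Φ Φ' + Λ_s Λ_s' + Ψ_s`, MGPS priors on `Φ` and each `Λ_s`,
conjugate Gibbs updates throughout. The common/specific split is
identified only up to shared directions: a factor present in every study
can migrate between `Φ` and the `Λ_s` (information-sharing
non-identifiability); post-hoc rank selection on the posterior-mean
`Σ_Φ` mitigates this.

### PFA (perturbed factor analysis)

`Q_s y = Φ f + ε` with per-study perturbation matrices `Q_s ≈ I`
(matrix-normal prior centred at `I` with scale `α`, `Q_1 = I` as the
reference-study convention). Marginally
`Σ_s = Q_s^{-1} (Φ V Φ' + Ψ) Q_s^{-T}`.

Two numerical points deserve emphasis:

* **Jacobian-corrected perturbation update.** Because the model specifies
  the density of `Q_s y`, the likelihood of the observed `y` carries a
  `|det Q_s|^{N_s}` factor. The naive Gaussian regression conditional for
  a row of `Q_s` omits it and the resulting pseudo-posterior collapses
  `Q_s → 0`. The sampler here exploits the fact that `det Q_s` is linear
  in any one row: the row conditional factorizes into an exactly Gaussian
  component orthogonal to the cofactor direction and a scalar density
  `|t|^n N(t; m, s²)` along it, which is sampled by independence
  Metropolis from a Laplace approximation at its mode (acceptance is
  near 1 in practice).
* **Partial identifiability of `Q_s`.** With Gaussian data the likelihood
  sees `Q_s` only through `Σ_s`, so `Q_s` is identified only up to the
  `Σ_1`-orthogonal group (`P(P−1)/2` directions); the prior centred at
  `I` resolves the remainder. Functionals of `Σ_s` (and the whitening
  relation `Q_s Σ_s Q_s' = Σ_1`) are identified; individual entries of
  `Q_s` are not fully.

Factor dimension uses MGPS-style adaptive truncation: columns whose
loadings fall below a tolerance are pruned during burn-in, and the modal
retained dimension is reported.

### MOM-SS (non-local spike-and-slab)

An EM algorithm for `y = α_s + B x + Φ f + ε` with per-study intercepts
`α_s`, optional observed covariates `x` with shared coefficients `B`, and
a product non-local (pMoM) spike-and-slab prior on loadings — the slab has
zero density at the origin, which separates genuinely non-zero loadings
from noise. The EM objective (marginal log posterior) is checked to be
monotone at every iteration. Two starts (±varimax of a spectral
initialization) guard against local maxima; factors with no loading above
an inclusion threshold of 0.05 are dropped.

### SUFA (subspace factor analysis)

`Σ_s = Φ (I + A_s A_s') Φ' + Ψ` with `A_s` a `K × J_s` matrix: the
study-specific part lives inside the span of the shared loadings, which
makes the common/specific split identifiable when `Σ J_s ≤ K`. A
Dirichlet–Laplace prior shrinks `Φ`; `Ψ` is updated with an adaptive
random-walk Metropolis step on `log ψ_p` tuned to 30–45 % acceptance
during burn-in. `K` can be chosen upstream by the cumulative
squared-singular-value rule (`sufa_select_k`), and `J_s` defaults to
`max(1, K // S)`.

### CAVI (coordinate-ascent variational inference)

A mean-field variational approximation to the BMSFA-style model with
Gaussian factors and loadings and conjugate exponential-family updates.
Every sweep must increase the evidence lower bound; a decrease raises an
error rather than a warning, because it can only come from an
implementation bug. Fast (seconds at the benchmark sizes) but known to
underestimate posterior spread; point estimates of covariances are the
intended use. `J_s` is floored at 2 (a warning is emitted) because the
mean-field updates degenerate at `J_s = 1`.

### BLAST (spectral shared-subspace estimation)

A deterministic four-stage spectral method: per-study spectral
decompositions, a shared-subspace vote in which a direction is accepted as
shared when its alignment across studies exceeds a membership threshold
`1 − 1/(2S)`, rank selection by an eigenvalue-gap rule, and a final
least-squares refit of shared and specific loadings. No MCMC; determinism
makes it the natural default for large `P`.

### Tetris (combinatorial factor sharing)

Loadings are global columns; a binary sharing matrix `𝒯` (`S × K`) says
which studies use which column, with a Beta–Bernoulli prior
(`α_𝒯 = 1.25 S`, `β_𝒯 = 1` by default). The sampler marginalizes factors
in the Metropolis ratio for `𝒯` entries (integrated Gaussian likelihood
via Woodbury). The reported `𝒯` is chosen by `choose_T`: the posterior
draw whose Hamming neighbourhood contains the most posterior mass
(earliest draw on ties), after left-order canonicalization.
`classify_factors` labels columns common (all ones), partially shared,
specific, or empty. A caveat shared with all discrete-structure samplers:
a single factor can split into parallel low-mass duplicate columns
without likelihood penalty, so column counts are less stable than the
implied covariances.

## Shrinkage priors

* **MGPS** — `ω_{pk} ~ Ga(κ/2, κ/2)` local precisions (κ = 3) times
  cumulative-product column precisions `θ_k = Π_{l≤k} δ_l`,
  `δ_1 ~ Ga(2.1, 1)`, `δ_{l>1} ~ Ga(3.1, 1)`. Conjugate updates; columns
  are increasingly shrunk, enabling adaptive truncation.
* **Dirichlet–Laplace** — per-row global–local decomposition with
  Dirichlet-distributed local scales (a = 0.5) and inverse-Gaussian /
  generalized-inverse-Gaussian conditional updates.
* **Non-local spike-and-slab (pMoM)** — mixture with a quadratic-tilted
  Gaussian slab (zero density at the origin) and a point-mass-like spike;
  used by MOM-SS in EM form.
* **Two-parameter IBP** — prior over binary sharing structures with
  `E[#columns] = α Σ_{s=1}^{S} β/(β+s−1)`; used in Beta–Bernoulli
  finite-truncation form by Tetris.

## Post-processing

* **Orthogonal Procrustes alignment** resolves rotation/sign/label
  switching across MCMC draws by rotating each draw to a reference.
* **SD loadings**: rank-`k` eigendecomposition of a posterior-mean
  covariance (best rank-`k` approximation, Eckart–Young).
* **Varimax** rotation for interpretability.
* **EVD factor-number rule**: retain eigenvalues explaining at least a
  threshold share (default 5 %) of total variance. Rotation-invariant.

## Simulation scenarios

Six generators mirror common multi-study regimes at fixed published
sizes (overridable): (1) small perturbations of a shared structure,
(2) batch effects as study intercepts plus shared covariate effects,
(3) study-specific loadings inside the shared span, (4) strong dense
study-specific structure alongside a weak shared part, (5) combinatorial
partial sharing, and (6) a high-dimensional (`P = 1060`) sparse version
of (5). Loadings are sparse signed-uniform (exact zero fractions,
non-zeros `±U(0.6, 1)`), which mimics the block-sparse loadings seen in
omics applications while keeping every scenario's true `Σ_Φ`, `Σ_{Λ_s}`
and marginal covariances available in closed form for evaluation.

Realism caveats: Gaussian factors and residuals, exact sparsity, and
homogeneous noise scales are idealizations; real nutrition/expression
data have heavier tails and correlated residuals. The generators are
benchmarks for estimator behaviour, not data emulators.

## Evaluation

* **RV coefficient** between estimated and true covariances (rotation
  invariant, in [0, 1]).
* **Frobenius distance** between covariances.
* **Bartlett factor scores** (GLS given loadings and residual variances)
  for out-of-sample reconstruction; `prediction_mse` splits each study,
  fits on the train part, and reports reconstruction error on the test
  part.

## Numerical choices and limitations

* MCMC defaults (10 000 iterations / 8 000 burn-in in the CLI; 3 000 /
  2 000 in the benchmark suites) are desk-scale; production analyses
  should run longer chains and check convergence.
* All samplers are validated by Geweke-style two-simulator tests at toy
  dimensions. Statistics used there are chosen to have finite prior
  variance (e.g. `log φ²` rather than `φ²` under MGPS, whose implied
  inverse-gamma tails have infinite variance). The PFA check runs at
  `S = 1`: for `S ≥ 2` the joint prior over `(Ψ, Q_s, Y)` has tails that
  overflow double precision (diffuse inverse-gamma draws of `ψ` inflate
  `Y` and the `Q` conditionals geometrically), so the two-simulator
  comparison is not representable in float64 — a limitation of the test,
  not a validated property of the kernel at `S ≥ 2`.
* Tetris is combinatorial in `𝒯` and is the slowest estimator by a wide
  margin; it is excluded from the benchmark-scale acceptance runs.
* Uncertainty summaries are draw-based for the Gibbs samplers, absent for
  BLAST (deterministic) and point-valued for EM/VI methods; CAVI
  intervals in particular should not be interpreted as calibrated.
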