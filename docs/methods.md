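# Methods

## Design and notation

A PB-CRT observes continuous outcomes `Y_ijk` for individual `k` in period
`j ∈ {0,1}` of cluster `i ∈ 1..I`, with cluster-period cell sizes `K_ij`.
All clusters are untreated at baseline (`j=0`); clusters randomized to
sequence `S_i = 1` are treated at follow-up, so the treatment indicator is
`X_ij = S_i·j`. Estimands are defined on follow-up potential outcomes under
a cluster superpopulation: the individual-average effect (iATE) weights
clusters by size, the cluster-average effect (cATE) weights them equally.
They coincide unless cluster size moderates the treatment effect
(informative cluster size, ICS).

## Generative model

`simulator` draws each cluster from a discrete set of subpopulations `u`
with probabilities `P(u)`; a subpopulation fixes a Poisson mean for the
cluster-period size `K_i` (equal across periods within a cluster) and a
treatment effect `δ_u`. Outcomes follow

    Y_ijk = μ + X_ij δ_u + Φ1·j + α_i + γ_ij + e_ijk,
    α_i ~ N(0, τα²),  γ_ij ~ N(0, τγ²),  e_ijk ~ N(0, σw²),

with both potential arms sharing the latent draws, so the per-cluster
potential contrast is exactly `δ_u` (`true_effect_surface`). Defaults are
the study conditions: I = 10, μ = 1, Φ1 = 0.2, τα² = 0.053, τγ² = 0.013,
σw² = 1 (within-period ICC ≈ 0.062, between-period ≈ 0.050, cluster
auto-correlation 0.803), subpopulations (0.5, Poisson(20), δ1) and
(0.5, Poisson(100), δ2) with δ = (0.2, 0.5) in the informative-size
condition and δ = (0.35, 0.35) in the homogeneous one. The implied
estimands are iATE = (10·δ1 + 50·δ2)/60 (0.45 under ICS) and
cATE = (δ1 + δ2)/2 = 0.35.

Implementation choices: subpopulation allocation is exact when `I·P(u)` is
integral (half/half at the default) and multinomial otherwise; Poisson
draws of 0 are redrawn (probability ≈ 2e-9 at mean 20); randomization is
simple and unstratified by default (`stratify=True` balances within
subpopulations); exactly `I/2` clusters are treated. One
`numpy.random.Generator` seeded per trial makes trials bitwise
reproducible; the simulation engine spawns per-replicate seeds from the
master seed with `SeedSequence.spawn`, so summaries are identical for any
`n_jobs`.

What the generator does **not** emulate: non-normal outcomes, within-cluster
period-size changes, missing data, covariates, more than two subpopulations'
worth of effect heterogeneity structure (any finite list is supported, but
effects vary only through `u`). Passing tests therefore demonstrate
correctness of the estimators and calibration of the inference under this
Gaussian, complete-data world, not robustness to real-data pathologies.

## Estimators

All estimators consume per-cluster sufficient statistics (cell sizes, cell
sums, sums of squares), which makes leave-one-cluster-out refits cheap.

- **IEE**: pooled follow-up mean difference between arms; identical to the
  OLS treatment coefficient of the independence model with treatment and
  period effects (the baseline period contributes nothing).
- **IEEw**: arm means of cluster follow-up means.
- **FE**: two-way fixed-effects (cluster + period dummies) OLS coefficient,
  computed by the general harmonic-weighted difference-in-differences
  formula valid for `K_i0 ≠ K_i1`; with equal cells it reduces to the
  within-arm DiD of summed outcomes.
- **FEw**: DiD on cluster-period cell means (valid for unequal cells;
  invariant to shifting all baseline outcomes).
- **EME/NEME (and weighted variants)**: GLS
  `θ̂ = (Σ Z_i'W_i⁻¹Z_i)⁻¹ Σ Z_i'W_i⁻¹Y_i` with `W_i = w_i R_i`,
  `w_i = K_i` for the weighted fits. With equal cells the covariance block
  is `R = I σw² + (I₂⊗J_K) t_w + ((J₂−I₂)⊗J_K) t_b` (`t_w = τα²(+τγ²)`,
  `t_b = τα²`); its inverse shares the three-constant structure with
  constants derived from the eigenvalues `σw²` and `σw² + K t_w ± K t_b`,
  so the normal equations reduce to O(I) scalar arithmetic. A dense
  per-cluster solve handles `K_i0 ≠ K_i1` for the unweighted fits; the
  weighted GLS is refused there (inverse cluster-period weights are only
  defined cluster-wise) with a pointer to IEEw/FEw.

Numerical policy: 3×3 normal equations are solved directly, never by
explicit inversion of larger systems; condition numbers above 1e10 warn and
above 1e15 raise. Degenerate one-cluster arms are allowed for point
estimation; the jackknife refuses them.

## Variance components (REML)

The restricted likelihood of the exchangeable (τα², σw²) or
nested-exchangeable (τα², τγ², σw²) model is profiled over σw² using
variance ratios φ = τ/σw²; one profiled evaluation costs O(I). Ratios are
optimized on the log scale: a bounded 1-d search for the exchangeable
model, Nelder-Mead from three fixed starts for the nested model, always
compared against the boundary candidates with each ratio pinned to zero
(log-ratio bounds [−18, 6]; ratios below e⁻¹² are projected to an exact
zero and flagged as boundary estimates rather than errors). The reported
log-likelihood is the standard REML criterion
`−½[(n−p)log 2π + log|V| + log|Z'V⁻¹Z| + r'V⁻¹r]` at the optimum, checked
in tests against a dense multivariate-normal oracle.

The weighted mixed-model fits (EMEw/NEMEw) plug the **unweighted** REML
components into the weighted estimating equation. This is a deliberate
design choice: the weighted estimating equation defines the estimator, and
the variance components are nuisance inputs whose probability limit — not
their weighting — drives the estimand weights. A weighted pseudo-likelihood
would shift the fitted ICC somewhat and with it the small residual bias of
EMEw; this sensitivity is the main caveat when comparing against analyses
run with weighted mixed-model software.

## Inference

- Model-based variances: classical `σ̂²(Z'Z)⁻¹` treatment element for
  IEE/FE (individual-level designs), the cell-mean regression's classical
  variance for IEEw/FEw, and the delta-element of `(Σ Z_i'W_i⁻¹Z_i)⁻¹` for
  the GLS fits. For the weighted GLS fits this last quantity is known to be
  badly calibrated (it treats `K_i R_i` as the outcome covariance); it is
  reported for completeness, and the simulations show its coverage
  collapsing — which is precisely why the jackknife is the recommended
  inference.
- Jackknife: `(I−1)/I Σ (δ̂_(−i) − c)²` over leave-one-cluster-out refits of
  the **entire** procedure, REML included. Centering `c` defaults to the
  mean of the leave-one-out estimates (`center="full"` switches to the
  full-sample estimate); both conventions exist in the literature.
- Wald intervals use t quantiles with I−2 degrees of freedom (clusters
  minus the two treatment-level parameters); `dist="normal"` switches to
  normal quantiles. Requires I ≥ 3.

## Estimands, limits, and weights

`estimands` evaluates each estimator's probability limit over the discrete
subpopulation distribution: `E[Kδ]/E[K]` (IEE/FE), `E[δ]` (IEEw/FEw), and
`E[g(K)Kδ]/E[g(K)K]` resp. `E[g(K)δ]/E[g(K)]` for the mixed models with

    g_EME(K)  = (1+(K−1)ρ)/(1+(2K−1)ρ),
    g_NEME(K) = (1+(K−1)ρwp)/((1+(K−1)ρwp)² − K²ρbp²).

By default the subpopulation Poisson means are plugged into `g` (the
conventional evaluation); `size_dist="poisson"` instead integrates over the
zero-truncated Poisson the simulator draws from — the difference is below
0.01 at the study sizes but the option exists because the limits are
nonlinear in K. At the study conditions the NEMEw limit is ≈ 0.296, i.e.
≈ −15.4% relative to the cATE, while the EMEw limit is ≈ −4%: the
exchangeable weighted analysis is intrinsically far more bias-resistant.

The estimand weights `λ_u = g(K_u)/E[g(K)]` are normalized to mean 1 by
construction. The ICC maximizing the EMEw weight *gap* `g(K1) − g(K2)` has
the closed form `ρ* = 1/(1+2√(K1K2))`, verified against a grid maximizer in
tests (the gap of the normalized λ has a slightly different maximizer; the
unnormalized gap is the quantity with the closed form). The bias-maximizing
sampling probability is computed as `P* = g(K2)/(g(K1)+g(K2))`, which is
close to but not exactly one half (0.436 at sizes 20/100); an exact grid
maximization of the cATE bias over P gives `√g2/(√g1+√g2)` ≈ 0.468 — both
are "≈ 0.5" at the resolution the quantity is used.

## Monte-Carlo engine

`run_scenario` aggregates per-estimator mean estimate, percent relative
bias and RMSE against both estimands, Monte-Carlo variance, mean
model-based and jackknife variances, coverage of the 95% Wald interval
against both estimands, and power, each with Monte-Carlo standard errors.
Coverage is reported against *both* estimands for every estimator; headline
claims use each estimator's natural target. Power under a zero-effect
configuration is the type-I error rate. Per-method failures inside a
replicate are recorded, never fatal; a method failing in more than 5% of
replicates flags the summary.

Problem sizes used by the shipped tests and the acceptance script: 1000
replicates of the I = 10 study conditions (the jackknife run refits
8 estimators on 11 datasets per replicate), ten I = 2000 trials for the
large-sample bridge between the GLS fits and their analytic limits, and a
single I = 500 trial for REML parameter recovery. Monte-Carlo assertions
use 3-standard-error bands throughout.

## Known limitations

- Two periods only; cross-sectional sampling; continuous outcomes; no
  covariate adjustment or baseline-constrained ANCOVA variant.
- No sandwich or bias-reduced-linearization variances; the jackknife is the
  robust option offered.
- REML assumes equal within-cluster cell sizes (as does the weighted GLS);
  unweighted GLS alone handles unequal cells, via dense per-cluster solves.
- The EMEw/NEMEw component plug-in differs from weighted pseudo-likelihood
  software, as discussed above; expect small differences in the fitted ICC
  and hence in the EMEw residual bias.
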