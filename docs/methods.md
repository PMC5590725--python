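# Methods

## Models

Both methods assume continuous data whose groups (known or latent) follow
multivariate normal distributions N(μ, Ω⁻¹) with sparse precision matrices.
Conditional-independence structure is read off the zeros of Ω; edge
strength is reported as the partial correlation
ρ_{jj'} = −Ω_{jj'}/√(Ω_{jj}Ω_{j'j'}).  Neither model is causal: edges are
conditional associations and may reflect, e.g., unobserved co-regulation.

### Two-sample network test

The null hypothesis is Ω₁ = Ω₂.  A single run:

1. Each group is standardized per variable and split 50/50 at random.
2. On the first halves, sparsity patterns A₁, A₂ (per group) and A₀
   (pooled) are estimated by graphical lasso, with λ chosen per fit by BIC
   over a 20-point log-spaced grid from λ_max (the fully-diagonal point)
   down to λ_max/20.
3. On the held-out halves, means fixed at zero and each half rescaled to
   exact unit second moments, maximum-likelihood precision matrices are
   fitted restricted to A₁, A₂ and (pooled) A₀, and the statistic
   T = 2[ℓ₁ + ℓ₂ − ℓ₀] is formed.  T may be negative in finite samples
   (the three patterns are not nested) and is not clipped.
4. Asymptotically T is a quadratic form in the two groups' score vectors,
   hence distributed as Σᵢ wᵢ χ²₁.  The weights are eigenvalues of the
   score-covariance-weighted difference of projected inverse Fisher
   informations, all evaluated at the joint restricted MLE.  Because the
   held-out halves are standardized exactly, the diagonal score
   coordinates vanish; the score covariance is the delta-method covariance
   of correlation fluctuations, u~_{jk} = u_{jk} − ρ_{jk}(u_{jj}+u_{kk}),
   which for p = 2 reproduces the classical Var(r) = (1−ρ²)²/n.  With
   saturated patterns the weights reduce to p(p−1)/2 ones.  P-values are
   computed by Monte Carlo over 10⁵ mixture draws (a fixed internal seed
   makes them deterministic); a parametric bootstrap from the fitted joint
   null (active sets held fixed, add-one rule) is available as the
   reference null and agrees with the weighted-χ² path within Monte Carlo
   error on test fixtures.

The multi-split variant repeats this over 50 independent splits and
aggregates with the quantile rule
P = min{1, (1 − log γ_min) · inf_γ min(1, q_γ/γ)}, γ_min = 0.05, evaluated
on a 100-point grid — valid under arbitrary dependence between splits.

Baselines: the classical LRT (centered covariance MLEs, means profiled
out, χ² with p(p+1)/2 df — intentionally anti-conservative when p ≈ n),
its permutation version (999 permutations, add-one rule), and a Fisher-Z
test comparing all p(p−1)/2 partial correlations with standard error
√(1/(n₁−p−1) + 1/(n₂−p−1)) and Bonferroni-corrected minimum P.  The
baselines operate on the data as given (partial correlations are
scale-invariant; the permutation test requires exchangeability, so
group-standardize first when mean/scale differences are possible — the
pairwise driver does this for every test).  Pairwise testing over K groups
applies per-group standardization, runs all K(K−1)/2 tests, adjusts by
Benjamini–Hochberg and masks at 1% FDR by default.

### Penalized mixture of GGMs

The penalized log-likelihood is ℓ(Θ; X) − λ pen(Θ) with
pen(Θ) = Σₖ πₖ^{1/2} Σ_{j≠j'} |Ω_{k;jj'}|/√(Ω_{k;jj}Ω_{k;j'j'}) (ordered
pairs, so each unordered pair counts twice).  The πₖ^{1/2} factor makes
the effective per-cluster regularization track cluster size; the
partial-correlation scaling makes it scale-invariant.  λ is fixed at
λ_uni = √(2 n log p)/2, the universal level motivated by high-dimensional
regression theory via the GGM–regression connection.

EM details:

* E-step in log space (log-sum-exp), responsibilities floored at 1e-12.
* M-step: πₖ and μₖ in closed form; each Ωₖ solves a weighted graphical
  lasso with effective scalar penalty 2λπₖ^{1/2}/nₖ^eff.  The entrywise
  weights 1/√(Ω̂_{jj}Ω̂_{j'j'}) are separable, so the subproblem reduces
  exactly to a scalar-α graphical lasso on the rescaled covariance
  D⁻¹SₖD⁻¹ with D = diag(Ω̂_{jj}^{−1/2}); two reweighting cycles per
  M-step (majorize–minimize style).
* Initialization: k-means (5 restarts), hard labels smoothed 0.9/0.1.
* Monotonicity: the π-coupled penalty and the reweighting make the M-step
  approximate, so after every iteration the penalized log-likelihood is
  evaluated; a non-improving step keeps the previous parameters and stops.
  The recorded trace is therefore non-decreasing by construction.
* Convergence: relative penalized log-likelihood change < 1e-6, max 500
  iterations.
* Empty components (nₖ^eff < p/2) are re-seeded once from the most
  ambiguous samples, then dropped with a warning on a second collapse.

Model selection minimizes BIC(K) = −ℓ + ½log(n)(K−1) + ½log(n)ΣₖDf(k),
Df(k) = p + #{nonzero upper-triangle entries of Ω̂ₖ incl. diagonal}, with
ℓ the unpenalized mixture log-likelihood (standard BIC practice; the
penalized alternative is not used).  Ties go to the smallest K.  Stability
subsampling removes 25% of samples, refits, and reports the mean ± sd ARI
between all pairs of refits on shared samples.

The non-adaptive penalized-mixture baseline runs the same EM with penalty
λ Σₖ Σ_{j≠j'} |Ω_{k;jj'}| (no πₖ^{1/2} factor, no partial-correlation
scaling) at the same λ_uni — isolating the contribution of adaptivity.

## Synthetic data

The generator draws from K-component mixtures with component-specific
sparse precisions, the same family the methods assume.  Defaults, fixed
once: p = 30 variables, K = 9 components, Dirichlet(5) proportions
(unequal cluster sizes), edge density 0.1, partial-correlation magnitudes
uniform in [0.2, 0.5] with random sign, component means drawn isotropically
and rescaled to average pairwise separation 4 (≈ Mahalanobis units, since
implied covariances have unit diagonal).  Precisions are built by placing
the requested partial correlations on a random pattern, damping toward the
diagonal until safely positive definite (the construction fails rather
than deliver magnitudes more than 20% below the request) and rescaling to
a unit-diagonal implied covariance, which leaves partial correlations
unchanged.  Edge perturbations for two-group alternatives remove, flip or
add a stated number of edges and restore positive definiteness by damping
only the changed entries, so the pattern difference is exactly the
selected set.  A multivariate-t family (default 5 df, covariance matched
to the Gaussian case) emulates heavy-tailed data.

What the generator does *not* emulate: real molecular data's non-Gaussian
marginals, batch structure, missingness, measurement error correlated with
abundance, and hub-dominated (scale-free) topologies.  Passing tests
demonstrate correctness of the statistical machinery under the model's own
assumptions, not robustness to these real-data features (the t family
probes tail robustness only).

## Study harnesses and problem sizes

The testing study measures type-I error, power and AUROC per method per
sample size over replicated null/alternative pairs (alternative: 10
perturbed edges at p = 10, edge density 0.25, partial correlations
0.3–0.45); methods whose preconditions fail at a given n (classical LRT
when n ≤ p) are recorded as missing.  The clustering study measures ARI
against the generating labels with K treated as known, over the default
grid n ∈ {450, 900, 1800} (halvings of the K-recovery scale); the
unpenalized Gaussian mixture is recorded as missing when the smallest true
cluster has no more samples than variables.

Default replicate counts in the automated checks are scaled to a desktop
time budget (hundreds of replicates for the cheap single-split size check,
around ten for the multi-split and clustering orderings); binomial
acceptance bands are always computed exactly for the count actually run.
The K-recovery script uses the full 10 replicates at p = 30, n = 1800.

## Numerical choices

* Covariances use 1/n (ML) scaling throughout; only user-facing
  standardization uses the (n−1) denominator.
* Graphical-lasso solves use coordinate descent with duality-gap tolerance
  1e-4 (estimation) or 5e-3 (pattern screening, where only the active set
  is consumed); estimates are symmetrized, thresholded at 1e-8, and
  pattern-enforced to exact zeros.
* The restricted MLE is solved by L-BFGS-B on the free entries with
  analytic gradient Ω⁻¹ − S, Cholesky-guarded against leaving the PD cone;
  closed forms are used for the saturated and empty patterns.
* The Fisher information for the weight construction is assembled via the
  duplication map, ½ Bᵀ(Σ⊗Σ)B — O(p⁴) memory, intended for moderate p
  (the regime the split test targets).
* Degenerate case: when screening removes every off-diagonal direction
  the statistic is identically zero and the P-value is 1.

## Known limitations

* The weighted-χ² null is first-order; with very weak edges near the
  screening threshold, mild miscalibration is possible — the parametric
  bootstrap is the slower, more robust alternative.
* p ≫ 10³ is out of scope (duplication-matrix memory, glasso cost).
* The mixture EM is a local optimizer; k-means initialization plus
  restarts is effective for separated clusters but offers no global
  guarantee.
* Missing values are rejected, not imputed.
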