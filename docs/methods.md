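# Methods

## Model

`stiefnet` models a data set of N symmetric n×n adjacency matrices sharing a
node set as noisy low-rank decompositions

    A(k) = X(k) Diag(λ(k)) X(k)ᵀ + ε(k),        k = 1…N,

where the pattern frame X(k) ∈ V(n,p) = {X : XᵀX = I_p} carries p orthonormal
rank-one patterns x_i x_iᵀ and λ(k) ∈ R^p their weights.  Across the
population,

* X(k) ~ vMF(F): the matrix von Mises–Fisher (matrix Langevin) distribution
  with density ∝ exp(tr(FᵀX)) against the normalized invariant measure on
  V(n,p).  The columns of F are constrained to be orthogonal, so that its
  column norms s_i (the *concentration parameters*) are the singular values
  of F, and the projection π_V(F) = UVᵀ (from the thin SVD of F) is the mode
  of the distribution.  Each concentration controls how tightly the i-th
  pattern clusters around its mode column.
* λ(k) ~ N(μ, σλ² I_p): independent Gaussian pattern weights.
* ε(k) is symmetric noise with independent N(0, σε²) entries on the
  n(n+1)/2 unique coordinates (upper triangle including the diagonal,
  mirrored below).

The parameters θ = (F, μ, σλ, σε) use n·p + p + 2 scalar degrees of freedom.
The model is a curved exponential family; its complete-data sufficient
statistics are S1 = mean X(k), S2 = mean λ(k), S3 = mean ‖λ(k)‖², and
S4 = mean squared residual ‖A(k) − λ(k)·X(k)‖².

Assumptions worth keeping in mind: patterns and weights are mutually
independent, weights are homoskedastic, and each matrix must be close to
rank p for the decomposition to be meaningful.

### Norm convention

A symmetric matrix has n(n+1)/2 free coordinates and the noise is generated
on exactly those.  All residual norms in the likelihood, the statistic S4
and the M-step therefore count each unique coordinate once (implemented as
a weighted full-matrix sum with weight ½ off the diagonal), and
σ̂ε² = S̄4 / (n(n+1)/2).  The superficially simpler full-matrix convention
(plain Frobenius norm, count n²) double-counts off-diagonal residuals: it
makes the latent posterior artificially tight, biases σ̂ε low by a large
factor (we measured 2.5 versus a true 4.0 on the small benchmark), and
propagates into every posterior quantity — credible intervals computed
under it cover far less than their nominal level.  The consistent
convention recovers σε essentially without bias.  A consequence worth
stating plainly: under consistent inference the estimated concentrations do
**not** shrink systematically when observation noise grows; reported
strong-noise concentration shrinkage in this model family is an artifact of
the double-counting convention (see Limitations).

## The vMF normalizing constant

C_{n,p}(F) is a hypergeometric function of matrix argument and intractable
exactly.  We use a saddle-point approximation built on the representation
of C as a ratio of noncentral-Wishart density values: if Z is n×p with
independent standard Gaussian columns centered at the columns of F, then
W = ZᵀZ is noncentral Wishart and

    log C(F) = log f_W(I_p; F) − log f_W(I_p; 0) + ‖F‖²/2,

with the convention C(0) = 1.  The cumulant generating function of W is
closed-form; for orthogonal-column F (diagonal noncentrality δ_i = s_i²)
the saddle point solves a scalar quadratic per coordinate,
u_i = (n + √(n² + 4δ_i))/2, and the Hessian is diagonal in the natural
basis of symmetric matrices.  The standard second-order correction is
included: the invariants ρ₄, ρ₁₃², ρ₂₃² reduce, for diagonal noncentrality,
to closed sums over closed walks on one, two or three pattern indices (the
explicit coefficients are in `vmf._spa_terms` and were verified against
numerical differentiation of the CGF).  The correction enters in
exponential form.

Accuracy: on the sphere (p=1, n=3) the approximation is within 0.4% of the
closed form sinh(κ)/κ over κ ∈ [0.1, 50]; on V(3,2) it agrees with
brute-force Monte-Carlo integration to better than 1% of the constant.
The residual error decreases quickly with n.

Maximum likelihood for F from a mean frame X̄ follows the classical SVD
reduction: the mode estimate is the polar factor M̄ of X̄, and the
concentrations maximize Σ s_i d̄_i − log Ĉ(s) with d̄ = diag(M̄ᵀX̄), a concave
problem solved with L-BFGS-B from the high-concentration initialization
s_i ≈ n d̄_i/(1 − d̄_i²) (or from the previous estimate inside the SAEM loop,
where consecutive M-steps move slowly).

## MCMC-SAEM estimation

The observed likelihood is maximized with MCMC-SAEM: a Metropolis-within-
Gibbs sampler replaces the intractable E-step, the sufficient statistics
are averaged with Robbins–Monro weights α_t (α_t = 1 for the first half of
the run, then (t − T/2)^{-0.6}), and the M-step is closed-form except for
the concentration solve above.

Kernels: one projected-Gaussian-random-walk proposal per sweep for the full
frame X(k) (perturb, then retract with the SVD projection; the projection
proposal is treated as symmetric in the acceptance ratio, a standard
approximation for this kernel) and one full-vector Gaussian perturbation
for λ(k).  Both are Metropolis–Hastings updates even though the λ
conditional is Gaussian in closed form — the MH version mixes the joint
chain faster.  The two log step sizes adapt toward a target acceptance rate
of 0.3 by ±1/(2t^{0.6}) per iteration (ties count as too-low acceptance).
Updates are vectorized across subjects.

Non-identifiability of column order and sign is handled by greedy column
matching: each subject frame is re-aligned to the current mode (permutation
and signs chosen by maximal absolute inner products, ties broken at the
lowest index, the weight vector permuted along) every 5 iterations during
the first third of the run.  Disabling it degrades weight recovery
substantially (the ablation test reproduces this).

Initialization is spectral: the p largest-|eigenvalue| eigenpairs per
subject, all frames aligned to the first subject, parameters from one
M-step.  Ten hybrid iterations follow in which the X-update is replaced by
a backtracking Riemannian gradient-ascent step (tangent projection
G − X·sym(XᵀG), retraction by SVD projection, step halved from 1e-2 until
the objective does not decrease).

Posterior summaries average the latent samples over the second half of the
iterations; the mean frame is projected back onto the manifold, which is
the mode of a vMF fit to the samples and a well-behaved center because the
vMF law is symmetric about its mode.

## Mixture extension

K components θ_c with probabilities π share the machinery: per-cluster
Gibbs sweeps, per-cluster statistics and M-steps, π̂ equal to the
Robbins–Monro average of the label frequencies.  The label conditional
p(z(k)=c | …) ∝ π_c exp(complete log-likelihood under θ_c) requires the
per-component normalizing constants — they do not cancel when
concentrations differ across clusters.

Labels are initialized by K-Means on the vectorized upper triangles
(10 restarts).  Crucially, the spectral initialization aligns all subjects
to one global reference frame: aligning each cluster to its own eigenvalue
order would place every cluster's dominant weight in slot 0 and erase the
between-cluster weight structure before the first M-step.

Tempering: the label update uses the profile T_t = 1 + 50/t^{0.6}.  The
flattened distribution p^{1/T_t} (renormalized) serves as a *Metropolis
proposal* accepted against the exact conditional.  Using the flattened
distribution as the sampling distribution itself — the textbook tempered
draw — provably destroys the initialization here: at T₁ = 51 the first
draws are near-uniform, the α=1 averaging immediately pools the clusters,
and the run is trapped at a symmetric fixed point (label accuracy stuck
near chance on designs the Metropolized variant solves to 98–99%).  The
Metropolized form keeps the label chain's invariant law untempered while
still encouraging early moves between clusters, and reduces exactly to the
plain Gibbs draw at T = 1.  Component modes are mutually re-aligned by
greedy column matching every 5 iterations; empty clusters keep their
previous parameters.

## Missing-edge imputation

Given fitted parameters and a partially observed matrix (observed set Ω),
the posterior over hidden entries is sampled with a collapsed Gibbs scheme:
the latent chain targets p(X, λ | A_Ω) directly (Metropolis kernels
evaluating the likelihood on observed coordinates only), and hidden entries
are drawn exactly from their conditional N(λ·X restricted to Ω̄, σε²) at
each kept sample.  Because hidden entries are conditionally independent of
everything else given the latents, this yields draws from the same joint
posterior as the literal three-block sweep over (A_Ω̄, X, λ) — but the
literal sweep locks (the imputed entries pin the latents near their
initialization) and was measured at roughly double the error of the
collapsed scheme.  The X-updates here are per-column Metropolis proposals
and the chain starts at the population mode with λ = μ; whole-frame
proposals mix too slowly in n·p dimensions to deliver calibrated intervals
within the default budget of 2000 kept sweeps after 500 burn-in.  Posterior
means and central 95% intervals are reported per hidden entry.

MAP imputation is block coordinate ascent on (A_Ω̄, X, λ): hidden entries
have the closed-form maximizer λ·X on Ω̄; λ takes a backtracking gradient
step; X a backtracking Riemannian ascent step.  The objective is
nondecreasing by construction.

Baselines: the training-set mean matrix, and rank-p truncation of the
zero-filled matrix.  Errors are relative RMSEs over hidden entries, with
mean ± standard deviation reported across matrices.

## Synthetic designs

The generators draw the vMF mode Haar-uniformly and are exactly the
generative model — so passing benchmarks demonstrates correct estimation
under the model's own assumptions, not robustness to model misspecification
(real connectivity matrices have heavy spectral tails, node-level
structure, and are not exact low-rank-plus-noise).

* Small dimension: n=3, p=2, concentrations (25, 10), μ = (20, 10),
  σλ = 2, N = 100; one latent draw observed under σε = 0.1 and σε = 4.
* High dimension: n=40, p=20, N=200, σε=1, σλ=2, with concentrations and
  weights in four matched decreasing batches (large weights paired with
  high concentrations).
* Imputation: n=20, p=5, N=200 training and 200 test matrices, σε
  calibrated by bisection so the mean ratio ‖ε‖/‖λ·X‖ is 25%.  The
  unprinted constants are concentrations (225, 190, 150, 120, 90),
  μ = (15, 12, 10, 8, 5), σλ = 9: weight-dominated variability is the only
  regime in which the training-mean baseline errs at the reported ~75–85%
  level while the posterior mean can still reach ~34% — with
  pattern-dominated variability the per-matrix completion problem is
  underdetermined (even noise-free hard-impute fails) and no estimator
  reaches the reported posterior level.
* Clustering, larger dimension: n=20, p=10, K=4, N=500; equal
  concentrations 20, modes jittered around a common frame (scale 0.03),
  μ_c = 2·(25,22,…,2) with one coordinate boosted by +40 per cluster,
  σλ = 10 (of the order of the means, larger than most coefficients),
  σε=1.  The moderate concentrations make pattern cross-talk inflate
  Euclidean distances — K-Means degrades — while per-subject latent
  inference keeps the weight channel clean for the mixture.  Below
  concentration ≈ 17 the pattern slots become unidentifiable and every
  method collapses; the preset sits safely above that transition.
* Clustering, small dimension: n=3, p=2, K=3; two clusters share μ and
  nearly share their mode, differing mainly by concentration ((120, 60) vs
  (25, 10)); the third differs in μ.

## Numerical choices

* Manifold membership tolerance 1e-8 on ‖XᵀX − I‖∞; projection refuses
  inputs with smallest singular value ≤ 1e-12 (non-unique projection).
* F-column orthogonality tolerance 1e-6 (relative).
* Variance estimates use the 1/N (maximum-likelihood) convention; negative
  finite-sample estimates are floored at 1e-12 with a warning.
* Concentration solve: bounds [0, 1e6], initialization clipped to
  [1e-3, 1e4], L-BFGS-B with numerical gradients.
* vMF sampling runs one independent adaptive chain per requested draw
  (vectorized), 600 burn-in steps from the mode; this gives exactly
  independent draws, unlike thinning a single chain.
* Greedy matching ties break at the lowest row-major index; the SVD sign
  convention fixes each left singular column's largest entry positive
  (the projection UVᵀ itself is sign-invariant).
* Random numbers: one `numpy` Generator drives each top-level run;
  vectorized updates consume it in a fixed order, so runs are exactly
  reproducible from the seed.

## Limitations

* The saddle-point constant has O(1%) relative error at very small n
  (n = 3); it sharpens rapidly with n.  The second-order correction is
  essential at high concentration.
* Under strong observation noise the concentration estimate is only weakly
  identified: the profile likelihood in s is nearly flat, the SAEM
  trajectory wanders, and on the small-dimension strong-noise benchmark the
  estimate settles 20–50% *above* the generating value rather than
  shrinking below it.  The often-reported noise-induced *under*-estimation
  arises only under the inconsistent full-matrix norm convention, which
  this package does not use.
* Under the weight-dominated imputation design, masking a node block is
  slightly *easier* than random masking of the same order (the block's
  cross-edges to observed nodes identify the relevant pattern rows);
  claims that block masking is much harder do not reproduce under a
  well-mixed sampler in this design family.
* K-Means accuracy on the clustering benchmark fluctuates strongly across
  generator draws (≈0.45–0.87); only the mixture accuracy is stable.
* Model selection for p and K is exposed only through diagnostics
  (reconstruction error, variance explained, concentrations against the
  uniform-baseline concentration), not automated.
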