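# stiefnet

Statistical modeling of the variability in populations of undirected
weighted networks that share a node set — the situation of brain functional
connectivity matrices, longitudinal social networks, or gene interaction
networks measured across many subjects.

Each symmetric adjacency matrix is decomposed as a noisy weighted sum of p
rank-one orthonormal patterns,

    A(k) = X(k) Diag(λ(k)) X(k)ᵀ + ε(k),

with the pattern frame X(k) a point on the Stiefel manifold
V(n,p) = {X : XᵀX = I_p} drawn from a matrix von Mises–Fisher distribution
vMF(F) (density ∝ exp tr(FᵀX)), Gaussian pattern weights
λ(k) ~ N(μ, σλ²I), and symmetric Gaussian noise.  The column norms of F are
concentration parameters: they quantify how stable each pattern is across
the population, which makes the fitted model directly interpretable — a
population template (the mode π_V(F) and mean weights μ) plus a small
number of variability parameters, n·p + p + 2 scalars in total.

The package provides:

* maximum-likelihood estimation by **MCMC-SAEM** (Metropolis-within-Gibbs
  E-step on the manifold, stochastic approximation of the sufficient
  statistics, closed-form M-step with a saddle-point approximation of the
  vMF normalizing constant for the concentrations);
* a **mixture** extension for heterogeneous populations, fitted with a
  tempered label sampler, for clustering networks by their mode of
  variability;
* posterior **imputation of missing edges** on new networks (Gibbs
  posterior mean with credible intervals, and a MAP variant), with simple
  baselines for comparison;
* the Stiefel-geometry and vMF primitives (projection, Haar sampling,
  random-walk proposals, Riemannian ascent, saddle-point log-normalizer,
  constrained MLE) as reusable modules;
* self-contained synthetic benchmark presets and a command-line interface.

The estimators follow scikit-learn conventions (`fit`,
`get_params`/`set_params`, trailing-underscore attributes) and compose with
sklearn tooling; the underlying functions live in `stiefnet.stiefel`,
`stiefnet.vmf`, `stiefnet.model`, `stiefnet.saem`, `stiefnet.mixture`,
`stiefnet.imputation`, `stiefnet.experiments` and `stiefnet.io`.

## Worked example

```python
import numpy as np
from stiefnet import StiefelPatternModel, experiments
from stiefnet import model

rng = np.random.default_rng(0)
pre = experiments.preset("smalldim-lownoise")   # n=3, p=2, N=100 benchmark
params = experiments.make_model_params(pre, rng)
A, _ = model.sample_dataset(params, pre.N, rng)

est = StiefelPatternModel(p=2, n_iterations=100, mcmc_steps_per_iter=20,
                          random_state=1).fit(A.matrices)
print("estimated concentrations:", np.round(np.sort(est.concentrations_)[::-1], 1))
print("estimated weight means:  ", np.round(np.sort(est.mu_)[::-1], 2))
print("sigma_lambda = %.2f   sigma_eps = %.3f" % (est.sigma_lambda_, est.sigma_eps_))
err = experiments.aligned_errors(est.params_, params)
print("mode distance to truth:   %.3f" % err["mode_distance"])
```

prints

```
estimated concentrations: [29.9 11.2]
estimated weight means:   [19.77 10.33]
sigma_lambda = 2.01   sigma_eps = 0.089
mode distance to truth:   0.038
```

The generating values were concentrations (25, 10), μ = (20, 10), σλ = 2,
σε = 0.1.  The pattern template (mode) is recovered to Frobenius distance
0.04, the weight parameters essentially exactly; the concentration estimate
carries the sampling noise of fitting a spread parameter from 100 frames
(its standard deviation at this design is about 2.6 — this particular
population happened to draw a tight set of frames, and the direct vMF MLE
on the true latent frames of this data set gives 30.9).

Clustering and imputation run the same way through
`StiefelPatternMixture(p, K, ...)` and `est.impute(A_obs, observed_mask)`,
or through the command line:

```bash
stiefnet simulate --preset cluster-highdim --seed 0 --out networks.npz
stiefnet fit --input networks.npz --p 10 --iters 100 --seed 0 --out params.zip
stiefnet fit-mixture --input networks.npz --p 10 --k 4 --iters 300 --seed 0 --out run/
stiefnet impute --params params.zip --input networks.npz --mask block:8 --out imputed/
stiefnet experiment impute-random --seed 0 --out report.json
```

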