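# braininv

Simulation-based Bayesian inference for whole-brain network models.

Whole-brain (virtual brain) models place a neural-mass model at every region
of a brain parcellation and couple the regions through a structural
connectome — a matrix of white-matter connection weights `SC`. Forward
simulation of such a model produces regional activity and, through a
hemodynamic model, BOLD signals. The *inverse* problem — which control
parameters θ (excitability maps, coupling strengths, conduction velocities,
synaptic counts) explain an observed recording x — has an intractable
likelihood. `braininv` solves it by neural posterior estimation: simulate a
training set {(θᵢ, xᵢ)} with θᵢ ~ p(θ) drawn from a box prior, reduce every
simulation to low-dimensional summary features, and train a conditional
normalizing flow q_φ(θ | x) by minimizing

    L(φ) = − Σᵢ log q_φ(θᵢ | xᵢ),

which approximates the true posterior p(θ | x_obs) when conditioned on the
observed features. Training is single-round (amortized): once fitted, the
flow returns posterior samples for any new observation in seconds.

## What is in the package

- **`braininv.connectome`** — load / validate / max-normalize structural
  connectomes (delimited text, NPZ, HDF5), conduction-delay matrices
  `T = d/v`, and a synthetic-connectome generator (log-normal weights,
  Euclidean distances from random 3-D centroids).
- **`braininv.models`** — stochastic-Heun network integrators (numba) for
  six neural-mass models: Wilson-Cowan, Jansen-Rit, delayed Stuart-Landau,
  2-D Epileptor, Montbrió (exact QIF mean field), and reduced Wong-Wang with
  the pDMF parameterization (3N regional parameters expressed through 9
  coefficients of two anatomical maps).
- **`braininv.hemodynamics`** — Balloon-Windkessel neurovascular model
  mapping activity to TR-sampled BOLD.
- **`braininv.features`** — PSD summaries, statistical moments, FC / FCD
  (sliding-window functional connectivity dynamics), seizure-envelope power
  and onset, composed through deterministic `FeatureRecipe`s.
- **`braininv.flows` / `braininv.inference`** — masked autoregressive flow
  (MAF) and rational-quadratic neural spline flow (NSF) conditional density
  estimators written in numpy on a small reverse-mode autodiff engine;
  `NeuralPosterior(dataset).fit()` returns a `PosteriorResult` with
  `sample()`, `log_prob()`, and a `summary()` table. Posterior draws are
  rejection-filtered to the prior box with leakage detection.
- **`braininv.diagnostics`** — posterior z-score `z = |θ̄ − θ*|/σ_post`,
  shrinkage `s = 1 − σ²_post/σ²_prior`, posterior correlations, and the
  sensitivity matrix `M = E[∇θ p ∇θ pᵀ]` with its eigen-decomposition.
- **`braininv.experiments`** — end-to-end scaled-down recovery studies
  (20-region synthetic connectomes, 1–3 k simulation budgets) for each
  model, reproducible bit-for-bit from a single master seed.
- **`braininv` CLI** — `simulate`, `featurize`, `train`, `sample`, and
  `exp run` subcommands.

## Worked example

Recover the global coupling G and mean excitability η of a 20-region
Montbrió network from synthetic BOLD (FC/FCD + moment features, 2 k
training simulations, MAF):

```python
from braininv.experiments import default_config, run_recovery

result = run_recovery(default_config("montbrio", seed=1))
print(result.estimator.summary(result.x_obs, theta_true=result.config.theta_true))
```

```
Posterior summary (MAF, 2000 training simulations, 2000 draws, acceptance 1.000)
------------------------------------------------------------------------------
parameter          mean       sd       5%      50%      95%  shrinkage        z
G                 0.542    0.124   0.3335   0.5439   0.7436      0.817     0.15
eta              -4.582   0.0244   -4.625    -4.58   -4.546      0.999     0.74
```

The ground truth was (G, η) = (0.56, −4.6): both posteriors are centred on
the truth (z well below 1), η is pinned almost completely (shrinkage 0.999)
by the regional BOLD moments, and G is constrained to about an eighth of its
prior width. The same pattern of diagnostics is produced for the
Stuart-Landau conduction-velocity study, the Jansen-Rit synapse-count study,
and the Epileptor epileptogenic-zone study (where per-region posterior-mean
excitability is classified EZ / propagation / healthy by nearest centroid).

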