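# Methods

This note documents the models, numerical choices, default study conditions,
and known limitations of `braininv`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Network models

All six models share one structure: a per-region neural-mass system coupled
through a normalized structural connectivity matrix `SC` (weights divided by
their global maximum, so the global coupling parameters keep comparable
scales across connectomes; self-connections are zero because the coupling
sums represent afferent input from *other* regions).

- **Wilson-Cowan.** Excitatory/inhibitory rate pair per region with
  sigmoidal transfer; the "shifted" sigmoid subtracts its value at zero so
  the resting origin is an exact fixed point. Coupling enters the excitatory
  and inhibitory input sums as `g_e Σ SC·E` and `g_i Σ SC·I`. Time is
  measured in the population time constant (τ = 8). Note: with the nominal
  parameter set, external drive P in roughly [1.2, 2] puts the isolated node
  in a limit-cycle window; fixed-point tests use drives outside it.
- **Jansen-Rit.** Three-population column (pyramidal, excitatory and
  inhibitory interneurons), six states per region; output y1 − y2; coupling
  through the firing rate of the pyramidal output scaled by G. The external
  pyramidal drive P(t) is modeled as a constant mean (220 Hz, the midpoint
  of the classic pulse-density range) plus white-noise increments with SD 5,
  chosen so the stochastic spectral peak stays in the alpha band of the
  deterministic limit cycle (~11 Hz at C = 135).
- **Stuart-Landau with delays.** Complex Hopf normal form per region
  (a = −5: damped, noise-sustained oscillations at 40 Hz), diffusive
  delayed coupling `G Σ SC [Z_k(t − T_jk) − Z_j]` with `T = d/v`. Delays are
  rounded to the nearest integration step (an edge whose delay rounds below
  one step raises a configuration error); history is the initial state held
  constant. At the nominal G = 350 the diffusive term dominates the local
  damping, producing a strongly coupled delay-resonator network whose
  *per-region* spectra have idiosyncratic resonances while the *pooled*
  spectrum varies smoothly with (G, v).
- **2-D Epileptor.** Fast variable x on a cubic nullcline, slow recovery z
  with time constant τ = 90 ms; the coupling enters the slow equation with
  the printed sign. The excitability map η sets the distance from the
  seizure bifurcation (η_c ≈ −2.06 for the isolated node): η = −1.6 seizes
  autonomously, η = −2.2 seizes only when recruited, η = −3.65 is stably
  healthy. The model is deterministic.
- **Montbrió.** Exact mean-field (firing rate r, mean potential v) of a QIF
  population with Lorentzian heterogeneity. The Δ/(πτ) term repels r = 0;
  the integrator additionally retries a violating step once at half step
  size and raises if r still crosses zero. Noise (SD σ = 0.037) enters only
  the v equation, as the model is written. With the nominal parameters each
  isolated node is bistable (verified by root solve + Jacobian eigenvalues),
  but at desk scale (20 regions, v-only noise) the network does not jump the
  barrier between states: it remains in the down state, and BOLD functional
  connectivity saturates near 1 (see Limitations).
- **Reduced Wong-Wang / pDMF.** One gating variable S per region with the
  transfer function H(x); the removable singularity at a·x = b is evaluated
  by a guarded series branch (H → 1/d). S is clipped to [0, 1] after every
  stage. The pDMF parameterization writes the 3N regional parameters
  (w, I, σ) as linear functions of two anatomical maps with 9 coefficients.

## Integration

Stochastic Heun throughout: an Euler predictor including the noise increment
σ√dt·ζ, then a trapezoidal corrector reusing the same increment. With σ = 0
this is deterministic Heun; measured convergence order on smooth
trajectories is ≥ 1.7 (test suite). Default steps are ≥ 20 per fastest time
constant: Wilson-Cowan 0.05 τ, Jansen-Rit 0.1–0.25 ms, Stuart-Landau 0.1 ms,
Epileptor 0.05 ms, Montbrió 0.01 ms (0.05 ms in the BOLD studies, verified
stable over the whole prior box), Wong-Wang 1 ms.

Per-region noise comes from independent Philox substreams spawned from the
master seed, with initial-condition draws taken first from the same
substream. Consequently a zero-coupling network run is *bit-identical*,
region by region, to isolated single-node runs on the matching substreams —
a sharp regression test for any coupling-term error — and every simulation
is reproducible from (parameters, connectome, seed, dt, duration).

Long runs record bin-averaged states on a coarser grid (e.g. 4 ms for the
Montbrió BOLD studies); the hemodynamic model then integrates at the
recorded dt. The first 10% of each simulation is discarded before
featurization except in the Epileptor study, where the onset transition is
itself the data feature.

## Hemodynamics

Balloon-Windkessel per region: vasodilatory signal s, inflow f, venous
volume v, deoxyhemoglobin q, driven by the model observable; readout
y = V₀(k₁(1 − q) + k₂(1 − q/v) + k₃(1 − v)) with k₁ = 4.3·ϑ₀·E₀·TE,
k₂ = ε·r₀·E₀·TE, k₃ = 1 − ε at the 1.5 T nominal parameter set. The two
distinct epsilons (neuronal efficacy 0.1 in the state equations;
intra/extravascular ratio 1.43 in the readout) are separate fields. Rest
(s=0, f=v=q=1) is an exact fixed point, so zero input produces exactly zero
BOLD. The deoxyhemoglobin clearance term is implemented exactly as the model
is specified here (v^{1/α}·q); the rest state is unaffected by the choice.
The balloon settles over ~10–15 s, so short-run BOLD carries a shared onset
transient; studies either cut it or (for FC-type features) must detrend —
see Limitations.

## Features

Fixed-length vectors assembled by deterministic recipes:

- **PSD summaries** — Welch periodogram (Hann taper, 50% overlap, segment
  length min(T, 2 s) by default): per region, peak frequency, peak power,
  total power, spectral centroid, spectral spread, plus requested band
  powers. Options: log10 (dB-like) power scaling — essential whenever power
  varies over orders of magnitude across the prior, since z-scoring a
  heavy-tailed feature crushes its information — and a pooled variant
  (summaries of the across-region mean PSD plus across-region mean/SD of
  the per-region summaries) for regimes where per-region resonance detail
  is unstable.
- **Moments** — per-region mean, variance, skewness, excess kurtosis
  (constant signals report zero higher moments).
- **FC / FCD** — Pearson functional connectivity; FCD as the correlation
  between vectorized upper-triangular FCs of sliding windows. Defaults for
  BOLD: window 30 TR, stride 2 TR (the studies use window ~15 samples at
  their shorter records); for fast signals: window 1 s, stride 0.1 s.
  Summaries are moments of the off-diagonal entries plus optional principal
  component scores with loadings fit once on the training set and frozen.
- **Seizure features** — envelope = smoothed |signal − moving average|;
  total power = area under the squared envelope (optionally log10); onset =
  first crossing of baseline mean + 3 baseline SDs (SD of the unsmoothed
  envelope, robust to noise crossings), sentinel = record duration. The
  baseline fraction is configurable; the Epileptor study uses the first 1%
  because its onsets occur within a few tens of ms.

Any non-finite feature is a hard failure; affected simulations are dropped
from training sets with a logged count (an error above 50%).

## Inference

Uniform box priors. The conditional density estimator is a masked
autoregressive flow — 5 transforms, each a 2-hidden-layer masked MLP of 50
tanh units with the conditioning features entering the first layer, batch
normalization after each transform, order reversal between transforms — or a
rational-quadratic neural spline coupling flow (5 transforms, 2 residual
blocks of 50 ReLU units, 10 bins, tail bound 3). Both are implemented in
numpy over a small reverse-mode autodiff engine; gradients are verified
against finite differences in the test suite, and the training path is
validated against the analytic conjugate posterior of a linear-Gaussian toy
problem and a simulation-based calibration (uniform-rank) check.

Numerical choices: features are z-scored by training statistics
(effectively constant features dropped); θ is standardized internally by a
fixed affine flow layer (exact, constant Jacobian) but trained in its
natural box — no logit transform, so shrinkage and z-scores read directly in
parameter units; log-scales are smoothly capped at ±5 to keep transforms
invertible under extrapolation. Optimization: Adam, batch 256, learning rate
5e-4, 90/10 train/validation split, early stopping with patience 20 (the
canned studies use 1e-3/patience 40, which the higher-dimensional Epileptor
fit needs to converge; the Stuart-Landau study keeps the default schedule,
which preserves its wide G–v posterior ridge rather than over-sharpening).
Posterior sampling rejects draws outside the prior box and reports the
acceptance fraction; below 1% a leakage error is raised.

Sensitivity analysis estimates M = E_post[∇θp ∇θpᵀ] over posterior draws
with ∇θp = p·∇θ log p from autodiff (central differences available),
normalizing density values by their posterior-sample mean first — M is
scale-sensitive and the flow density is unnormalized, so only the
eigenstructure, not the absolute eigenvalues, is interpretable.

## Study conditions (scaled down)

All recovery studies use 20-region synthetic connectomes (symmetric
log-normal weights, zero diagonal, centroids in a 150 mm cube with ≥ 10 mm
separation so delays stay resolvable), desk-scale durations, and reduced
budgets; one master seed derives every stage seed. Ground truths are the
models' nominal values.

| study | θ | budget | observation | features |
|---|---|---|---|---|
| Stuart-Landau | G=350, v=6 m/s | 2000 | 2.2 s at 0.2 ms | per-region PSD summaries + γ-band powers |
| Jansen-Rit | G=1.5, C=135 | 2000 | 2.2 s at 1 ms | per-region PSD summaries + θ/α/β bands |
| Epileptor | G=1, η map (2 EZ, 3 PZ) | 3000 | 2000 ms | log seizure power + onset + moments per region |
| Montbrió (BOLD) | G=0.56, η=−4.6 | 2000 | 10 s, TR 0.3 s | FC/FCD summaries + per-region moments |

The Epileptor study plants maximal-weight connectome edges from the two
epileptogenic to the three propagation regions: with the model's
difference-coupling, densely connected healthy neighbours *stabilize* a
near-threshold region, and recruitment of an arbitrary random edge pattern
is a coin flip. Clinically the propagation zone is defined precisely by its
strong structural pathway from the epileptogenic zone, so the synthetic
patient encodes that structure; recruitment of all three PZ regions with
delayed onsets was verified across 12 connectome realizations.

## What the synthetic studies do and do not show

The generator reproduces the structural properties the models assume
(non-negative heavy-tailed weights, Euclidean distances, smooth anatomical
maps) but not the topology of real connectomes (hubs, modules, spatial
embedding of fiber bundles), the measurement chain of real recordings
(sensor projection, physiological noise, preprocessing), or subject
variability. Passing recoveries demonstrate that the inference machinery is
calibrated and that the stated features identify the stated parameters
*under the model that generated the data* — not that the models fit
empirical recordings.

## Known limitations

- At desk scale the Montbrió network never switches between its bistable
  states (noise enters only v, and the barrier is high at σ = 0.037), so
  BOLD FC/FCD are nearly degenerate (≈ 1) and coupling is identified
  through regional BOLD moments instead. Realizing FCD-carried coupling
  information requires the full-scale regime.
- Stuart-Landau conduction-velocity recovery from short single observations
  is noise-limited: the posterior mean scatters by roughly ±1–2 m/s across
  observation realizations at the 2.2 s default record.
- The NSF family needs at least two parameters (coupling split); use MAF
  for one-dimensional problems.
- Sequential (multi-round) refinement, sensor-level forward models, and
  information-theoretic features are out of scope.
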