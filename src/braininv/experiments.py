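"""End-to-end in-silico parameter-recovery studies.

Each study is the full pipeline on synthetic data: build a connectome, pick a
ground-truth parameter set, simulate one observation, reduce it to features,
simulate a prior-predictive training batch, train a conditional flow, sample
the posterior at the observation, and evaluate z-score / shrinkage /
correlation diagnostics. Default configurations are desk-scale versions of
the canonical experiments for each model (20 regions, 1-3k simulation
budgets, seconds-long runs); every stage's seed derives from one master seed
so a study is reproducible bit-for-bit from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectome import (
    StructuralConnectome,
    generate_regional_maps,
    generate_synthetic_connectome,
    normalize_connectome,
)
from .diagnostics import DiagnosticsReport, make_report
from .errors import PreconditionError, ValidationError
from .features import FeatureRecipe, FeatureVector, build_feature_recipe
from .flows import TrainConfig
from .hemodynamics import BalloonParams, bold_forward
from .inference import (
    NeuralPosterior,
    PosteriorResult,
    PosteriorSamples,
    PriorSpec,
    TrainingDataset,
    run_simulation_batch,
)
from .models import (
    EpileptorParams,
    JansenRitParams,
    MontbrioParams,
    SimulationResult,
    StuartLandauParams,
    WilsonCowanParams,
    WongWangParams,
    PDMFCoefficients,
    pdmf_expand,
    simulate_epileptor2d,
    simulate_jansen_rit,
    simulate_montbrio,
    simulate_stuart_landau,
    simulate_wilson_cowan,
    simulate_wong_wang,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RecoveryConfig",
    "RecoveryResult",
    "default_config",
    "run_recovery",
    "classify_epileptogenicity",
    "cut_transient",
    "EPILEPTOGENICITY_CENTROIDS",
]

# nearest-centroid classes for the epileptogenicity map: healthy at the
# nominal stable value, EZ well above the seizure bifurcation, PZ just below
EPILEPTOGENICITY_CENTROIDS = {"EZ": -1.6, "PZ": -2.2, "healthy": -3.65}


def cut_transient(result: SimulationResult, fraction: float = 0.1) -> SimulationResult:
    """Drop the leading ``fraction`` of a simulation before featurization."""
    T = result.states.shape[1]
    cut = int(round(fraction * T))
    return SimulationResult(
        time=result.time[cut:],
        states=result.states[:, cut:],
        dt=result.dt,
        model_id=result.model_id,
        seed=result.seed,
        params_digest=result.params_digest,
        time_unit=result.time_unit,
        extras={k: v[:, cut:] for k, v in result.extras.items()},
    )


@dataclass
class RecoveryConfig:
    """One parameter-recovery study, fully determined by its fields."""

    model_id: str
    prior: PriorSpec
    theta_true: np.ndarray
    n_regions: int = 20
    density: float = 0.6
    budget: int = 2000
    family: str = "MAF"
    seed: int = 1
    duration: float = 2.2
    dt: float = 1e-4
    record_every: int = 1
    transient_fraction: float = 0.1
    feature_steps: dict = field(default_factory=dict)
    n_draws: int = 10_000
    use_bold: bool = False
    balloon: BalloonParams | None = None
    train: TrainConfig | None = None
    model_kwargs: dict = field(default_factory=dict)
    n_mc_sensitivity: int = 0
    planted_edges: list = field(default_factory=list)  # (i, j, weight) set post-normalization

    def __post_init__(self):
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        if self.theta_true.size != self.prior.dim:
            raise ValidationError("ground truth dimension must match the prior")
        if not bool(self.prior.contains(self.theta_true)[0]):
            raise ValidationError("ground truth must lie inside the prior box")

    def stage_seeds(self) -> dict:
        s = np.random.SeedSequence(self.seed).generate_state(6) % (2**31 - 1)
        return {
            "connectome": int(s[0]),
            "observation": int(s[1]),
            "batch": int(s[2]),
            "train": int(s[3]),
            "sample": int(s[4]),
            "flow_init": int(s[5]),
        }


@dataclass
class RecoveryResult:
    """Everything a recovery produced, plus a replayable manifest."""

    config: RecoveryConfig
    sc: StructuralConnectome
    x_obs: FeatureVector
    dataset: TrainingDataset
    estimator: PosteriorResult
    samples: PosteriorSamples
    report: DiagnosticsReport
    manifest: dict

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.samples.mean()

    def save(self, out_dir: str | Path) -> Path:
        """Write manifest + report JSON under one output directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        (out / "report.json").write_text(json.dumps(self.report.to_dict(), indent=2))
        return out


def _theta_to_params(model_id: str, theta: np.ndarray, n: int,
                     model_kwargs: dict):
    """Map a parameter vector onto a model parameter object."""
    kw = dict(model_kwargs)
    if model_id == "stuart_landau":
        return StuartLandauParams(G=theta[0], velocity=theta[1], **kw)
    if model_id == "jansen_rit":
        return JansenRitParams(G=theta[0], C=theta[1], **kw)
    if model_id == "epileptor2d":
        return EpileptorParams(G=theta[0], eta=np.asarray(theta[1:]), **kw)
    if model_id == "montbrio":
        return MontbrioParams(G=theta[0], eta=theta[1], **kw)
    if model_id == "wilson_cowan":
        return WilsonCowanParams(g_e=theta[0], P=theta[1], **kw)
    if model_id == "wong_wang":
        maps = kw.pop("maps")
        coeffs = PDMFCoefficients(
            a_w=theta[1], b_w=theta[2], c_w=theta[3],
            a_I=theta[4], b_I=theta[5], c_I=theta[6],
            a_sigma=theta[7], b_sigma=theta[8], c_sigma=theta[9],
            mye=maps[0], grad=maps[1],
        )
        w, I, sigma = pdmf_expand(coeffs)
        return WongWangParams(G=theta[0], w=w, I=I,
                              sigma=np.clip(sigma, 0.0, None), **kw)
    raise ValidationError(f"unknown model_id {model_id!r}")


_SIMULATE = {
    "stuart_landau": simulate_stuart_landau,
    "jansen_rit": simulate_jansen_rit,
    "epileptor2d": simulate_epileptor2d,
    "montbrio": simulate_montbrio,
    "wilson_cowan": simulate_wilson_cowan,
    "wong_wang": simulate_wong_wang,
}


def make_simulator(config: RecoveryConfig, sc: StructuralConnectome):
    """Build the theta -> features-ready result callable for one study."""
    simulate = _SIMULATE[config.model_id]

    def simulator(theta: np.ndarray, sim_seed: int):
        params = _theta_to_params(config.model_id, theta, sc.n_regions,
                                  config.model_kwargs)
        result = simulate(sc, params, duration=config.duration, dt=config.dt,
                          seed=sim_seed, record_every=config.record_every)
        if config.use_bold:
            return bold_forward(result, config.balloon or BalloonParams(),
                                transient_fraction=config.transient_fraction)
        return cut_transient(result, config.transient_fraction)

    return simulator


def run_recovery(config: RecoveryConfig, out_dir: str | Path | None = None) -> RecoveryResult:
    """Execute one recovery study end to end."""
    seeds = config.stage_seeds()
    sc = normalize_connectome(
        generate_synthetic_connectome(config.n_regions, config.density,
                                      seed=seeds["connectome"])
    )
    if config.planted_edges:
        W = sc.weights.copy()
        for i, j, w in config.planted_edges:
            W[i, j] = W[j, i] = w
        sc = StructuralConnectome(W, sc.distances, list(sc.labels),
                                  normalized=bool(W.max() == 1.0))
    recipe = build_feature_recipe(config.feature_steps,
                                  recipe_id=f"{config.model_id}_recovery")
    simulator = make_simulator(config, sc)

    x_obs = recipe.apply(simulator(config.theta_true, seeds["observation"]))
    dataset = run_simulation_batch(simulator, config.prior, config.budget,
                                   recipe, seed=seeds["batch"])
    train_cfg = config.train or TrainConfig()
    train_cfg.seed = seeds["train"]
    model = NeuralPosterior(dataset, family=config.family,
                            train_config=train_cfg,
                            flow_seed=seeds["flow_init"])
    estimator = model.fit()
    samples = estimator.sample(x_obs, n_draws=config.n_draws,
                               seed=seeds["sample"])
    report = make_report(estimator, samples, config.theta_true, x_obs=x_obs,
                         n_mc_sensitivity=config.n_mc_sensitivity,
                         seed=seeds["sample"])
    manifest = {
        "model_id": config.model_id,
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_regions": config.n_regions,
        "budget": config.budget,
        "kept_rows": dataset.n_sim,
        "family": config.family,
        "duration": config.duration,
        "dt": config.dt,
        "theta_true": config.theta_true.tolist(),
        "prior_lower": config.prior.lower.tolist(),
        "prior_upper": config.prior.upper.tolist(),
        "recipe": config.feature_steps,
        "n_features": len(x_obs),
        "best_epoch": estimator.history.best_epoch,
    }
    result = RecoveryResult(config=config, sc=sc, x_obs=x_obs, dataset=dataset,
                            estimator=estimator, samples=samples,
                            report=report, manifest=manifest)
    if out_dir is not None:
        result.save(out_dir)
    return result


def classify_epileptogenicity(
    posterior_mean_eta: np.ndarray,
    centroids: dict[str, float] | None = None,
) -> list[str]:
    """Nearest-centroid classification of regions into EZ / PZ / healthy."""
    centroids = centroids or EPILEPTOGENICITY_CENTROIDS
    vals = np.array(list(centroids.values()))
    names = list(centroids.keys())
    if len(set(vals)) != len(vals) or not (np.diff(np.sort(vals)) > 0).all():
        raise PreconditionError("class centroids must be strictly ordered")
    eta = np.asarray(posterior_mean_eta, dtype=float)
    idx = np.argmin(np.abs(eta[:, None] - vals[None, :]), axis=1)
    return [names[i] for i in idx]


# ---------------------------------------------------------------------------
# canned desk-scale study configurations
# ---------------------------------------------------------------------------


def default_config(model_id: str, seed: int = 1, **overrides) -> RecoveryConfig:
    """Desk-scale default study for each model (override any field)."""
    # training schedule shared by the canned studies: a slightly higher
    # learning rate with longer early-stopping patience converges the
    # higher-dimensional fits reliably at these budgets
    study_train = TrainConfig(learning_rate=1e-3, patience=40, max_epochs=300)
    if model_id == "stuart_landau":
        cfg = RecoveryConfig(
            model_id=model_id,
            prior=PriorSpec(("G", "V"), [0.0, 1.0], [400.0, 30.0]),
            theta_true=[350.0, 6.0],
            budget=2000,
            duration=2.2,
            dt=1e-4,
            record_every=2,
            feature_steps={"psd_summary": {"bands": [(20.0, 35.0), (35.0, 45.0), (45.0, 60.0)]}},
            # the wide-ridge G-V posterior (the degeneracy the joint posterior
            # correlation measures) is preserved best by the default estimator
            # schedule; the longer study schedule over-sharpens G here
            train=TrainConfig(),
            seed=seed,
        )
    elif model_id == "jansen_rit":
        cfg = RecoveryConfig(
            model_id=model_id,
            prior=PriorSpec(("G", "C"), [0.0, 100.0], [5.0, 650.0]),
            theta_true=[1.5, 135.0],
            budget=2000,
            duration=2.2,
            dt=2e-4,
            record_every=5,
            feature_steps={"psd_summary": {"bands": [(3.0, 8.0), (8.0, 12.0), (12.0, 30.0)]}},
            train=study_train,
            seed=seed,
        )
    elif model_id == "epileptor2d":
        n = overrides.get("n_regions", 20)
        eta_true = np.full(n, EPILEPTOGENICITY_CENTROIDS["healthy"])
        eta_true[:2] = EPILEPTOGENICITY_CENTROIDS["EZ"]
        eta_true[2:5] = EPILEPTOGENICITY_CENTROIDS["PZ"]
        names = ("G",) + tuple(f"eta_{i}" for i in range(n))
        cfg = RecoveryConfig(
            model_id=model_id,
            prior=PriorSpec(names, [0.0] + [-5.0] * n, [2.0] + [-1.0] * n),
            theta_true=np.concatenate([[1.0], eta_true]),
            density=0.3,
            budget=3000,
            duration=2000.0,
            dt=0.05,
            record_every=10,
            transient_fraction=0.0,  # seizure onsets are the feature; keep t=0
            feature_steps={"seizure_features": {
                "baseline_fraction": 0.01, "log_power": True},
                "stat_moments": {}},
            model_kwargs={"tau": 90.0},
            # the synthetic patient has maximal-weight pathways from the
            # epileptogenic to the propagation regions, so recruitment is a
            # structural property of the network rather than a lottery over
            # random connectomes
            planted_edges=[(i, j, 1.0) for i in (0, 1) for j in (2, 3, 4)],
            train=study_train,
            seed=seed,
        )
    elif model_id == "montbrio":
        cfg = RecoveryConfig(
            model_id=model_id,
            prior=PriorSpec(("G", "eta"), [0.0, -6.0], [1.0, -3.5]),
            theta_true=[0.56, -4.6],
            budget=2000,
            duration=10_000.0,
            dt=0.05,
            record_every=80,
            use_bold=True,
            balloon=BalloonParams(TR=0.3),
            feature_steps={
                "stat_moments": {},
                "fcd_fc_summary": {"window": 14, "stride": 3},
            },
            train=study_train,
            seed=seed,
        )
    elif model_id == "wilson_cowan":
        cfg = RecoveryConfig(
            model_id=model_id,
            prior=PriorSpec(("g_e", "P"), [0.0, 0.0], [3.0, 3.0]),
            theta_true=[1.0, 1.5],
            budget=1500,
            duration=400.0,
            dt=0.05,
            record_every=4,
            feature_steps={"psd_summary": {}, "stat_moments": {}},
            train=study_train,
            seed=seed,
        )
    elif model_id == "wong_wang":
        n = overrides.get("n_regions", 20)
        maps = generate_regional_maps(n, seed=seed)
        names = ("G", "a_w", "b_w", "c_w", "a_I", "b_I", "c_I",
                 "a_sigma", "b_sigma", "c_sigma")
        lower = [1.0, -0.3, -0.3, 0.3, -0.2, -0.2, 0.2, -0.002, -0.002, 0.003]
        upper = [10.0, 0.3, 0.3, 0.9, 0.2, 0.2, 0.45, 0.002, 0.002, 0.008]
        truth = [6.28, 0.1, -0.1, 0.6, 0.05, -0.05, 0.3, 0.001, -0.001, 0.005]
        cfg = RecoveryConfig(
            model_id=model_id,
            prior=PriorSpec(names, lower, upper),
            theta_true=truth,
            budget=500,
            duration=120_000.0,
            dt=2.0,
            record_every=50,
            use_bold=True,
            balloon=BalloonParams(TR=1.0),
            feature_steps={
                "stat_moments": {},
                "fcd_fc_summary": {"window": 30, "stride": 4},
            },
            model_kwargs={"maps": maps},
            train=study_train,
            seed=seed,
        )
    else:
        raise ValidationError(f"unknown model_id {model_id!r}")
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.__post_init__()
    return cfg
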