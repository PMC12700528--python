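"""Neural posterior estimation: priors, simulation batches, training, sampling.

The workflow mirrors amortized simulation-based inference: draw parameters
from a box prior, simulate, reduce each simulation to features, train a
conditional flow q(theta | x) by maximum likelihood on the (theta, x) pairs,
then condition on observed features to obtain posterior draws. The model /
results split follows the fitting idiom of statistical-modeling packages:
``NeuralPosterior`` is constructed from a TrainingDataset and ``fit()``
returns a ``PosteriorResult`` that carries the trained estimator, sampling,
log-density, diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DatasetQualityError,
    DegeneratePosteriorError,
    LeakageError,
    PreconditionError,
    ValidationError,
)
from .features import FeatureRecipe, FeatureVector
from .flows import ConditionalMAF, ConditionalNSF, TrainConfig, train_flow

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "TrainingDataset",
    "PosteriorSamples",
    "NeuralPosterior",
    "PosteriorResult",
    "sample_prior",
    "run_simulation_batch",
    "train_posterior_estimator",
    "sample_posterior",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform box prior over named parameters."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size < 1:
            raise ValidationError("lower/upper must be equal-length 1-D arrays")
        if np.any(lo >= hi):
            raise ValidationError("prior requires lower < upper elementwise")
        if len(self.names) != lo.size:
            raise ValidationError("one name per parameter required")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def variance(self) -> np.ndarray:
        """Variance of each U(lower, upper) marginal: width^2 / 12."""
        return (self.upper - self.lower) ** 2 / 12.0

    @property
    def std(self) -> np.ndarray:
        return np.sqrt(self.variance)

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return np.all((theta >= self.lower) & (theta <= self.upper), axis=1)


def sample_prior(prior: PriorSpec, n: int, seed: int = 0) -> np.ndarray:
    """I.i.d. uniform draws from the prior box; deterministic given seed."""
    if n < 1:
        raise PreconditionError("n must be at least 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(prior.lower, prior.upper, size=(n, prior.dim))


@dataclass
class TrainingDataset:
    """Row-aligned (theta, features) pairs with prior and seed provenance."""

    theta: np.ndarray
    features: np.ndarray
    prior: PriorSpec
    recipe_id: str = ""
    seeds: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.theta.shape[0] != self.features.shape[0]:
            raise ValidationError("theta and features must have aligned rows")
        if self.theta.shape[0] < 1:
            raise ValidationError("dataset must contain at least one row")

    @property
    def n_sim(self) -> int:
        return self.theta.shape[0]


def run_simulation_batch(
    simulator,
    prior: PriorSpec,
    n_sim: int,
    recipe: FeatureRecipe,
    seed: int = 0,
    theta: np.ndarray | None = None,
    progress: bool = False,
) -> TrainingDataset:
    """Simulate n_sim prior draws and featurize each one.

    ``simulator(theta_row, sim_seed)`` must return a SimulationResult or
    BoldResult. Per-simulation seeds derive from the master seed through a
    SeedSequence spawn, so the dataset is reproducible and resumable.
    Rows whose features contain non-finite values (or whose simulation
    diverges) are dropped with a logged count; more than 50% bad rows raises
    DatasetQualityError.
    """
    if theta is None:
        theta = sample_prior(prior, n_sim, seed)
    theta = np.atleast_2d(theta)
    sim_seeds = np.random.SeedSequence(seed).generate_state(n_sim) % (2**31 - 1)
    rows, kept_theta, kept_seeds = [], [], []
    names: list[str] = []
    n_bad = 0
    for i in range(n_sim):
        try:
            result = simulator(theta[i], int(sim_seeds[i]))
            fv = recipe.apply(result)
            names = fv.names
            rows.append(fv.values)
            kept_theta.append(theta[i])
            kept_seeds.append(sim_seeds[i])
        except Exception as exc:  # noqa: BLE001 - any bad simulation is a dropped row
            n_bad += 1
            logger.debug("simulation %d dropped: %s", i, exc)
        if progress and (i + 1) % max(1, n_sim // 10) == 0:
            logger.info("simulated %d / %d", i + 1, n_sim)
    if n_bad:
        logger.warning("dropped %d / %d simulations with unusable features", n_bad, n_sim)
    if n_bad > 0.5 * n_sim:
        raise DatasetQualityError(
            f"{n_bad}/{n_sim} simulations produced unusable features"
        )
    return TrainingDataset(
        theta=np.asarray(kept_theta),
        features=np.asarray(rows),
        prior=prior,
        recipe_id=recipe.recipe_id,
        seeds=np.asarray(kept_seeds, dtype=np.int64),
        feature_names=names,
    )


@dataclass
class PosteriorSamples:
    """Posterior draws conditioned on one observation."""

    samples: np.ndarray
    x_obs: np.ndarray
    acceptance_fraction: float
    names: tuple = ()

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0]

    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def std(self) -> np.ndarray:
        return self.samples.std(axis=0)


class NeuralPosterior:
    """Conditional-density model of p(theta | x) built from a TrainingDataset.

    Parameters
    ----------
    data : TrainingDataset
        Aligned (theta, features) pairs with their prior.
    family : {"MAF", "NSF"}
        Flow family; MAF is the default used throughout the experiments.
    train_config : TrainConfig, optional
        Optimization settings (batch size, learning rate, early stopping).
    min_sims : int
        Floor on the number of training simulations.
    """

    def __init__(
        self,
        data: TrainingDataset,
        family: str = "MAF",
        train_config: TrainConfig | None = None,
        min_sims: int = 100,
        n_transforms: int = 5,
        hidden: int = 50,
        flow_seed: int = 0,
    ):
        if data.n_sim < min_sims:
            raise PreconditionError(
                f"need at least {min_sims} simulations, got {data.n_sim}"
            )
        family = family.upper()
        if family not in ("MAF", "NSF"):
            raise ValidationError("family must be 'MAF' or 'NSF'")
        self.data = data
        self.family = family
        self.train_config = train_config or TrainConfig()
        self.n_transforms = n_transforms
        self.hidden = hidden
        self.flow_seed = flow_seed

        feats = data.features
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        # drop only features constant to machine precision relative to their
        # own level; small-magnitude features with genuine variation stay
        keep = (sd > 0) & (sd > 1e-12 * np.abs(mu))
        if not np.all(keep):
            dropped = [data.feature_names[i] if data.feature_names else str(i)
                       for i in np.flatnonzero(~keep)]
            logger.warning("dropping %d zero-variance features: %s",
                           len(dropped), dropped[:8])
        self.feature_keep = keep
        self.feature_mean = mu[keep]
        self.feature_std = sd[keep]

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.feature_keep.size:
            raise ValidationError(
                f"observation has {x.shape[1]} features, "
                f"estimator expects {self.feature_keep.size}"
            )
        return (x[:, self.feature_keep] - self.feature_mean) / self.feature_std

    def fit(self) -> "PosteriorResult":
        """Train the flow by maximum conditional likelihood; returns results."""
        d = self.data.prior.dim
        x_std = self._standardize(self.data.features)
        m = x_std.shape[1]
        cls = ConditionalMAF if self.family == "MAF" else ConditionalNSF
        flow = cls(d, m, n_transforms=self.n_transforms, hidden=self.hidden,
                   seed=self.flow_seed)
        flow.set_standardization(self.data.theta.mean(axis=0),
                                 self.data.theta.std(axis=0))
        history = train_flow(flow, self.data.theta, x_std, self.train_config)
        return PosteriorResult(model=self, flow=flow, history=history)


class PosteriorResult:
    """Trained posterior estimator with sampling, density, and summaries."""

    def __init__(self, model: NeuralPosterior, flow, history):
        self.model = model
        self.flow = flow
        self.history = history
        self.prior = model.data.prior

    def log_prob(self, theta: np.ndarray, x_obs: np.ndarray) -> np.ndarray:
        """log q(theta | x_obs) under the trained flow."""
        x = self.model._standardize(self._as_features(x_obs))
        theta = np.atleast_2d(theta)
        return self.flow.log_prob(theta, np.broadcast_to(x, (theta.shape[0], x.shape[1])))

    def log_prob_grad(self, theta: np.ndarray, x_obs: np.ndarray):
        x = self.model._standardize(self._as_features(x_obs))
        theta = np.atleast_2d(theta)
        return self.flow.log_prob_grad(
            theta, np.broadcast_to(x, (theta.shape[0], x.shape[1]))
        )

    @staticmethod
    def _as_features(x_obs) -> np.ndarray:
        if isinstance(x_obs, FeatureVector):
            return x_obs.values
        return np.asarray(x_obs, dtype=float)

    def sample(
        self,
        x_obs,
        n_draws: int = 1000,
        seed: int = 0,
        max_tries: int = 50,
    ) -> PosteriorSamples:
        """Draw from q(theta | x_obs), rejecting draws outside the prior box.

        The acceptance fraction is reported; below 1% the posterior mass has
        leaked outside the prior support and an error is raised.
        """
        x = self.model._standardize(self._as_features(x_obs))[0]
        if n_draws == 0:
            return PosteriorSamples(
                samples=np.zeros((0, self.prior.dim)), x_obs=x,
                acceptance_fraction=1.0, names=self.prior.names,
            )
        rng = np.random.default_rng(seed)
        out: list[np.ndarray] = []
        proposed = accepted = 0
        for _ in range(max_tries):
            batch = self.flow.sample(n_draws, x, rng)
            ok = self.prior.contains(batch)
            proposed += len(batch)
            accepted += int(ok.sum())
            out.append(batch[ok])
            if sum(len(o) for o in out) >= n_draws:
                break
            if proposed >= 5 * n_draws and accepted / proposed < 0.01:
                raise LeakageError(
                    f"acceptance fraction {accepted / proposed:.4f} < 1%: "
                    "posterior mass leaked outside the prior support"
                )
        samples = np.concatenate(out)[:n_draws]
        if samples.shape[0] < n_draws:
            raise LeakageError(
                f"could not draw {n_draws} in-support samples "
                f"(acceptance {accepted / max(proposed, 1):.4f})"
            )
        return PosteriorSamples(
            samples=samples, x_obs=x,
            acceptance_fraction=accepted / proposed, names=self.prior.names,
        )

    def summary(self, x_obs, n_draws: int = 2000, seed: int = 0,
                theta_true: np.ndarray | None = None) -> str:
        """Plain-text posterior summary table for one observation."""
        ps = self.sample(x_obs, n_draws=n_draws, seed=seed)
        q05, q50, q95 = np.percentile(ps.samples, [5, 50, 95], axis=0)
        mean, sd = ps.mean(), ps.std()
        shrink = 1.0 - ps.samples.var(axis=0) / self.prior.variance
        lines = [
            f"Posterior summary ({self.flow.family}, "
            f"{self.model.data.n_sim} training simulations, "
            f"{ps.n_draws} draws, acceptance {ps.acceptance_fraction:.3f})",
            "-" * 78,
            f"{'parameter':<14}{'mean':>9}{'sd':>9}{'5%':>9}{'50%':>9}"
            f"{'95%':>9}{'shrinkage':>11}"
            + ("{:>9}".format("z") if theta_true is not None else ""),
        ]
        for j, name in enumerate(self.prior.names):
            row = (f"{name:<14}{mean[j]:>9.4g}{sd[j]:>9.3g}{q05[j]:>9.4g}"
                   f"{q50[j]:>9.4g}{q95[j]:>9.4g}{shrink[j]:>11.3f}")
            if theta_true is not None:
                z = abs((mean[j] - theta_true[j]) / sd[j]) if sd[j] > 0 else np.inf
                row += f"{z:>9.2f}"
            lines.append(row)
        return "\n".join(lines)


def train_posterior_estimator(
    data: TrainingDataset,
    family: str = "MAF",
    train_config: TrainConfig | None = None,
    **kwargs,
) -> PosteriorResult:
    """Functional wrapper: build a NeuralPosterior and fit it."""
    return NeuralPosterior(data, family=family, train_config=train_config,
                           **kwargs).fit()


def sample_posterior(
    est: PosteriorResult, x_obs, n_draws: int = 1000, seed: int = 0
) -> PosteriorSamples:
    """Functional wrapper over PosteriorResult.sample."""
    return est.sample(x_obs, n_draws=n_draws, seed=seed)
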