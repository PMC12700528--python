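"""Priors, simulation batches, estimator fitting, and posterior sampling."""

import numpy as np
import pytest

from braininv.errors import (
    DatasetQualityError,
    LeakageError,
    PreconditionError,
    ValidationError,
)
from braininv.features import FeatureVector, build_feature_recipe
from braininv.flows import TrainConfig
from braininv.inference import (
    NeuralPosterior,
    PosteriorSamples,
    PriorSpec,
    TrainingDataset,
    run_simulation_batch,
    sample_posterior,
    sample_prior,
    train_posterior_estimator,
)


class TestPrior:
    def test_sample_mean_clt_bound(self):
        prior = PriorSpec(("u",), [0.0], [1.0])
        draws = sample_prior(prior, 100_000, seed=1)
        assert abs(draws.mean() - 0.5) < 0.005

    def test_single_draw_in_bounds(self):
        prior = PriorSpec(("G", "eta"), [0.0, -6.0], [1.0, -3.5])
        d = sample_prior(prior, 1, seed=0)
        assert prior.contains(d)[0]

    def test_named_box_bounds(self):
        prior = PriorSpec(("G", "eta"), [0.0, -6.0], [1.0, -3.5])
        d = sample_prior(prior, 1000, seed=3)
        assert d[:, 0].min() >= 0 and d[:, 0].max() <= 1
        assert d[:, 1].min() >= -6 and d[:, 1].max() <= -3.5

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValidationError):
            PriorSpec(("a",), [1.0], [0.0])

    def test_uniform_variance_formula(self):
        prior = PriorSpec(("a", "b"), [0.0, -6.0], [3.0, -3.5])
        np.testing.assert_allclose(prior.variance,
                                   [(3.0**2) / 12, (2.5**2) / 12])


def _toy_simulator(theta, seed):
    """Deterministic stand-in simulator returning features directly."""
    class R:
        pass

    rng = np.random.default_rng(seed)
    r = R()
    r.values = np.concatenate([theta, rng.normal(size=1)])
    return r


class _PassthroughRecipe:
    recipe_id = "passthrough"

    def apply(self, r):
        return FeatureVector(r.values, [f"f{i}" for i in range(len(r.values))],
                             self.recipe_id)


class TestBatch:
    def test_bookkeeping(self):
        prior = PriorSpec(("a", "b"), [0, 0], [1, 1])
        ds = run_simulation_batch(_toy_simulator, prior, 4, _PassthroughRecipe(),
                                  seed=0)
        assert ds.theta.shape == (4, 2)
        assert ds.features.shape == (4, 3)

    def test_master_seed_determinism(self):
        prior = PriorSpec(("a", "b"), [0, 0], [1, 1])
        a = run_simulation_batch(_toy_simulator, prior, 10, _PassthroughRecipe(), seed=5)
        b = run_simulation_batch(_toy_simulator, prior, 10, _PassthroughRecipe(), seed=5)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.features, b.features)

    def test_bad_rows_filtered_in_order(self):
        def flaky(theta, seed):
            if theta[0] > 0.7:
                raise RuntimeError("diverged")
            return _toy_simulator(theta, seed)

        prior = PriorSpec(("a",), [0.0], [1.0])
        ds = run_simulation_batch(flaky, prior, 60, _PassthroughRecipe(), seed=2)
        assert ds.n_sim < 60
        assert np.all(ds.theta[:, 0] <= 0.7)
        # surviving rows keep their original relative order
        full = sample_prior(prior, 60, seed=2)
        kept = full[full[:, 0] <= 0.7]
        np.testing.assert_array_equal(ds.theta, kept)

    def test_mostly_bad_batch_rejected(self):
        def broken(theta, seed):
            raise RuntimeError("boom")

        prior = PriorSpec(("a",), [0.0], [1.0])
        with pytest.raises(DatasetQualityError):
            run_simulation_batch(broken, prior, 20, _PassthroughRecipe(), seed=0)


class TestEstimator:
    def test_minimum_dataset_floor(self, toy_problem):
        ds = TrainingDataset(toy_problem["theta"][:50], toy_problem["x"][:50],
                             toy_problem["prior"])
        with pytest.raises(PreconditionError):
            NeuralPosterior(ds, min_sims=100)

    def test_zero_variance_features_dropped(self, toy_problem):
        th, x = toy_problem["theta"][:300], toy_problem["x"][:300]
        x_aug = np.column_stack([x, np.full(300, 3.14)])
        ds = TrainingDataset(th, x_aug, toy_problem["prior"],
                             feature_names=["a", "b", "const"])
        model = NeuralPosterior(ds)
        assert model.feature_keep.tolist() == [True, True, False]

    def test_standardization_round_trip(self, toy_problem):
        th, x = toy_problem["theta"][:300], toy_problem["x"][:300]
        ds = TrainingDataset(th, x, toy_problem["prior"])
        model = NeuralPosterior(ds)
        z = model._standardize(x)
        back = z * model.feature_std + model.feature_mean
        np.testing.assert_allclose(back, x, atol=1e-12)

    def test_self_consistency_on_held_in_pairs(self, toy_problem):
        """Density at a training pair's own theta beats the prior-mean theta."""
        ds = TrainingDataset(toy_problem["theta"], toy_problem["x"],
                             toy_problem["prior"])
        est = train_posterior_estimator(
            ds, train_config=TrainConfig(seed=1, max_epochs=80, patience=20))
        wins = 0
        center = np.zeros(2)
        for i in range(50):
            lp_truth = est.log_prob(ds.theta[i], ds.features[i])[0]
            lp_center = est.log_prob(center, ds.features[i])[0]
            wins += lp_truth > lp_center
        assert wins >= 35  # most pairs concentrate near their own parameters

    def test_amortized_conditioning_without_retraining(self, toy_problem):
        ds = TrainingDataset(toy_problem["theta"][:1500], toy_problem["x"][:1500],
                             toy_problem["prior"])
        est = train_posterior_estimator(
            ds, train_config=TrainConfig(seed=1, max_epochs=40, patience=10))
        s1 = est.sample([1.0, 1.0], n_draws=300, seed=0)
        s2 = est.sample([-1.0, -1.0], n_draws=300, seed=0)
        assert abs(s1.samples[:, 0].mean() - s2.samples[:, 0].mean()) > 0.5

    def test_empty_draw_request(self, toy_problem):
        ds = TrainingDataset(toy_problem["theta"][:300], toy_problem["x"][:300],
                             toy_problem["prior"])
        est = train_posterior_estimator(
            ds, train_config=TrainConfig(seed=1, max_epochs=10, patience=5))
        s = sample_posterior(est, [0.0, 0.0], n_draws=0)
        assert s.samples.shape == (0, 2)
        assert s.acceptance_fraction == 1.0

    def test_samples_respect_prior_support(self, toy_problem, ):
        ds = TrainingDataset(toy_problem["theta"][:1000], toy_problem["x"][:1000],
                             toy_problem["prior"])
        est = train_posterior_estimator(
            ds, train_config=TrainConfig(seed=1, max_epochs=30, patience=10))
        s = est.sample([1.9, -1.9], n_draws=500, seed=3)  # near the box corner
        assert toy_problem["prior"].contains(s.samples).all()
        assert s.n_draws == 500

    def test_leakage_escalates_to_error(self, toy_problem):
        ds = TrainingDataset(toy_problem["theta"][:1000], toy_problem["x"][:1000],
                             toy_problem["prior"])
        est = train_posterior_estimator(
            ds, train_config=TrainConfig(seed=1, max_epochs=10, patience=5))

        # estimator whose conditional mass sits almost entirely outside the
        # prior box: <1% acceptance must escalate to an error
        def leaky_sample(n, x, rng):
            return rng.normal(10.0, 0.5, size=(n, 2))

        est.flow.sample = leaky_sample
        with pytest.raises(LeakageError):
            est.sample([0.0, 0.0], n_draws=500, seed=3)

    def test_summary_table_contents(self, toy_problem):
        ds = TrainingDataset(toy_problem["theta"][:500], toy_problem["x"][:500],
                             toy_problem["prior"])
        est = train_posterior_estimator(
            ds, train_config=TrainConfig(seed=1, max_epochs=15, patience=5))
        text = est.summary([0.5, -0.5], n_draws=200, theta_true=[0.5, -0.5])
        assert "shrinkage" in text
        assert "a" in text and "b" in text
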