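"""Feature extraction: FC, FCD, PSD summaries, moments, seizure envelopes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from braininv.errors import DegenerateInputError, PreconditionError, RecipeError
from braininv.features import (
    FeatureRecipe,
    FeatureVector,
    build_feature_recipe,
    fc_matrix,
    fcd_matrix,
    fcd_fc_summary,
    psd_summary,
    seizure_features,
    stat_moments,
)


class TestFC:
    def test_identical_rows_perfectly_correlated(self):
        x = np.sin(np.linspace(0, 10, 200))
        fc = fc_matrix(np.vstack([x, x, np.cos(np.linspace(0, 10, 200))]))
        assert fc[0, 1] == pytest.approx(1.0)

    def test_negated_row_anticorrelated(self):
        x = np.sin(np.linspace(0, 10, 200))
        fc = fc_matrix(np.vstack([x, -x]))
        assert fc[0, 1] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        fc = fc_matrix(rng.standard_normal((4, 10_000)))
        assert np.abs(fc[np.triu_indices(4, 1)]).max() < 0.05

    def test_constant_row_names_region(self):
        x = np.vstack([np.ones(100), np.random.default_rng(0).standard_normal(100)])
        with pytest.raises(DegenerateInputError, match="region 0"):
            fc_matrix(x)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        fc = fc_matrix(rng.standard_normal((5, 60)))
        assert fc.min() >= -1.0 - 1e-12
        assert fc.max() <= 1.0 + 1e-12
        np.testing.assert_allclose(fc, fc.T)


class TestFCD:
    def test_stationary_signal_all_windows_alike(self):
        t = np.arange(4000) * 1e-3
        states = np.vstack([np.sin(2 * np.pi * 7 * t + ph)
                            for ph in (0.0, 0.8, 1.6, 2.4)])
        fcd = fcd_matrix(states, window=500, stride=250)
        assert fcd.matrix.min() > 0.9

    def test_coupling_flip_creates_block_structure(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(4000)
        a = base + 0.1 * rng.standard_normal(4000)
        b = np.concatenate([base[:2000], -base[2000:]]) + 0.1 * rng.standard_normal(4000)
        fcd = fcd_matrix(np.vstack([a, b, rng.standard_normal(4000)]),
                         window=400, stride=200)
        W = fcd.matrix.shape[0]
        half = W // 2
        within = np.concatenate([fcd.matrix[:half, :half].ravel(),
                                 fcd.matrix[half:, half:].ravel()])
        between = fcd.matrix[:half, half:].ravel()
        assert between.mean() < within.mean()

    def test_window_equals_length_trivial(self):
        x = np.random.default_rng(0).standard_normal((3, 64))
        fcd = fcd_matrix(x, window=64, stride=10)
        np.testing.assert_array_equal(fcd.matrix, [[1.0]])

    def test_too_short_series(self):
        with pytest.raises(PreconditionError):
            fcd_matrix(np.zeros((3, 30)), window=25, stride=10)


class TestPSD:
    def test_pure_tone_peak(self):
        t = np.arange(10_000) / 1000.0
        x = np.sin(2 * np.pi * 40 * t)[None, :]
        fv = psd_summary(x, fs=1000.0)
        peak = fv.values[fv.names.index("psd_peak_freq_r0")]
        assert abs(peak - 40.0) <= 0.5

    def test_parseval_total_power(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 50_000))
        fv = psd_summary(x, fs=100.0)
        total = fv.values[fv.names.index("psd_total_power_r0")]
        assert total == pytest.approx(x.var(), rel=0.05)

    def test_two_tone_band_power_ratio(self):
        t = np.arange(20_000) / 1000.0
        x = (2 * np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 40 * t))[None, :]
        fv = psd_summary(x, fs=1000.0, bands=[(5, 15), (35, 45)])
        p10 = fv.values[fv.names.index("psd_band_5_15_r0")]
        p40 = fv.values[fv.names.index("psd_band_35_45_r0")]
        peak = fv.values[fv.names.index("psd_peak_freq_r0")]
        assert abs(peak - 10.0) <= 0.5
        assert p40 / p10 == pytest.approx(0.25, rel=0.05)

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateInputError):
            psd_summary(np.zeros((2, 100)), fs=10.0)

    def test_log_power_scale(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((1, 8000))
        lin = psd_summary(x, fs=100.0)
        log = psd_summary(x, fs=100.0, log_power=True)
        i = lin.names.index("psd_total_power_r0")
        assert log.values[i] == pytest.approx(np.log10(lin.values[i]), abs=1e-9)
        # frequency-valued summaries are untouched by the power scale
        j = lin.names.index("psd_peak_freq_r0")
        assert log.values[j] == lin.values[j]

    def test_pooled_summaries(self):
        t = np.arange(8000) / 1000.0
        x = np.vstack([np.sin(2 * np.pi * 40 * t + ph) for ph in (0, 1, 2)])
        fv = psd_summary(x, fs=1000.0, pooled=True)
        # identical spectra: pooled peak at the tone, zero across-region SD
        assert fv.values[fv.names.index("psd_peak_freq_pooled")] == pytest.approx(40.0, abs=0.5)
        assert fv.values[fv.names.index("psd_peak_freq_rsd")] == pytest.approx(0.0, abs=1e-9)
        assert len(fv) == 15  # 5 base summaries x (pooled, rmean, rsd)


class TestMoments:
    def test_constant_signal_degenerate_convention(self):
        fv = stat_moments(np.ones((1, 100)))
        assert fv.values[fv.names.index("var_r0")] == 0.0
        assert fv.values[fv.names.index("skew_r0")] == 0.0
        assert fv.values[fv.names.index("kurt_r0")] == 0.0

    def test_standard_normal_sample(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 100_000))
        fv = stat_moments(x)
        se_mean = 1 / np.sqrt(100_000)
        assert abs(fv.values[0]) < 3 * se_mean
        assert fv.values[1] == pytest.approx(1.0, abs=3 * np.sqrt(2 / 100_000))

    def test_affine_transform_moment_algebra(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(size=(1, 5000))
        a = stat_moments(x)
        b = stat_moments(2 * x + 1)
        assert b.values[0] == pytest.approx(2 * a.values[0] + 1)
        assert b.values[2] == pytest.approx(a.values[2], rel=1e-9)  # skew invariant


class TestSeizureFeatures:
    def test_flat_signal_sentinel(self):
        fv = seizure_features(np.zeros((1, 1000)), dt=0.1)
        assert fv.values[fv.names.index("sz_onset_r0")] == pytest.approx(100.0)
        assert fv.values[fv.names.index("sz_power_r0")] == pytest.approx(0.0, abs=1e-12)

    def test_step_burst_onset_detection(self):
        rng = np.random.default_rng(5)
        T, dt = 6000, 0.01
        x = 0.01 * rng.standard_normal(T)
        start = 3000  # burst begins at t = 30
        x[start:] += np.sin(2 * np.pi * 10 * np.arange(T - start) * dt) * 2
        fv = seizure_features(x[None, :], dt=dt)
        onset = fv.values[fv.names.index("sz_onset_r0")]
        smoothing = 0.01 * T * dt
        assert 30.0 - smoothing <= onset <= 30.0 + 2 * smoothing

    def test_power_quadratic_in_amplitude(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, 5000))
        p1 = seizure_features(x, dt=0.1).values[0]
        p2 = seizure_features(2 * x, dt=0.1).values[0]
        assert p2 == pytest.approx(4 * p1, rel=1e-9)


class TestFCDFCSummary:
    def test_identity_fc_zero_mean(self):
        from braininv.features import FCDMatrix

        fv = fcd_fc_summary(np.eye(5), FCDMatrix(np.ones((2, 2)), 10, 5))
        assert fv.values[fv.names.index("fc_mean")] == 0.0

    def test_all_ones_fc(self):
        from braininv.features import FCDMatrix

        fv = fcd_fc_summary(np.ones((5, 5)), FCDMatrix(np.ones((2, 2)), 10, 5))
        assert fv.values[fv.names.index("fc_mean")] == 1.0
        assert fv.values[fv.names.index("fc_var")] == 0.0

    def test_planted_two_community_first_component(self):
        from braininv.features import PCAProjector

        rng = np.random.default_rng(7)
        iu = np.triu_indices(6, 1)
        vecs = []
        for _ in range(50):
            strength = rng.uniform(0.3, 0.9)  # community strength varies
            fc = np.ones((6, 6)) * 0.1
            fc[:3, :3] = strength
            fc[3:, 3:] = strength
            fc += rng.normal(0, 0.02, fc.shape)
            fc = (fc + fc.T) / 2
            np.fill_diagonal(fc, 1.0)
            vecs.append(fc[iu])
        proj = PCAProjector(2).fit(np.array(vecs))
        comp = proj.components[0]
        within_mask = np.array([(i < 3) == (j < 3) for i, j in zip(*iu)])
        within = comp[within_mask]
        between = comp[~within_mask]
        # loading signs separate within- from between-community pairs
        assert np.sign(within.mean()) != np.sign(between.mean())


class TestRecipes:
    def test_empty_recipe_zero_length(self, sc5):
        from braininv.models import WilsonCowanParams, simulate_wilson_cowan

        r = simulate_wilson_cowan(sc5, WilsonCowanParams(), duration=10.0,
                                  dt=0.05, seed=0)
        fv = build_feature_recipe({}).apply(r)
        assert len(fv) == 0

    def test_deterministic_application(self, sc5):
        from braininv.models import WilsonCowanParams, simulate_wilson_cowan

        r = simulate_wilson_cowan(sc5, WilsonCowanParams(P=1.0), duration=40.0,
                                  dt=0.05, seed=1)
        recipe = build_feature_recipe({"psd_summary": {"bands": [(0.1, 1.0)]},
                                       "stat_moments": {}})
        a, b = recipe.apply(r), recipe.apply(r)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.names == b.names

    def test_declared_arity_arithmetic(self, sc5):
        # psd: N x (5 + len(bands)); moments: N x 4
        from braininv.models import WilsonCowanParams, simulate_wilson_cowan

        r = simulate_wilson_cowan(sc5, WilsonCowanParams(P=1.0), duration=40.0,
                                  dt=0.05, seed=1)
        n_bands = 2
        recipe = build_feature_recipe(
            {"psd_summary": {"bands": [(0.1, 0.5), (0.5, 1.0)]}, "stat_moments": {}}
        )
        fv = recipe.apply(r)
        N = sc5.n_regions
        assert len(fv) == N * (5 + n_bands) + N * 4

    def test_unknown_extractor_rejected(self):
        with pytest.raises(RecipeError):
            build_feature_recipe({"not_an_extractor": {}})

    def test_region_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((4, 2000))
        perm = [2, 0, 3, 1]
        a = stat_moments(x).values.reshape(4, 4)
        b = stat_moments(x[perm]).values.reshape(4, 4)
        np.testing.assert_allclose(b, a[perm])

    def test_nonfinite_features_hard_failure(self):
        from braininv.errors import ValidationError

        with pytest.raises(ValidationError):
            FeatureVector(np.array([1.0, np.nan]), ["a", "b"])
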