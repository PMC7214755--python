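import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from kinlatent import (
    DimensionVarianceProfile,
    dimension_variance,
    linear_r2,
    range_of_dimension_variance,
    signal_variance,
    vaf,
)
from kinlatent.metrics import MetricError


class TestVAF:
    def test_identical_reconstruction_is_exactly_100(self, rng):
        Y = rng.standard_normal((200, 20))
        result = vaf(Y, Y.copy())
        assert result.aggregate_vaf == 100.0
        np.testing.assert_array_equal(result.per_channel_vaf, 100.0)

    def test_column_mean_reconstruction_is_0(self, rng):
        Y = rng.standard_normal((500, 4))
        Yhat = np.tile(Y.mean(axis=0), (500, 1))
        assert vaf(Y, Yhat).aggregate_vaf == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_single_channel(self):
        # var(Y - Yhat) = 1, var(Y) = 4 with the m-1 denominator
        Y = np.array([0.0, 2.0, 4.0])
        Yhat = np.array([0.0, 3.0, 3.0])
        assert vaf(Y, Yhat).aggregate_vaf == pytest.approx(75.0)

    def test_invariant_to_common_constant_shift(self, rng):
        Y = rng.standard_normal((100, 3))
        Yhat = Y + 0.1 * rng.standard_normal((100, 3))
        a = vaf(Y, Yhat).aggregate_vaf
        b = vaf(Y + 7.0, Yhat + 7.0).aggregate_vaf
        assert a == pytest.approx(b, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(
        data=hnp.arrays(
            float,
            st.tuples(st.integers(3, 30), st.integers(1, 6)),
            elements=st.floats(-100, 100),
        ),
        scale=st.floats(0.01, 10),
    )
    def test_aggregate_never_exceeds_100(self, data, scale):
        rng = np.random.default_rng(0)
        if np.var(data, axis=0).sum() == 0:
            return
        noisy = data + scale * rng.standard_normal(data.shape)
        assert vaf(data, noisy).aggregate_vaf <= 100.0

    def test_zero_variance_channel_flagged_not_fatal(self, rng):
        Y = rng.standard_normal((50, 3))
        Y[:, 1] = 2.0
        result = vaf(Y, Y * 0.9)
        assert result.degenerate_channels == [1]
        assert np.isnan(result.per_channel_vaf[1])
        assert np.isfinite(result.aggregate_vaf)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(MetricError):
            vaf(np.zeros((3, 2)), np.zeros((3, 3)))


class TestSignalVariance:
    def test_mean_of_channel_variances(self):
        X = np.array([[0.0, 1.0], [2.0, 1.0], [4.0, 1.0]])
        # channel variances 4 and 0 -> mean 2
        assert signal_variance(X) == pytest.approx(2.0)

    def test_constant_matrix_is_zero(self):
        assert signal_variance(np.full((10, 5), 3.3)) == 0.0

    def test_quadratic_scaling(self, rng):
        X = rng.standard_normal((100, 4))
        assert signal_variance(3.0 * X) == pytest.approx(9.0 * signal_variance(X))


class TestDimensionVariance:
    def test_9_to_1_gives_90_10(self, rng):
        n = 100_000
        A = np.column_stack([3.0 * rng.standard_normal(n), rng.standard_normal(n)])
        profile = dimension_variance(A)
        np.testing.assert_allclose(profile.v_dim, [90.0, 10.0], atol=0.5)
        assert profile.range == pytest.approx(80.0, abs=1.0)

    def test_equal_variance_columns_are_uniform(self, rng):
        A = rng.standard_normal((20_000, 4))
        profile = dimension_variance(A)
        np.testing.assert_allclose(profile.v_dim, 25.0, atol=1.5)

    def test_sums_to_100_and_sorted_descending(self, rng):
        A = rng.standard_normal((50, 6)) * rng.uniform(0.1, 5, 6)
        profile = dimension_variance(A)
        assert profile.v_dim.sum() == pytest.approx(100.0, abs=1e-8)
        assert (np.diff(profile.v_dim) <= 0).all()

    def test_permutation_invariant_up_to_sorting(self, rng):
        A = rng.standard_normal((60, 5)) * np.arange(1, 6)
        shuffled = A[:, rng.permutation(5)]
        np.testing.assert_allclose(
            dimension_variance(A).v_dim, dimension_variance(shuffled).v_dim, atol=1e-9
        )

    def test_zero_variance_latent_rejected(self):
        with pytest.raises(MetricError):
            dimension_variance(np.ones((10, 3)))

    def test_anisotropic_cloud_steeper_than_its_isotropized_rotation(self, rng):
        """Variance-ordered projections concentrate variance; whitening the
        same cloud flattens the profile."""
        A = rng.standard_normal((5000, 4)) * np.array([3.0, 1.5, 1.0, 0.5])
        cov = np.cov(A, rowvar=False)
        white = A @ np.linalg.inv(np.linalg.cholesky(cov)).T
        assert dimension_variance(A).range > dimension_variance(white).range


class TestRangeOfDimensionVariance:
    def test_single_profile(self):
        assert range_of_dimension_variance(
            [DimensionVarianceProfile(np.array([90.0, 10.0]))]
        ) == pytest.approx(80.0)

    def test_mean_over_profiles(self):
        profiles = [
            DimensionVarianceProfile(np.array([80.0, 20.0])),
            DimensionVarianceProfile(np.array([60.0, 40.0])),
        ]
        assert range_of_dimension_variance(profiles) == pytest.approx(40.0)

    def test_uniform_profiles_give_zero(self):
        profiles = [DimensionVarianceProfile(np.array([50.0, 50.0]))] * 3
        assert range_of_dimension_variance(profiles) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(MetricError):
            range_of_dimension_variance([])


class TestLinearR2:
    def test_perfect_line(self):
        x = np.arange(10.0)
        r2, slope, intercept = linear_r2(x, 2 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_independent_noise_has_near_zero_r2(self, rng):
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        r2, _, _ = linear_r2(x, y)
        assert r2 < 0.01

    def test_negative_slope(self):
        x = np.linspace(0, 1, 20)
        r2, slope, _ = linear_r2(x, -x)
        assert r2 == pytest.approx(1.0)
        assert slope < 0

    def test_constant_x_rejected(self):
        with pytest.raises(MetricError):
            linear_r2(np.ones(5), np.arange(5.0))
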