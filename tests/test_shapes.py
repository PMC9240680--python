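import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dentdist.shapes import (
    DentalDistribution,
    InsufficientSampleError,
    ShapeVector,
    bootstrap_shape_uncertainty,
    compute_shape_vector,
    error_epsilon,
    estimate_modes,
)

RNG = np.random.default_rng(20220808)


@pytest.fixture(scope="module")
def gaussian_sample():
    return DentalDistribution(values=RNG.normal(18.9, 2.9, 5000), site_label="g")


@pytest.fixture(scope="module")
def mixture_sample():
    comp = RNG.random(5000) < 0.5
    vals = np.where(comp, RNG.normal(10, 1, 5000), RNG.normal(20, 1, 5000))
    return DentalDistribution(values=vals, site_label="mix")


class TestModeDetection:
    def test_unimodal_gaussian(self, gaussian_sample):
        modes = estimate_modes(gaussian_sample)
        assert modes.count == 1
        assert modes.locations[0] == pytest.approx(18.9, abs=0.5)

    def test_separated_mixture(self, mixture_sample):
        modes = estimate_modes(mixture_sample)
        assert modes.count == 2
        assert modes.locations[0] == pytest.approx(10.0, abs=0.5)
        assert modes.locations[1] == pytest.approx(20.0, abs=0.5)

    def test_degenerate_sample_single_mode(self):
        d = DentalDistribution(values=np.full(50, 12.3))
        modes = estimate_modes(d)
        assert modes.count == 1
        assert modes.locations[0] == pytest.approx(12.3)

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            estimate_modes(DentalDistribution(values=np.ones(5) * 9.0))

    def test_histogram_count_scaling_invariance(self):
        edges = np.linspace(5, 30, 61)
        c = np.exp(-0.5 * ((0.5 * (edges[:-1] + edges[1:]) - 12) / 2) ** 2)
        c += 0.6 * np.exp(-0.5 * ((0.5 * (edges[:-1] + edges[1:]) - 24) / 1.5) ** 2)
        m1 = estimate_modes(DentalDistribution(bin_edges=edges, counts=100 * c))
        m2 = estimate_modes(DentalDistribution(bin_edges=edges, counts=70000 * c))
        assert m1.count == m2.count == 2
        assert np.allclose(m1.locations, m2.locations)


class TestShapeVector:
    def test_normal_quantiles_closed_form(self, gaussian_sample):
        sv = compute_shape_vector(gaussian_sample)
        mu, sd = 18.9, 2.9
        assert sv.mean == pytest.approx(mu, abs=3 * sd / np.sqrt(5000) * 3)
        assert sv.p25 == pytest.approx(mu - 0.6745 * sd, abs=0.2)
        assert sv.median == pytest.approx(mu, abs=0.2)
        assert sv.p75 == pytest.approx(mu + 0.6745 * sd, abs=0.2)
        assert sv.n_modes == 1 and sv.delta_mode == 0.0

    def test_mixture_mode_separation(self, mixture_sample):
        sv = compute_shape_vector(mixture_sample)
        assert sv.n_modes == 2
        assert sv.delta_mode == pytest.approx(10.0, abs=1.0)

    def test_percentile_ordering_invariant(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            sv = compute_shape_vector(
                DentalDistribution(values=r.gamma(4.0, 3.0, 300) + 1))
            assert sv.p25 <= sv.median <= sv.p75
            assert (sv.n_modes == 1) == (sv.delta_mode == 0.0)

    def test_invalid_vectors_rejected(self):
        with pytest.raises(ValueError):
            ShapeVector(10, 4, 12, 11, 13, 1, 0)  # p25 > median
        with pytest.raises(ValueError):
            ShapeVector(10, 4, 9, 10, 11, 2, 0)  # bimodal with zero delta


class TestErrorEpsilon:
    def _vec(self, scale=1.0):
        return ShapeVector(mean=16.0 * scale, variance=20.0 * scale,
                           p25=12.0 * scale, median=16.0 * scale,
                           p75=19.0 * scale, n_modes=2 * scale,
                           delta_mode=8.0 * scale)

    def test_identity(self):
        assert error_epsilon(self._vec(), self._vec()) == 0.0

    def test_uniform_offset(self):
        """1.5x on all seven components gives epsilon = 7 * 0.5 = 3.5."""
        assert error_epsilon(self._vec(1.5), self._vec()) == pytest.approx(3.5)

    def test_zero_denominator_rule(self):
        obs = ShapeVector(16.0, 20.0, 12.0, 16.0, 19.0, 1, 0.0)
        sim = ShapeVector(16.0, 20.0, 12.0, 16.0, 19.0, 2, 2.0)
        # n_modes term |2-1|/1, delta term |2-0|/max(0, 0.1) = 20
        assert error_epsilon(sim, obs) == pytest.approx(1.0 + 20.0)

    @given(st.floats(0.55, 5.0), st.floats(0.55, 5.0))
    @settings(deadline=None, max_examples=40)
    def test_nonnegative_and_monotone(self, a, b):
        obs = self._vec()
        ea = error_epsilon(self._vec(a), obs)
        eb = error_epsilon(self._vec(b), obs)
        assert ea >= 0 and eb >= 0
        if abs(a - 1) <= abs(b - 1):  # uniformly closer to obs
            assert ea <= eb + 1e-12


class TestBootstrap:
    def test_se_of_mean_matches_closed_form(self):
        r = np.random.default_rng(7)
        d = DentalDistribution(values=r.normal(13.7, 3.4, 400))
        table = bootstrap_shape_uncertainty(d, B=400, seed=1)
        assert table.loc["mean", "se"] == pytest.approx(3.4 / 20.0, rel=0.2)
        est = table.loc["mean", "estimate"]
        assert table.loc["mean", "ci_low"] < est < table.loc["mean", "ci_high"]

    def test_degenerate_sample_zero_spread(self):
        d = DentalDistribution(values=np.full(60, 15.0))
        table = bootstrap_shape_uncertainty(d, B=100, seed=0)
        assert np.allclose(table["se"], 0.0)

    def test_too_few_replicates_rejected(self):
        d = DentalDistribution(values=np.linspace(8, 20, 50))
        with pytest.raises(ValueError):
            bootstrap_shape_uncertainty(d, B=50, seed=0)


class TestDistributionContainer:
    def test_histogram_and_raw_mutually_exclusive(self):
        with pytest.raises(ValueError):
            DentalDistribution(values=np.ones(5),
                               bin_edges=np.arange(6.0), counts=np.ones(5))
        with pytest.raises(ValueError):
            DentalDistribution()

    def test_histogram_quantiles_within_bin_interpolation(self):
        # uniform counts on [10, 20): quartiles at 12.5 / 15 / 17.5
        edges = np.linspace(10, 20, 11)
        d = DentalDistribution(bin_edges=edges, counts=np.full(10, 5.0))
        sv = compute_shape_vector(d)
        assert sv.p25 == pytest.approx(12.5)
        assert sv.median == pytest.approx(15.0)
        assert sv.p75 == pytest.approx(17.5)
        assert sv.mean == pytest.approx(15.0)
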