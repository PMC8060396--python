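"""Synthetic landscape, virtual species and generative outcome model."""

import numpy as np
import pytest
from scipy.special import logit

from nichemargin import (
    calibrate_env_space,
    generate_climate,
    generate_species,
    kde_envelope,
    simulate_introductions,
    simulate_model_data,
    SimulationTruth,
)
from nichemargin.synthetic import gradient_field


@pytest.fixture(scope="module")
def landscape():
    stack = generate_climate((40, 80), seed=101)
    space = calibrate_env_space(stack)
    return stack, space


class TestGenerateClimate:
    def test_zero_noise_equals_gradient_formula(self):
        stack = generate_climate((20, 30), noise_sd=0.0, amplitudes=2 * np.ones(8), seed=0)
        lon = stack.lon_centers()
        lat = stack.lat_centers()
        ln = 2 * (lon - (-180)) / 360 - 1
        lt = 2 * (lat - (-90)) / 180 - 1
        XX, YY = np.meshgrid(ln, lt)
        for k in range(8):
            np.testing.assert_allclose(stack.values[k], 2 * gradient_field(k, XX, YY), atol=1e-12)

    def test_same_seed_identical_stacks(self):
        a = generate_climate((16, 16), seed=7)
        b = generate_climate((16, 16), seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_band_moments_match_requested_parameters(self):
        means = np.array([5.0, -1.0, 0.0, 10.0, 2.0, 0.0, 1.0, 3.0])
        stack = generate_climate((60, 120), means=means, noise_sd=0.05, seed=3)
        lon_n = 2 * (stack.lon_centers() + 180) / 360 - 1
        lat_n = 2 * (stack.lat_centers() + 90) / 180 - 1
        XX, YY = np.meshgrid(lon_n, lat_n)
        for k in range(8):
            expected = means[k] + gradient_field(k, XX, YY).mean()
            assert stack.values[k].mean() == pytest.approx(expected, abs=0.05)

    def test_mask_fraction(self):
        stack = generate_climate((50, 50), mask_fraction=0.3, seed=5)
        assert 0.6 < stack.mask.mean() < 0.8


class TestGenerateSpecies:
    def test_level_one_with_broad_covariance_covers_all_pixels(self, landscape):
        stack, space = landscape
        sp = generate_species(stack, space, center=[0, 0], covariance=100 * np.eye(2), level=1.0)
        assert len(sp.pixel_ids) == stack.mask.sum()

    def test_estimated_envelope_overlaps_analytic_truth(self):
        # a niche wide relative to the KDE bandwidth, so the estimated
        # envelope is not dominated by boundary smoothing
        stack = generate_climate((60, 120), seed=101)
        space = calibrate_env_space(stack)
        from nichemargin import project

        scores = project(stack, space)
        med = np.median(scores.coords, axis=0)
        sp = generate_species(stack, space, center=med, covariance=0.5 * np.eye(2), level=0.99)
        sel = np.isin(scores.ids, sp.pixel_ids)
        est = kde_envelope(scores.coords[sel], level=0.99)
        inter = est.geometry.intersection(sp.true_envelope.geometry).area
        union = est.geometry.union(sp.true_envelope.geometry).area
        assert inter / union >= 0.8

    def test_shrinking_covariance_shrinks_range_nestedly(self, landscape):
        stack, space = landscape
        big = generate_species(stack, space, [0, 0], 1.0 * np.eye(2), level=0.95)
        small = generate_species(stack, space, [0, 0], 0.3 * np.eye(2), level=0.95)
        assert set(small.pixel_ids) <= set(big.pixel_ids)
        assert len(small.pixel_ids) < len(big.pixel_ids)


class TestSimulateIntroductions:
    @staticmethod
    def _species(landscape, k=4):
        stack, space = landscape
        from nichemargin import project

        scores = project(stack, space)
        med = np.median(scores.coords, axis=0)
        rng = np.random.default_rng(55)
        out = []
        for i in range(k):
            c = med + rng.uniform(-1, 1, 2)
            out.append(
                generate_species(stack, space, c, 0.3 * np.eye(2), level=0.99, name=f"sp{i}")
            )
        return out

    def test_null_model_gives_half_success(self, landscape):
        stack, space = landscape
        truth = SimulationTruth(
            intercept=0.0, beta={}, sigma_species=0.0, sigma_family=0.0,
            sigma_region=0.0, missing_rate=0.0,
        )
        ev = simulate_introductions(
            self._species(landscape), stack, space, truth, n_events=2000,
            rng=np.random.default_rng(1),
        )
        se = 0.5 / np.sqrt(len(ev))
        assert ev["outcome"].mean() == pytest.approx(0.5, abs=3 * se)

    def test_intercept_sets_baseline_rate(self, landscape):
        stack, space = landscape
        truth = SimulationTruth(
            intercept=float(logit(0.8)), beta={}, sigma_species=0.0,
            sigma_family=0.0, sigma_region=0.0, missing_rate=0.0,
        )
        ev = simulate_introductions(
            self._species(landscape), stack, space, truth, n_events=2000,
            rng=np.random.default_rng(2),
        )
        se = np.sqrt(0.8 * 0.2 / len(ev))
        assert ev["outcome"].mean() == pytest.approx(0.8, abs=3 * se)

    def test_strong_nmi_effect_raises_success_inside_niche(self, landscape):
        stack, space = landscape
        truth = SimulationTruth(
            intercept=0.0, beta={"nmi": 2.0}, sigma_species=0.0,
            sigma_family=0.0, sigma_region=0.0, missing_rate=0.0,
        )
        ev = simulate_introductions(
            self._species(landscape), stack, space, truth, n_events=2000,
            rng=np.random.default_rng(3),
        )
        inside = ev.loc[ev["nmi"] > 0, "outcome"].mean()
        outside = ev.loc[ev["nmi"] <= 0, "outcome"].mean()
        assert inside > outside

    def test_missingness_rate_applied(self, landscape):
        stack, space = landscape
        truth = SimulationTruth(missing_rate=0.2)
        ev = simulate_introductions(
            self._species(landscape), stack, space, truth, n_events=1500,
            rng=np.random.default_rng(4),
        )
        frac = ev["weaning_age"].isna().mean()
        assert frac == pytest.approx(0.2, abs=0.04)
        assert ev["nmi"].isna().sum() == 0


class TestSimulateModelData:
    def test_reproducible_and_exactly_standardized(self):
        truth = SimulationTruth(seed=9)
        a, _ = simulate_model_data(truth, n=300)
        b, _ = simulate_model_data(truth, n=300)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)
        assert a.X[:, 0].mean() == pytest.approx(0.0, abs=1e-9)
        assert a.X[:, 0].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_truth_vector_follows_column_order(self):
        truth = SimulationTruth(beta={"nmi": 1.5, "island": -0.5})
        _, bvec = simulate_model_data(truth, n=100, rng=np.random.default_rng(0))
        assert bvec[0] == 1.5 and bvec[-1] == -0.5
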