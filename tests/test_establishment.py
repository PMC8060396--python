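"""Covariate preparation and the hierarchical Bayesian establishment model."""

import numpy as np
import pandas as pd
import pytest

from nichemargin import (
    ModelSpec,
    bayesian_p_value,
    cross_validate,
    fit_model,
    max_tss,
    prepare_covariates,
)
from nichemargin.establishment import FIXED_COLS
from nichemargin.synthetic import SimulationTruth, simulate_model_data

QUICK_SPEC = dict(burn_in=300, iterations=1200, thin=6)  # 2 x 200 retained


def make_records(n=40, seed=0, **overrides):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "species": [f"sp{i % 8}" for i in range(n)],
            "family": [f"fam{(i % 8) // 2}" for i in range(n)],
            "region": [f"reg{i % 3}" for i in range(n)],
            "outcome": rng.integers(0, 2, n),
            "nmi": rng.normal(size=n),
            "n_individuals": rng.integers(1, 500, n).astype(float),
            "intro_date": rng.integers(1850, 2000, n).astype(float),
            "range_area": np.exp(rng.normal(10, 1, n)),
            "weaning_age": np.exp(rng.normal(4, 0.5, n)),
            "litter_size": np.exp(rng.normal(1, 0.3, n)),
            "litters_per_year": rng.uniform(0.5, 3, n),
            "cv_adult_mass": rng.uniform(0.05, 0.3, n),
            "cv_neonate_mass": rng.uniform(0.05, 0.3, n),
            "island": rng.integers(0, 2, n).astype(float),
        }
    )
    if df["outcome"].nunique() == 1:
        df.loc[0, "outcome"] = 1 - df.loc[0, "outcome"]
    for k, v in overrides.items():
        df[k] = v
    return df


class TestPrepareCovariates:
    def test_log_then_zscore_of_powers_of_ten(self):
        df = make_records(3)
        df["weaning_age"] = [10.0, 100.0, 1000.0]
        data = prepare_covariates(df)
        j = list(data.col_names).index("weaning_age")
        np.testing.assert_allclose(data.X[:, j], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent_on_standardized_column(self):
        df = make_records(24)
        z = df["nmi"].to_numpy()
        z = (z - z.mean()) / z.std(ddof=1)
        df["nmi"] = z
        data = prepare_covariates(df)
        np.testing.assert_allclose(data.X[:, 0], z, atol=1e-12)

    def test_missing_cell_stays_masked_and_rest_standardized(self):
        df = make_records(24)
        df.loc[3, "litter_size"] = np.nan
        data = prepare_covariates(df)
        j = list(data.col_names).index("litter_size")
        assert data.missing[3, j] and not data.missing[2, j]
        obs = data.X[~data.missing[:, j], j]
        assert obs.mean() == pytest.approx(0.0, abs=1e-9)
        assert obs.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_island_stays_binary_with_mainland_reference(self):
        data = prepare_covariates(make_records(24))
        j = list(data.col_names).index("island")
        assert set(np.unique(data.X[:, j])) <= {0.0, 1.0}

    def test_non_positive_value_under_log_names_record(self):
        df = make_records(10)
        df.loc[4, "range_area"] = -2.0
        with pytest.raises(ValueError, match=r"range_area.*\[4\]"):
            prepare_covariates(df)

    def test_missing_required_column_raises(self):
        df = make_records(10).drop(columns=["outcome"])
        with pytest.raises(ValueError, match="outcome"):
            prepare_covariates(df)

    def test_species_in_two_families_rejected(self):
        df = make_records(10)
        df.loc[0, "family"] = "other_family"
        with pytest.raises(ValueError, match="families"):
            prepare_covariates(df)

    def test_count_below_one_rejected(self):
        df = make_records(10)
        df.loc[2, "n_individuals"] = 0.0
        with pytest.raises(ValueError, match="individuals"):
            prepare_covariates(df)


class TestFitModel:
    def test_posterior_matches_ml_logistic_when_effects_strong(self):
        # small random-effect sds: a plain ML logistic fit is a valid oracle
        truth = SimulationTruth(
            intercept=0.0,
            beta={"nmi": 1.0},
            sigma_species=0.05,
            sigma_family=0.05,
            sigma_region=0.05,
        )
        data, _ = simulate_model_data(truth, n=2000, rng=np.random.default_rng(99))
        fit = fit_model(data, ModelSpec(seed=1, **QUICK_SPEC))
        med = fit.median("beta_nmi")

        import statsmodels.api as sm

        ml = sm.Logit(data.y, sm.add_constant(data.X)).fit(disp=0)
        se = ml.bse[1]
        assert med == pytest.approx(ml.params[1], abs=2 * se)
        assert med == pytest.approx(1.0, abs=2 * np.std(fit.parameter("beta_nmi")) + 2 * se)

    def test_retained_draw_count_follows_spec(self):
        truth = SimulationTruth()
        data, _ = simulate_model_data(truth, n=200, n_species=10, rng=np.random.default_rng(3))
        spec = ModelSpec(seed=0, chains=2, burn_in=100, iterations=400, thin=4)
        fit = fit_model(data, spec)
        assert fit.samples.shape[0] == 2 * 100
        assert fit.chains.shape[:2] == (2, 100)

    def test_negating_covariate_negates_posterior_effect(self):
        truth = SimulationTruth(beta={"litter_size": 0.8})
        data, _ = simulate_model_data(truth, n=600, rng=np.random.default_rng(21))
        j = list(data.col_names).index("litter_size")
        fit_a = fit_model(data, ModelSpec(seed=5, **QUICK_SPEC))
        flipped = data.subset(np.arange(data.n))
        flipped.X[:, j] = -flipped.X[:, j]
        fit_b = fit_model(flipped, ModelSpec(seed=5, **QUICK_SPEC))
        a = fit_a.median("beta_litter_size")
        b = fit_b.median("beta_litter_size")
        mc = 3 * (np.std(fit_a.parameter("beta_litter_size")) / np.sqrt(50) + 0.02)
        assert a == pytest.approx(-b, abs=max(0.1, mc))

    def test_imputation_under_mcar_stays_close_to_complete_data_fit(self):
        truth = SimulationTruth(beta={"nmi": 0.5, "weaning_age": 0.5})
        rng = np.random.default_rng(7)
        data, _ = simulate_model_data(truth, n=500, rng=rng)
        fit_full = fit_model(data, ModelSpec(seed=2, **QUICK_SPEC))
        j = list(data.col_names).index("weaning_age")
        masked = data.subset(np.arange(data.n))
        hide = np.random.default_rng(8).random(data.n) < 0.10
        masked.X = masked.X.copy()
        masked.missing = masked.missing.copy()
        masked.X[hide, j] = np.nan
        masked.missing[hide, j] = True
        fit_miss = fit_model(masked, ModelSpec(seed=2, **QUICK_SPEC))
        sd = np.std(fit_full.parameter("beta_weaning_age"))
        shift = abs(fit_miss.median("beta_weaning_age") - fit_full.median("beta_weaning_age"))
        assert shift < 0.5 * sd + 0.03  # small slack for finite-draw MC error
        assert "nu_weaning_age" in fit_miss.names

    def test_all_failures_or_all_successes_rejected(self):
        truth = SimulationTruth()
        data, _ = simulate_model_data(truth, n=100, rng=np.random.default_rng(11))
        data.y[:] = 1.0
        with pytest.raises(ValueError, match="success and one failure"):
            fit_model(data, ModelSpec(seed=0, **QUICK_SPEC))

    def test_bayesian_p_value_calibrated_under_truth(self):
        truth = SimulationTruth(beta={"nmi": 0.4})
        data, _ = simulate_model_data(truth, n=800, rng=np.random.default_rng(17))
        fit = fit_model(data, ModelSpec(seed=4, **QUICK_SPEC))
        p = bayesian_p_value(fit)
        assert 0.2 <= p <= 0.8
        assert fit.converged


class TestCrossValidate:
    def test_separable_signal_scores_high(self):
        rng = np.random.default_rng(31)
        truth = SimulationTruth(
            intercept=0.0, beta={"nmi": 6.0},
            sigma_species=0.05, sigma_family=0.05, sigma_region=0.05,
        )
        data, _ = simulate_model_data(truth, n=600, rng=rng)
        scores = cross_validate(data, ModelSpec(**QUICK_SPEC), reps=1, seed=0)
        assert scores[0] > 0.6

    def test_fixed_seed_reproduces_scores(self):
        truth = SimulationTruth(beta={"nmi": 1.0})
        data, _ = simulate_model_data(truth, n=300, n_species=10, rng=np.random.default_rng(13))
        spec = ModelSpec(chains=2, burn_in=100, iterations=400, thin=4)
        a = cross_validate(data, spec, reps=2, seed=42)
        b = cross_validate(data, spec, reps=2, seed=42)
        assert a == b

    def test_both_classes_present_in_every_evaluation_split(self):
        truth = SimulationTruth()
        data, _ = simulate_model_data(truth, n=200, n_species=10, rng=np.random.default_rng(19))
        # max_tss inside cross_validate raises if a class is missing, so
        # completion of all reps is itself the assertion
        scores = cross_validate(
            data, ModelSpec(chains=2, burn_in=50, iterations=200, thin=4), reps=3, seed=1
        )
        assert len(scores) == 3
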