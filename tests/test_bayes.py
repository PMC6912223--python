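import numpy as np
import pytest

import occuwatch as ow
from occuwatch.bayes import DetectionModel, DesignMatrix, PosteriorDraws, PriorSpec


def toy_binomial_design(successes=7, trials=20):
    """Intercept-only day-level design: `trials` days, `successes` detections."""
    y = np.zeros(trials)
    y[:successes] = 1.0
    return DesignMatrix(
        X=np.ones((trials, 1)),
        y=y,
        columns=("intercept",),
        variant=DetectionModel.NULL,
        seasons=("2015",),
    )


def empty_design(k=1, columns=("intercept",)):
    return DesignMatrix(
        X=np.empty((0, k)),
        y=np.empty(0),
        columns=columns,
        variant=DetectionModel.NULL,
        seasons=("2015",),
    )


from conftest import draws_from_chains


class TestConditioning:
    def test_all_detected_is_noop(self, make_ds):
        ds = make_ds(
            {("Potorous", "A", "2015"): [1, 0], ("Potorous", "B", "2015"): [0, 1]}
        )
        assert ow.condition_on_occupancy(ds).histories.keys() == ds.histories.keys()

    def test_no_detections_is_error(self, make_ds):
        ds = make_ds({("Potorous", "A", "2015"): [0, 0]})
        with pytest.raises(ValueError, match="unfittable"):
            ow.condition_on_occupancy(ds)

    def test_filter_keeps_exactly_detected_records(self, make_ds):
        ds = make_ds(
            {
                ("Potorous", "A", "2015"): [1, 0],
                ("Potorous", "B", "2015"): [0, 0],
                ("Potorous", "C", "2015"): [0, 1],
                ("Potorous", "D", "2015"): [0, np.nan],
                ("Potorous", "E", "2015"): [np.nan, 1],
            }
        )
        kept = ow.condition_on_occupancy(ds)
        assert {k[1] for k in kept.histories} == {"A", "C", "E"}


class TestDesign:
    def test_null_variant_is_intercept_only(self, make_ds, toy_sites):
        ds = make_ds({("Potorous", "A1", "2015"): [1, 0, 1]})
        design = ow.build_design(ds, toy_sites, DetectionModel.NULL)
        assert design.columns == ("intercept",)
        assert design.n_rows == 3

    def test_full_variant_columns(self, make_ds, toy_sites):
        ds = make_ds(
            {
                ("Potorous", "A1", "2015"): [1, 0],
                ("Potorous", "B1", "2016"): [1, 1],
            },
            seasons=("2015", "2016"),
        )
        design = ow.build_design(ds, toy_sites, DetectionModel.FULL)
        assert design.columns == ("intercept", "bait", "ground", "shrub", "year_2016")
        # B1: unbaited, ground 1, shrub 3, year 2016
        np.testing.assert_array_equal(design.X[-1], [1, 0, 1, 3, 1])

    def test_row_count_is_nonmissing_day_total(self, make_ds, toy_sites):
        ds = make_ds(
            {
                ("Potorous", "A1", "2015"): [1, np.nan, 0, np.nan],
                ("Potorous", "B1", "2015"): [1, 1, np.nan, 0, 1],
            }
        )
        design = ow.build_design(ds, toy_sites, DetectionModel.BAIT)
        brute = sum(int((~np.isnan(h)).sum()) for h in ds.histories.values())
        assert design.n_rows == brute == 6

    def test_aggregation_preserves_totals(self, small_dataset):
        data, sites, _ = small_dataset
        design = ow.build_design(
            ow.condition_on_occupancy(data), sites, DetectionModel.FULL
        )
        xu, s, n = design.aggregated()
        assert s.sum() == design.y.sum()
        assert n.sum() == design.n_rows


class TestSampler:
    def test_constant_covariate_rejected(self, make_ds, toy_sites):
        ds = make_ds({("Potorous", "A1", "2015"): [1, 0, 1]})
        design = ow.build_design(ds, toy_sites, DetectionModel.BAIT)  # only baited site
        with pytest.raises(ValueError, match="degenerate"):
            ow.sample_posterior(design, iterations=2000, seed=0)

    def test_prior_only_run_recovers_prior_sd(self):
        draws = ow.sample_posterior(
            empty_design(), PriorSpec(mean=0.0, precision=1e-6),
            iterations=30000, chains=2, seed=5,
        )
        post = draws.posterior()[:, 0]
        assert np.std(post) == pytest.approx(1000.0, rel=0.25)
        assert abs(np.mean(post)) < 3 * np.std(post) / np.sqrt(50)  # generous ESS bound

    def test_two_seeds_agree_within_mc_error(self):
        design = toy_binomial_design()
        a = ow.sample_posterior(design, iterations=4000, seed=1)
        b = ow.sample_posterior(design, iterations=4000, seed=2)
        assert not np.array_equal(a.chains, b.chains)
        assert a.posterior().mean() == pytest.approx(b.posterior().mean(), abs=0.1)

    def test_acceptance_in_target_band(self):
        design = toy_binomial_design()
        draws = ow.sample_posterior(design, iterations=4000, seed=3)
        assert (draws.acceptance > 0.1).all() and (draws.acceptance < 0.55).all()

    def test_burn_in_is_half(self):
        design = toy_binomial_design()
        draws = ow.sample_posterior(design, iterations=2468, seed=4)
        assert draws.burn_in == 1234
        assert draws.iterations == 2468 and draws.n_chains == 2

    def test_posterior_concentrates_at_logistic_mle(self, small_dataset):
        import statsmodels.api as sm

        data, sites, _ = small_dataset
        design = ow.build_design(
            ow.condition_on_occupancy(data), sites, DetectionModel.BAIT_HABITAT
        )
        draws = ow.sample_posterior(design, iterations=6000, seed=6)
        mle = sm.GLM(design.y, design.X, family=sm.families.Binomial()).fit()
        post_mean = draws.posterior().mean(axis=0)
        assert np.all(np.abs(post_mean - mle.params) < 4 * mle.bse + 0.05)


class TestDiagnostics:
    def test_identical_chains_give_exactly_one(self):
        chain = np.random.default_rng(0).normal(size=(1, 400, 2))
        draws = draws_from_chains(np.repeat(chain, 2, axis=0), columns=("a", "b"))
        rhat = ow.gelman_rubin(draws)
        assert (rhat == 1.0).all()

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, (500, 1)), rng.normal(10, 1, (500, 1))])
        rhat = ow.gelman_rubin(draws_from_chains(chains))
        # closed form: B/n = var of chain means ~ 50, W ~ 1 -> rhat >> 1.05
        assert rhat.iloc[0] > 1.05

    def test_single_chain_rejected(self):
        draws = draws_from_chains(np.zeros((1, 100, 1)) + np.linspace(0, 1, 100)[None, :, None])
        with pytest.raises(ValueError, match="2 chains"):
            ow.gelman_rubin(draws)

    def test_converged_run_passes_threshold(self):
        draws = ow.sample_posterior(toy_binomial_design(), iterations=6000, seed=7)
        assert (ow.gelman_rubin(draws) < 1.05).all()

    def test_autocorrelation_table_shape(self):
        draws = ow.sample_posterior(toy_binomial_design(), iterations=2000, seed=8)
        table = ow.autocorrelation_table(draws, lags=(1, 5))
        assert list(table.columns) == ["coefficient", "lag_1", "lag_5"]
        assert (table["lag_1"].abs() <= 1.0).all()


class TestDic:
    def test_point_mass_posterior_has_zero_pd(self):
        design = toy_binomial_design()
        beta0 = 0.3
        chains = np.full((2, 400, 1), beta0)
        dic_val, pd_val = ow.dic(draws_from_chains(chains), design)
        eta = beta0
        loglik = 7 * eta - 20 * np.log1p(np.exp(eta))
        assert pd_val == pytest.approx(0.0, abs=1e-10)
        assert dic_val == pytest.approx(-2 * loglik)

    def test_irrelevant_covariate_adds_about_one_effective_parameter(self):
        rng = np.random.default_rng(9)
        n = 4000
        x_noise = rng.normal(size=n)
        y = (rng.random(n) < 0.3).astype(float)
        base = DesignMatrix(np.ones((n, 1)), y, ("intercept",), DetectionModel.NULL, ("2015",))
        wide = DesignMatrix(
            np.column_stack([np.ones(n), x_noise]), y,
            ("intercept", "noise"), DetectionModel.NULL, ("2015",),
        )
        d_base = ow.sample_posterior(base, iterations=6000, seed=10)
        d_wide = ow.sample_posterior(wide, iterations=6000, seed=11)
        _, pd_base = ow.dic(d_base, base)
        _, pd_wide = ow.dic(d_wide, wide)
        assert pd_wide - pd_base == pytest.approx(1.0, abs=0.5)


class TestDetectionCurves:
    def test_zero_coefficients_give_half(self):
        chains = np.zeros((2, 400, 2))
        draws = draws_from_chains(chains, columns=("intercept", "ground"))
        curves = ow.detection_curves(draws, [{"ground": g} for g in range(4)])
        assert all(c.mean == 0.5 and c.lo == 0.5 and c.hi == 0.5 for c in curves)

    def test_positive_ground_effect_recovered_as_monotone(self, small_dataset):
        data, sites, _ = small_dataset
        design = ow.build_design(
            ow.condition_on_occupancy(data), sites, DetectionModel.HABITAT
        )
        draws = ow.sample_posterior(design, iterations=4000, seed=12)
        curves = ow.detection_curves(
            draws, [{"ground": g, "shrub": 1} for g in range(4)]
        )
        means = [c.mean for c in curves]
        assert means == sorted(means)  # generating ground effect is positive
        assert all(0.0 <= c.lo <= c.hi <= 1.0 for c in curves)

    def test_missing_covariate_rejected(self):
        draws = draws_from_chains(np.zeros((2, 100, 2)), columns=("intercept", "bait"))
        with pytest.raises(ValueError, match="bait"):
            ow.detection_curves(draws, [{"ground": 1}])
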