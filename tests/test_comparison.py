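"""Maximum-likelihood fitting and AIC/SC contest semantics."""

import math

import numpy as np
import pytest
from scipy import stats

from scidiscovery.comparison import (
    DegenerateFitError,
    FitResult,
    Statistic,
    contest,
    fit_mle,
    score,
    score_matrix,
    win_probability,
    win_probability_table,
)
from scidiscovery.datagen import Dataset, TrueModelConfig, generate_dataset, simulate_batch

from conftest import model


@pytest.fixture()
def dataset(rng):
    config = TrueModelConfig(model=model("1+2+12"), noise_ratio=0.25)
    return generate_dataset(config, rng)


class TestFit:
    def test_matches_statsmodels_ols(self, dataset):
        import statsmodels.api as sm
        from scidiscovery.comparison import design_matrix

        m = model("1+2+12")
        fit = fit_mle(m, dataset)
        ols = sm.OLS(dataset.response, design_matrix(m, dataset.predictors)).fit()
        np.testing.assert_allclose(
            [fit.coefficients[t] for t in m.sorted_terms], ols.params, rtol=1e-8
        )
        np.testing.assert_allclose(fit.rss, ols.ssr, rtol=1e-8)

    def test_loglik_equals_density_sum_oracle(self, dataset):
        from scidiscovery.comparison import design_matrix

        m = model("1+2")
        fit = fit_mle(m, dataset)
        x = design_matrix(m, dataset.predictors)
        beta = np.array([fit.coefficients[t] for t in m.sorted_terms])
        sigma2 = fit.rss / fit.n
        oracle = stats.norm.logpdf(
            dataset.response, loc=x @ beta, scale=math.sqrt(sigma2)
        ).sum()
        assert fit.max_loglik == pytest.approx(oracle, rel=1e-10)

    def test_true_coefficients_recovered_at_large_n(self, rng):
        config = TrueModelConfig(model=model("1+2+12"), noise_ratio=0.25, sample_size=10_000)
        data = generate_dataset(config, rng)
        fit = fit_mle(config.model, data)
        # ballpark 3-sigma window: se ~ sigma/sqrt(n * var_x)
        for t, est in fit.coefficients.items():
            assert est == pytest.approx(1.0, abs=0.05)

    def test_zero_noise_perfect_fit(self, rng):
        config = TrueModelConfig(model=model("1+2+12"), noise_ratio=0.0)
        data = generate_dataset(config, rng)
        fit = fit_mle(config.model, data)
        assert fit.rss == 0.0 and fit.perfect

    def test_degenerate_design_detected(self):
        x = np.ones((10, 3))  # x1 column == x2 column
        data = Dataset(predictors=x, response=np.arange(10.0))
        with pytest.raises(DegenerateFitError):
            fit_mle(model("1+2"), data)

    def test_k_counts_error_variance(self, dataset):
        assert fit_mle(model("1+2+12"), dataset).k == 4


class TestScore:
    def _fit(self, loglik, k, n=100):
        return FitResult(
            model=model("1"), coefficients={}, rss=1.0, max_loglik=loglik, k=k, n=n
        )

    def test_penalty_monotone_in_k(self):
        for stat in Statistic:
            assert score(self._fit(-50.0, 3), stat) < score(self._fit(-50.0, 4), stat)

    def test_aic_sc_difference_closed_form(self):
        f = self._fit(-50.0, 4, n=100)
        diff = score(f, Statistic.AIC) - score(f, Statistic.SC)
        assert diff == pytest.approx(8 - 4 * math.log(100))

    def test_row_order_invariance(self, dataset):
        m = model("1+2")
        perm = np.random.default_rng(0).permutation(dataset.n)
        shuffled = Dataset(dataset.predictors[perm], dataset.response[perm])
        for stat in Statistic:
            assert score(fit_mle(m, dataset), stat) == pytest.approx(
                score(fit_mle(m, shuffled), stat)
            )

    def test_score_matrix_agrees_with_scalar_path(self, rng, space):
        config = TrueModelConfig(model=model("1+2+12"), noise_ratio=1.0)
        x, y = simulate_batch(config, 5, rng)
        models = list(space)
        for stat in Statistic:
            s = score_matrix(models, x, y, stat)
            for r in range(5):
                data = Dataset(x[r], y[r])
                for j, m in enumerate(models):
                    assert s[r, j] == pytest.approx(
                        score(fit_mle(m, data), stat), rel=1e-9
                    )


class TestContest:
    def test_self_proposal_retained(self, dataset):
        m = model("1+2+12")
        assert contest(m, m, dataset, Statistic.AIC) == m

    def test_near_zero_noise_truth_beats_disjoint_model(self, rng):
        config = TrueModelConfig(model=model("1+2+12"), noise_ratio=1e-8)
        data = generate_dataset(config, rng)
        for stat in Statistic:
            assert contest(model("1+2+12"), model("3"), data, stat) == model("1+2+12")

    def test_near_zero_noise_superset_loses_to_truth_global(self, rng, space):
        config = TrueModelConfig(model=model("1+2+12"), noise_ratio=1e-8)
        data = generate_dataset(config, rng)
        for stat in Statistic:
            assert contest(space.full_model, model("1+2+12"), data, stat) == model("1+2+12")

    def test_exactly_zero_noise_decided_by_k(self, rng, space):
        # both fits perfect (rss = 0): the smaller model must win/be retained
        config = TrueModelConfig(model=model("1+2+12"), noise_ratio=0.0)
        data = generate_dataset(config, rng)
        assert contest(space.full_model, model("1+2+12"), data, Statistic.AIC) == model("1+2+12")
        assert contest(model("1+2+12"), space.full_model, data, Statistic.AIC) == model("1+2+12")


class TestWinProbability:
    def test_self_contest_is_zero(self, rng):
        config = TrueModelConfig(model=model("1"))
        est = win_probability(model("1"), model("1"), config, Statistic.SC, 10, rng)
        assert est.probability == 0.0

    def test_two_independent_runs_agree(self):
        config = TrueModelConfig(model=model("1"), noise_ratio=1.0)
        args = (model("1+2"), model("1"), config, Statistic.AIC, 4000)
        e1 = win_probability(*args, np.random.default_rng(101))
        e2 = win_probability(*args, np.random.default_rng(202))
        assert 0.0 < e1.probability < 1.0
        tol = 3 * math.hypot(e1.se, e2.se)
        assert abs(e1.probability - e2.probability) <= tol

    def test_truth_favoured_over_wrong_single_main(self, rng):
        config = TrueModelConfig(model=model("1+2+12"), noise_ratio=0.25)
        est = win_probability(model("1+2+12"), model("3"), config, Statistic.SC, 400, rng)
        assert est.probability > 0.5

    def test_table_consistent_with_pairwise_estimates(self, rng, space):
        config = TrueModelConfig(model=model("1"), noise_ratio=0.25)
        table = win_probability_table(config, space, Statistic.SC, 2000, rng)
        assert np.all(np.diag(table) == 0.0)
        assert table.min() >= 0.0 and table.max() <= 1.0
        p_idx, g_idx = space.index(model("1")), space.index(model("2"))
        direct = win_probability(
            model("1"), model("2"), config, Statistic.SC, 2000, np.random.default_rng(7)
        )
        se = math.sqrt(direct.se**2 + direct.probability * (1 - direct.probability) / 2000 + 1e-8)
        assert abs(table[p_idx, g_idx] - direct.probability) < 3 * se + 0.01


class TestConsistency:
    def test_sc_selects_truth_with_growing_n(self):
        """SC win probability of truth vs a fixed wrong model is
        non-decreasing in n (within Monte-Carlo error)."""
        truth_m = model("1+2")
        wrong = model("1+2+12")
        reps = 800
        probs = []
        for n in (100, 1000, 10_000):
            config = TrueModelConfig(model=truth_m, noise_ratio=1.0, sample_size=n)
            est = win_probability(
                truth_m, wrong, config, Statistic.SC, reps,
                np.random.default_rng(n), chunk=200,
            )
            probs.append(est)
        for lo, hi in zip(probs, probs[1:]):
            assert hi.probability >= lo.probability - 2 * math.hypot(lo.se, hi.se)
        assert probs[-1].probability > 0.9
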