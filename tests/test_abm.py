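"""Agent-based process: replication semantics and trajectory metrics."""

import numpy as np
import pytest

from scidiscovery.abm import (
    ABMConfig,
    ExperimentRecord,
    reproducibility_rates,
    run,
    step,
)
from scidiscovery.comparison import Statistic
from scidiscovery.datagen import TrueModelConfig
from scidiscovery.markov import PopulationSpec
from scidiscovery.model_space import ConfigurationError
from scidiscovery.strategies import ScientistType, StrategyMode

from conftest import model


def make_config(**kw):
    defaults = dict(
        population=PopulationSpec(
            {"rey": 0.25, "tess": 0.25, "mave": 0.25, "bo": 0.25}
        ),
        truth=TrueModelConfig(model=model("1+2+12"), noise_ratio=0.25),
        statistic=Statistic.SC,
        mode=StrategyMode.hard(),
        iterations=2000,
        burn_in=200,
    )
    defaults.update(kw)
    return ABMConfig(**defaults)


class TestDeterminism:
    def test_same_seed_identical_runs(self):
        config = make_config(iterations=1500)
        r1 = run(config, np.random.default_rng(33))
        r2 = run(config, np.random.default_rng(33))
        np.testing.assert_array_equal(r1.states, r2.states)
        np.testing.assert_array_equal(r1.scientists, r2.scientists)
        np.testing.assert_array_equal(r1.score_proposed, r2.score_proposed)
        assert r1.repro == r2.repro

    def test_different_seeds_differ(self):
        config = make_config(iterations=1500)
        r1 = run(config, np.random.default_rng(1))
        r2 = run(config, np.random.default_rng(2))
        assert not np.array_equal(r1.states, r2.states)


class TestReplicationSemantics:
    def test_every_replication_reuses_predecessor_pair(self):
        """Rey contests her predecessor's exact (proposed, global) pair,
        even when the consensus moved in between."""
        config = make_config(iterations=3000)
        records = run(config, np.random.default_rng(7)).records()
        n_checked = 0
        for prev, rec in zip(records, records[1:]):
            if rec.is_replication:
                assert rec.proposed == prev.proposed
                assert rec.global_before == prev.global_before
                assert rec.reproduced == (rec.proposed_won == prev.proposed_won)
                n_checked += 1
        assert n_checked > 300

    def test_rey_after_winning_proposal_can_revert(self):
        """Somewhere in a long trace a replication overturns a win."""
        config = make_config(iterations=5000, statistic=Statistic.AIC)
        records = run(config, np.random.default_rng(13)).records()
        overturned = [
            r
            for prev, r in zip(records, records[1:])
            if r.is_replication and prev.proposed_won and not r.proposed_won
        ]
        assert overturned, "expected at least one failed replication of a win"
        for r in overturned:
            assert r.reproduced is False
            assert r.global_after == r.global_before

    def test_rey_never_first(self):
        config = make_config(
            population=PopulationSpec({"rey": 0.999999, "tess": 1e-6})
        )
        result = run(config, np.random.default_rng(5))
        assert not result.is_replication[0]
        # an almost-pure-Rey population endlessly replicates the first pair
        assert result.is_replication[1:].mean() > 0.999
        first = result.records()[0]
        for rec in result.records()[1:]:
            if rec.is_replication:
                assert rec.proposed == first.proposed
                assert rec.global_before == first.global_before

    def test_zero_noise_every_replication_reproduces(self):
        config = make_config(
            truth=TrueModelConfig(model=model("1+2+12"), noise_ratio=0.0),
            iterations=3000,
        )
        result = run(config, np.random.default_rng(21))
        assert result.repro.n_replications > 300
        assert result.repro_rate_overall == 1.0
        assert result.repro_rate_truth_global in (None, 1.0)
        assert result.repro_rate_other in (None, 1.0)


class TestStep:
    def test_step_without_predecessor_never_replicates(self, rng):
        config = make_config(population=PopulationSpec({"rey": 0.99, "mave": 0.01}))
        for _ in range(20):
            _, rec = step(model("1"), None, config, rng)
            assert not rec.is_replication

    def test_step_replicates_given_predecessor(self, space):
        rng = np.random.default_rng(2)
        config = make_config(population=PopulationSpec({"rey": 0.999999, "mave": 1e-6}))
        predecessor = ExperimentRecord(
            time=0,
            scientist=ScientistType.MAVE,
            proposed=model("1+2"),
            global_before=model("3"),
            score_proposed=0.0,
            score_global=1.0,
            proposed_won=True,
            global_after=model("1+2"),
            is_replication=False,
        )
        new_global, rec = step(model("1+2"), predecessor, config, rng, space=space, time=1)
        assert rec.is_replication
        assert rec.proposed == model("1+2") and rec.global_before == model("3")
        assert rec.reproduced == (rec.proposed_won == predecessor.proposed_won)
        assert new_global in (model("1+2"), model("3"))

    def test_step_nonrey_contests_current_global(self, space, rng):
        config = make_config(population=PopulationSpec({"tess": 1.0}))
        g = model("1+2+12")
        new_global, rec = step(g, None, config, rng, space=space)
        assert rec.global_before == g
        assert rec.proposed in {model("1"), model("2"), model("1+2+3+12")}
        assert new_global == (rec.proposed if rec.proposed_won else g)


class TestMetrics:
    def test_initial_at_truth_gives_zero_first_passage(self):
        config = make_config(initial_model=model("1+2+12"), iterations=500, burn_in=100)
        result = run(config, np.random.default_rng(3))
        assert result.first_passage_to_truth == 0

    def test_absorbing_truth_time_at_truth_one(self):
        # zero noise: once at the truth nothing dethrones it
        config = make_config(
            truth=TrueModelConfig(model=model("1+2+12"), noise_ratio=0.0),
            initial_model=model("1+2+12"),
            iterations=500,
            burn_in=100,
        )
        result = run(config, np.random.default_rng(3))
        assert result.time_at_truth == 1.0
        assert result.empirical_stickiness == 1.0

    def test_censoring_flagged_when_truth_unreachable(self):
        # hard-mode pure Bo starting above the truth can never reach it
        config = make_config(
            population=PopulationSpec({"bo": 1.0}),
            truth=TrueModelConfig(model=model("1"), noise_ratio=0.25),
            initial_model=model("2"),
            iterations=300,
            burn_in=50,
        )
        result = run(config, np.random.default_rng(9))
        assert result.censored and result.first_passage_to_truth is None

    def test_at_truth_rate_exceeds_overall_in_bo_free_low_noise(self):
        config = make_config(
            population=PopulationSpec({"rey": 0.3, "tess": 0.4, "mave": 0.3}),
            truth=TrueModelConfig(model=model("1+2+12"), noise_ratio=0.25),
            iterations=8000,
            burn_in=500,
        )
        result = run(config, np.random.default_rng(17))
        r = result.repro
        assert r.n_at_truth > 50
        se = np.sqrt(
            r.at_truth * (1 - r.at_truth) / r.n_at_truth
            + r.overall * (1 - r.overall) / r.n_replications
            + 1e-12
        )
        assert r.at_truth >= r.overall - 3 * se

    def test_rates_arithmetic_on_hand_built_records(self):
        def rec(t, reproduced, g="1"):
            return ExperimentRecord(
                time=t,
                scientist=ScientistType.REY,
                proposed=model("1+2"),
                global_before=model(g),
                score_proposed=0.0,
                score_global=0.0,
                proposed_won=False,
                global_after=model(g),
                is_replication=reproduced is not None,
                reproduced=reproduced,
            )

        records = [rec(0, None), rec(1, True), rec(2, True, g="2"), rec(3, False, g="2")]
        rates = reproducibility_rates(records, model("1"))
        assert rates.overall == pytest.approx(2 / 3)
        assert rates.at_truth == 1.0
        assert rates.off_truth == pytest.approx(1 / 2)
        assert rates.n_replications == 3

    def test_no_replications_rates_undefined(self):
        rates = reproducibility_rates([], model("1"))
        assert rates.overall is None and rates.at_truth is None

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            make_config(iterations=100, burn_in=100)
        with pytest.raises(ConfigurationError):
            make_config(population=PopulationSpec({"rey": 1.0}))
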