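"""End-to-end study computations behind ``scripts/acceptance.py``.

Two studies are bundled here so that the headline quantities of the
framework can be recomputed from scratch at a chosen scale:

* the **no-replication study**: for every true model in the space,
  Monte-Carlo win-probability tables feed the exact chain, giving the
  long-run time at the true model and the mean first passage time for
  each replication-free population preset under AIC and SC (soft
  strategies, noise ratio 1:4, n = 100);
* the **ABM factorial study**: hard-strategy agent-based runs over
  3 true models x 3 noise ratios x 5 populations, summarized by the
  pooled median first passage time of the Bo-dominant population (both
  statistics) and the median post-burn-in time at the true model across
  all SC runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .comparison import Statistic
from .experiments import (
    FactorialDesign,
    abm_populations,
    default_true_models,
    markov_populations,
    markov_summary,
)
from .model_space import enumerate_space
from .strategies import StrategyMode

__all__ = [
    "no_replication_study",
    "abm_factorial_study",
    "pooled_median",
]


def no_replication_study(
    reps: int = 10_000,
    seed: int = 0,
    epsilon: float = 0.1,
    noise_ratio: float = 0.25,
) -> pd.DataFrame:
    """Per-(population, statistic) averages over all 14 true models.

    Columns: ``time_at_truth_pct`` (mean stationary probability of the
    true model, in percent) and ``mean_mfpt`` (mean first passage time to
    the truth, averaged over initial models != truth and over true
    models).
    """
    summary, _ = markov_summary(
        populations=markov_populations(),
        statistics=(Statistic.AIC, Statistic.SC),
        noise_ratio=noise_ratio,
        mode=StrategyMode.make_soft(epsilon),
        reps=reps,
        seed=seed,
    )
    out = (
        summary.groupby(["population", "statistic"])
        .agg(
            time_at_truth_pct=("time_at_truth", lambda s: 100.0 * s.mean()),
            mean_mfpt=("mean_mfpt", "mean"),
            mean_stickiness=("stickiness", "mean"),
        )
        .reset_index()
    )
    return out


def pooled_median(first_passage: pd.Series, censored: pd.Series) -> float:
    """Median first passage time with censored runs entered as +inf.

    Well-defined whenever fewer than half the runs never reached the
    truth; returns +inf otherwise (reported, never imputed).
    """
    vals = first_passage.astype(float).to_numpy().copy()
    vals[censored.astype(bool).to_numpy()] = np.inf
    return float(np.median(vals))


def abm_factorial_study(
    replicates: int = 20,
    seed: int = 0,
    iterations: int = 11_000,
    burn_in: int = 1_000,
    progress: bool = False,
) -> dict:
    """Run the hard-strategy ABM factorial and derive its two headline numbers.

    Returns the per-run table plus ``bo_first_passage_median`` (pooled
    over true models, noise ratios and both statistics for the
    Bo-dominant population) and ``sc_time_at_truth_median_pct`` (median
    over all SC runs of the post-burn-in proportion of time at the true
    model, in percent).  The SC half of the Bo cells is shared between
    the two summaries.
    """
    from .experiments import run_design

    space = enumerate_space(3)
    tms = default_true_models(space)
    common = dict(
        true_models=tms,
        noise_ratios=(0.25, 1.0, 4.0),
        mode=StrategyMode.hard(),
        replicates=replicates,
        iterations=iterations,
        burn_in=burn_in,
        base_seed=seed,
    )
    sc_design = FactorialDesign(
        populations=abm_populations(), statistics=[Statistic.SC], design_id=1, **common
    )
    bo_aic_design = FactorialDesign(
        populations={"bo": abm_populations()["bo"]},
        statistics=[Statistic.AIC],
        design_id=2,
        **common,
    )
    sc_runs = run_design(sc_design, progress=progress)
    bo_aic_runs = run_design(bo_aic_design, progress=progress)

    bo_runs = pd.concat(
        [sc_runs[sc_runs.population == "bo"], bo_aic_runs], ignore_index=True
    )
    return {
        "sc_runs": sc_runs,
        "bo_runs": bo_runs,
        "bo_first_passage_median": pooled_median(bo_runs.first_passage, bo_runs.censored),
        "sc_time_at_truth_median_pct": float(100.0 * sc_runs.time_at_truth.median()),
    }
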