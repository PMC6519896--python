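"""Factorial experiment runner, population presets and summary statistics.

Reproduces the study's aggregate analyses: the exact-chain summaries for
replication-free populations (stickiness, long-run time at the true model
and mean first passage time, for every true model in the space), and the
randomized ABM factorial (true models x noise ratios x populations x
statistics, independently seeded replicates) with median/IQR summaries
and Spearman rank correlations between the rate of reproducibility and
the other desirable properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .abm import ABMConfig, RunResult, run
from .comparison import Statistic, win_probability_table
from .datagen import TrueModelConfig, parse_ratio, ratio_label
from .markov import PopulationSpec, build_transition_matrix, chain_metrics
from .model_space import ConfigurationError, Model, ModelSpace, enumerate_space
from .strategies import ScientistType, StrategyMode

__all__ = [
    "dominant_population",
    "diverse_population",
    "markov_populations",
    "abm_populations",
    "default_true_models",
    "FactorialDesign",
    "run_design",
    "summarize_runs",
    "spearman_r",
    "ConstantInputError",
    "markov_summary",
]


# ---------------------------------------------------------------------------
# population presets
# ---------------------------------------------------------------------------

def dominant_population(
    kind: ScientistType, rey_free: bool = False, dominance: float = 0.99
) -> PopulationSpec:
    """A population dominated by one type.

    The remaining mass is split equally over the other types: the two
    other proposing types when ``rey_free`` (the exact-chain analyses
    exclude the replicator), the other three types otherwise.
    """
    kind = ScientistType.parse(kind)
    if rey_free and kind is ScientistType.REY:
        raise ConfigurationError("a Rey-dominant population cannot be Rey-free")
    others = [t for t in ScientistType if t is not kind]
    if rey_free:
        others = [t for t in others if t is not ScientistType.REY]
    weights = {t: (1.0 - dominance) / len(others) for t in others}
    weights[kind] = dominance
    return PopulationSpec(weights=weights, name=f"{kind.value}-dominant")


def diverse_population(rey_free: bool = False) -> PopulationSpec:
    """Equal representation of all types (of the proposing types if Rey-free)."""
    kinds = [t for t in ScientistType if not (rey_free and t is ScientistType.REY)]
    return PopulationSpec(
        weights={t: 1.0 / len(kinds) for t in kinds}, name="diverse"
    )


def markov_populations() -> dict:
    """The four replication-free presets of the exact-chain analyses."""
    return {
        "tess": dominant_population(ScientistType.TESS, rey_free=True),
        "mave": dominant_population(ScientistType.MAVE, rey_free=True),
        "bo": dominant_population(ScientistType.BO, rey_free=True),
        "diverse": diverse_population(rey_free=True),
    }


def abm_populations() -> dict:
    """The five ABM presets: four dominant populations and the diverse one."""
    out = {
        t.value: dominant_population(t) for t in ScientistType
    }
    out["diverse"] = diverse_population()
    return out


def default_true_models(space: ModelSpace) -> list:
    """Three true models spanning a gradient of complexity.

    TM1 = a single main effect, TM2 = all mains plus one two-way
    interaction, TM3 = the full model.
    """
    return [
        Model.from_label("1"),
        Model.from_label("1+2+3+12"),
        space.full_model,
    ]


# ---------------------------------------------------------------------------
# ABM factorial
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorialDesign:
    """A completely randomized factorial of ABM runs.

    Each (cell, replicate) gets an independent seed derived from
    ``base_seed`` and its coordinates, so results are reproducible and
    independent of execution order.
    """

    true_models: Sequence[Model]
    noise_ratios: Sequence[float] = (0.25, 1.0, 4.0)
    populations: Mapping = None  # name -> PopulationSpec
    statistics: Sequence[Statistic] = (Statistic.AIC, Statistic.SC)
    mode: StrategyMode = field(default_factory=StrategyMode.hard)
    replicates: int = 100
    iterations: int = 11000
    burn_in: int = 1000
    sample_size: int = 100
    base_seed: int = 0
    design_id: int = 0  # disambiguates seed streams when a study runs several designs

    def __post_init__(self) -> None:
        if self.populations is None:
            object.__setattr__(self, "populations", abm_populations())
        object.__setattr__(
            self, "statistics", tuple(Statistic.parse(s) for s in self.statistics)
        )
        object.__setattr__(
            self, "noise_ratios", tuple(parse_ratio(r) for r in self.noise_ratios)
        )
        if not (self.true_models and self.noise_ratios and self.populations
                and self.statistics and self.replicates >= 1):
            raise ConfigurationError("all design axes must be nonempty")

    def cells(self) -> list:
        """Deterministically ordered design cells."""
        out = []
        idx = 0
        for tm in self.true_models:
            for rho in self.noise_ratios:
                for pop_name, pop in self.populations.items():
                    for stat in self.statistics:
                        out.append((idx, tm, rho, pop_name, pop, stat))
                        idx += 1
        return out

    def rng_for(self, cell_index: int, replicate: int) -> np.random.Generator:
        ss = np.random.SeedSequence(
            entropy=self.base_seed, spawn_key=(self.design_id, cell_index, replicate)
        )
        return np.random.default_rng(ss)


def _run_row(design: FactorialDesign, cell, replicate: int) -> dict:
    cell_idx, tm, rho, pop_name, pop, stat = cell
    truth = TrueModelConfig(model=tm, noise_ratio=rho, sample_size=design.sample_size)
    config = ABMConfig(
        population=pop,
        truth=truth,
        statistic=stat,
        mode=design.mode,
        iterations=design.iterations,
        burn_in=design.burn_in,
    )
    result = run(config, design.rng_for(cell_idx, replicate))
    return {
        "cell": cell_idx,
        "true_model": tm.label,
        "noise_ratio": ratio_label(rho),
        "population": pop_name,
        "statistic": stat.value,
        "mode": "soft" if design.mode.soft else "hard",
        "replicate": replicate,
        "first_passage": result.first_passage_to_truth,
        "censored": result.censored,
        "time_at_truth": result.time_at_truth,
        "stickiness": result.empirical_stickiness,
        "repro_rate": result.repro_rate_overall,
        "repro_rate_truth": result.repro_rate_truth_global,
        "repro_rate_other": result.repro_rate_other,
    }


def run_design(design: FactorialDesign, progress: bool = False) -> pd.DataFrame:
    """Execute every cell x replicate; one row of metrics per run."""
    rows = []
    cells = design.cells()
    for cell in cells:
        for rep in range(design.replicates):
            rows.append(_run_row(design, cell, rep))
        if progress:  # pragma: no cover - console feedback only
            print(f"cell {cell[0] + 1}/{len(cells)} done", flush=True)
    return pd.DataFrame(rows)


def _iqr(x: pd.Series) -> float:
    q = x.dropna().quantile([0.25, 0.75])
    return float(q.loc[0.75] - q.loc[0.25])


_METRICS = ("time_at_truth", "stickiness", "first_passage", "repro_rate")


def summarize_runs(runs: pd.DataFrame, by: str = "population") -> pd.DataFrame:
    """Median and IQR of each metric per group, plus an overall margin.

    Censored first-passage values (truth never reached) enter the order
    statistics as +inf, so a median is reported as long as fewer than half
    the runs in a group are censored.
    """
    df = runs.copy()
    df["first_passage"] = df["first_passage"].astype(float)
    df.loc[df["censored"].astype(bool), "first_passage"] = np.inf
    frames = []
    groups = [(g, sub) for g, sub in df.groupby(by)] + [("overall", df)]
    for g, sub in groups:
        row = {by: g, "n_runs": len(sub)}
        for metric in _METRICS:
            vals = sub[metric].astype(float)
            row[f"{metric}_median"] = float(vals.median())
            row[f"{metric}_iqr"] = _iqr(vals)
            row[f"{metric}_mean"] = float(vals.mean())
        for metric in ("time_at_truth", "stickiness", "first_passage"):
            pairs = sub[["repro_rate", metric]].astype(float).replace(
                [np.inf, -np.inf], np.nan
            ).dropna()
            try:
                row[f"r_sr_repro_vs_{metric}"] = (
                    spearman_r(pairs["repro_rate"], pairs[metric])
                    if len(pairs) >= 3
                    else np.nan
                )
            except ConstantInputError:
                row[f"r_sr_repro_vs_{metric}"] = np.nan
        frames.append(row)
    return pd.DataFrame(frames)


class ConstantInputError(ValueError):
    """Spearman correlation is undefined for a constant sequence."""


def spearman_r(xs, ys) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1 or len(xs) < 3:
        raise ValueError("need two equal-length 1-d sequences of length >= 3")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise ConstantInputError("correlation undefined for constant input")
    return float(_sstats.spearmanr(xs, ys).statistic)


# ---------------------------------------------------------------------------
# exact-chain summaries
# ---------------------------------------------------------------------------

def markov_summary(
    populations: Mapping | None = None,
    statistics: Sequence[Statistic] = (Statistic.AIC, Statistic.SC),
    noise_ratio: float = 0.25,
    mode: StrategyMode | None = None,
    reps: int = 10_000,
    seed: int = 0,
    sample_size: int = 100,
    space: ModelSpace | None = None,
) -> tuple:
    """Chain metrics for every (population, statistic, true model).

    Returns ``(summary, mfpt_long)``: a per-condition table of stickiness,
    long-run time at the true model (pi), and mean first passage time
    averaged over initial models; and a heat-map-ready long table with one
    row per (initial model, true model) pair.  Win-probability tables are
    estimated once per (true model, statistic) and shared across
    populations.
    """
    if populations is None:
        populations = markov_populations()
    if mode is None:
        mode = StrategyMode.make_soft()
    if space is None:
        space = enumerate_space(3)
    statistics = [Statistic.parse(s) for s in statistics]
    rho = parse_ratio(noise_ratio)

    summary_rows = []
    mfpt_rows = []
    for si, stat in enumerate(statistics):
        for ti, tm in enumerate(space):
            truth = TrueModelConfig(model=tm, noise_ratio=rho, sample_size=sample_size)
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(si, ti))
            )
            w = win_probability_table(truth, space, stat, reps, rng)
            for pop_name, pop in populations.items():
                t = build_transition_matrix(pop, space, w, mode)
                metrics = chain_metrics(t, tm)
                summary_rows.append(
                    {
                        "population": pop_name,
                        "statistic": stat.value,
                        "true_model": tm.label,
                        "noise_ratio": ratio_label(rho),
                        "stickiness": metrics.stickiness,
                        "time_at_truth": metrics.time_at_truth,
                        "mean_mfpt": metrics.mean_mfpt,
                    }
                )
                for ii, initial in enumerate(space):
                    mfpt_rows.append(
                        {
                            "population": pop_name,
                            "statistic": stat.value,
                            "true_model": tm.label,
                            "initial_model": initial.label,
                            "mfpt": float(metrics.mfpt[ii]),
                        }
                    )
    return pd.DataFrame(summary_rows), pd.DataFrame(mfpt_rows)
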