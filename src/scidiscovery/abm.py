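"""Forward-in-time agent-based simulation with replication experiments.

Each time step one scientist is drawn from the population.  A proposing
type (Tess, Mave, Bo) draws a challenger from her proposal distribution,
generates a fresh dataset from the true model, and the AIC/SC contest
decides the next consensus.  Rey, the replicator, instead re-runs her
predecessor's exact (proposed, global) contest on new data; the result
*reproduces* the original when the win/lose outcome matches, and the
consensus is updated with Rey's own contest outcome.

Because a replication depends on the previous step's experiment, the
process with Rey is no longer a first-order Markov chain and is analyzed
by simulation; without Rey the simulation is the forward counterpart of
the exact chain in :mod:`scidiscovery.markov` (a cross-check used in the
test suite).

Performance note: a run precomputes the RSS of all space models on every
step's dataset with one batched least-squares pass, so the per-step loop
is pure bookkeeping.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .comparison import Statistic, contest, fit_mle, score, score_matrix
from .datagen import TrueModelConfig, generate_dataset, simulate_batch
from .markov import PopulationSpec
from .model_space import ConfigurationError, Model, ModelSpace, enumerate_space
from .strategies import ScientistType, StrategyMode, proposal_distribution, proposal_matrix

__all__ = [
    "ABMConfig",
    "ExperimentRecord",
    "ReproducibilityRates",
    "RunResult",
    "step",
    "run",
    "reproducibility_rates",
]

_PROPOSERS = (ScientistType.TESS, ScientistType.MAVE, ScientistType.BO)


@dataclass(frozen=True)
class ABMConfig:
    """Configuration of one ABM run (defaults match the study design:
    11000 iterations, 1000 burn-in, random non-true initial consensus)."""

    population: PopulationSpec
    truth: TrueModelConfig
    statistic: Statistic
    mode: StrategyMode = field(default_factory=StrategyMode.hard)
    iterations: int = 11000
    burn_in: int = 1000
    initial_model: Model | None = None  # None: uniform over non-true models
    mave_includes_global: bool = True
    rey_updates_global: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "statistic", Statistic.parse(self.statistic))
        if not (self.iterations > self.burn_in >= 0):
            raise ConfigurationError("need iterations > burn_in >= 0")
        if all(self.population[t] == 0.0 for t in _PROPOSERS):
            raise ConfigurationError("population must contain at least one proposing type")


@dataclass(frozen=True)
class ExperimentRecord:
    """One idealized experiment.

    For a replication, ``proposed`` and ``global_before`` are the
    *predecessor's* pair (which may differ from the current consensus when
    the predecessor's proposal won), and ``reproduced`` says whether the
    win/lose outcome matched; otherwise ``reproduced`` is ``None``.
    """

    time: int
    scientist: ScientistType
    proposed: Model
    global_before: Model
    score_proposed: float
    score_global: float
    proposed_won: bool
    global_after: Model
    is_replication: bool
    reproduced: bool | None = None


@dataclass(frozen=True)
class ReproducibilityRates:
    """Sample proportions of successful replications.

    Rates are ``None`` when no replication experiment fell in the
    corresponding stratum (undefined rather than zero).
    """

    overall: float | None
    at_truth: float | None  # replicated pair's global model == truth
    off_truth: float | None
    n_replications: int
    n_at_truth: int


def reproducibility_rates(
    records: Iterable[ExperimentRecord], truth_model: Model
) -> ReproducibilityRates:
    """Proportion of replications whose outcome matched the original,
    overall and stratified by whether the contested global model was true."""
    reps = [r for r in records if r.is_replication]
    at = [r for r in reps if r.global_before == truth_model]
    off = [r for r in reps if r.global_before != truth_model]

    def rate(rs):
        return sum(1 for r in rs if r.reproduced) / len(rs) if rs else None

    return ReproducibilityRates(
        overall=rate(reps),
        at_truth=rate(at),
        off_truth=rate(off),
        n_replications=len(reps),
        n_at_truth=len(at),
    )


def step(
    global_model: Model,
    predecessor: ExperimentRecord | None,
    config: ABMConfig,
    rng: np.random.Generator,
    space: ModelSpace | None = None,
    time: int = 0,
) -> tuple:
    """Execute one experiment; returns ``(new_global, record)``.

    The reference single-step implementation: draws a scientist, a
    proposal (or the predecessor's pair for Rey) and a fresh dataset, and
    fits both models.  :func:`run` uses a vectorized but decision-
    equivalent fast path.
    """
    if space is None:
        space = enumerate_space(config.truth.n_factors)
    kind = _draw_scientist(config.population, predecessor is not None, rng)
    is_rep = kind is ScientistType.REY
    if is_rep:
        proposed, contested = predecessor.proposed, predecessor.global_before
    else:
        dist = proposal_distribution(
            kind, global_model, space, config.mode, config.mave_includes_global
        )
        proposed, contested = dist.sample(rng), global_model
    data = generate_dataset(config.truth, rng)
    fit_p = fit_mle(proposed, data)
    fit_g = fit_mle(contested, data)
    s_p, s_g = score(fit_p, config.statistic), score(fit_g, config.statistic)
    if proposed == contested:
        won = False
    else:
        winner = contest(proposed, contested, data, config.statistic)
        won = winner == proposed
    if is_rep:
        reproduced = won == predecessor.proposed_won
        new_global = (proposed if won else contested) if config.rey_updates_global else global_model
    else:
        reproduced = None
        new_global = proposed if won else global_model
    record = ExperimentRecord(
        time=time,
        scientist=kind,
        proposed=proposed,
        global_before=contested,
        score_proposed=s_p,
        score_global=s_g,
        proposed_won=won,
        global_after=new_global,
        is_replication=is_rep,
        reproduced=reproduced,
    )
    return new_global, record


def _draw_scientist(
    pop: PopulationSpec, has_predecessor: bool, rng: np.random.Generator
) -> ScientistType:
    kinds = list(ScientistType)
    w = np.array([pop[k] for k in kinds])
    if not has_predecessor:
        # a replication needs a predecessor: redraw among proposing types
        w = np.array([pop[k] if k is not ScientistType.REY else 0.0 for k in kinds])
    w = w / w.sum()
    return kinds[rng.choice(len(kinds), p=w)]


@dataclass(frozen=True)
class RunResult:
    """One ABM trajectory and its derived metrics.

    ``states[t]`` is the consensus model index *after* experiment ``t``
    (``states[0]`` is the initial consensus).  First passage counts steps
    from t = 0 without discarding burn-in; all other metrics are computed
    over post-burn-in steps only.
    """

    config: ABMConfig
    space: ModelSpace
    states: np.ndarray  # (iterations + 1,) int
    scientists: np.ndarray  # (iterations,) int index into ScientistType
    proposed: np.ndarray  # (iterations,) int model index
    contested: np.ndarray  # (iterations,) int model index (global of the pair)
    proposed_won: np.ndarray  # (iterations,) bool
    is_replication: np.ndarray  # (iterations,) bool
    reproduced: np.ndarray  # (iterations,) bool (valid only where is_replication)
    score_proposed: np.ndarray
    score_global: np.ndarray
    first_passage_to_truth: int | None
    censored: bool
    time_at_truth: float
    empirical_stickiness: float | None
    repro: ReproducibilityRates

    @property
    def repro_rate_overall(self):
        return self.repro.overall

    @property
    def repro_rate_truth_global(self):
        return self.repro.at_truth

    @property
    def repro_rate_other(self):
        return self.repro.off_truth

    def records(self) -> list:
        """Materialize the per-step trace as ExperimentRecord objects."""
        kinds = list(ScientistType)
        out = []
        for t in range(len(self.proposed)):
            rep = bool(self.is_replication[t])
            out.append(
                ExperimentRecord(
                    time=t,
                    scientist=kinds[self.scientists[t]],
                    proposed=self.space[self.proposed[t]],
                    global_before=self.space[self.contested[t]],
                    score_proposed=float(self.score_proposed[t]),
                    score_global=float(self.score_global[t]),
                    proposed_won=bool(self.proposed_won[t]),
                    global_after=self.space[self.states[t + 1]],
                    is_replication=rep,
                    reproduced=bool(self.reproduced[t]) if rep else None,
                )
            )
        return out

    def trace_frame(self):
        import pandas as pd

        kinds = [t.value for t in ScientistType]
        labels = self.space.labels
        return pd.DataFrame(
            {
                "t": np.arange(len(self.proposed)),
                "scientist": [kinds[i] for i in self.scientists],
                "proposed": [labels[i] for i in self.proposed],
                "global_before": [labels[i] for i in self.contested],
                "score_proposed": self.score_proposed,
                "score_global": self.score_global,
                "proposed_won": self.proposed_won,
                "global_after": [labels[i] for i in self.states[1:]],
                "is_replication": self.is_replication,
                "reproduced": [
                    bool(r) if rep else None
                    for r, rep in zip(self.reproduced, self.is_replication)
                ],
            }
        )


def run(
    config: ABMConfig,
    rng: np.random.Generator,
    score_chunk: int = 20000,
) -> RunResult:
    """Simulate one full trajectory; reproducible given the generator state.

    Scores of all space models on every step's fresh dataset are
    precomputed in chunks; the sequential loop then only resolves
    proposals, replications and consensus updates.
    """
    space = enumerate_space(config.truth.n_factors)
    n_models = len(space)
    truth_idx = space.index(config.truth.model)
    iters = config.iterations

    # scores[t, m]: statistic of model m on the dataset of step t
    scores = np.empty((iters, n_models))
    models = list(space)
    done = 0
    while done < iters:
        r = min(score_chunk, iters - done)
        x, y = simulate_batch(config.truth, r, rng)
        scores[done : done + r] = score_matrix(models, x, y, config.statistic)
        done += r

    # per-type proposal CDFs over the space, one row per global model
    kinds = list(ScientistType)
    cdfs = {}
    for kind in _PROPOSERS:
        if config.population[kind] > 0:
            q = proposal_matrix(kind, space, config.mode, config.mave_includes_global)
            cdfs[kind] = [row.tolist() for row in np.cumsum(q, axis=1)]

    type_w = np.array([config.population[k] for k in kinds])
    type_w_nopred = np.where([k is ScientistType.REY for k in kinds], 0.0, type_w)
    type_cdf = np.cumsum(type_w / type_w.sum()).tolist()
    type_cdf_nopred = np.cumsum(type_w_nopred / type_w_nopred.sum()).tolist()

    if config.initial_model is not None:
        state = space.index(config.initial_model)
    else:
        others = [i for i in range(n_models) if i != truth_idx]
        state = others[rng.integers(len(others))]

    u_type = rng.random(iters)
    u_prop = rng.random(iters)

    states = np.empty(iters + 1, dtype=np.intp)
    states[0] = state
    scientists = np.empty(iters, dtype=np.intp)
    proposed_arr = np.empty(iters, dtype=np.intp)
    contested_arr = np.empty(iters, dtype=np.intp)
    won_arr = np.zeros(iters, dtype=bool)
    is_rep = np.zeros(iters, dtype=bool)
    reproduced = np.zeros(iters, dtype=bool)
    s_p_arr = np.empty(iters)
    s_g_arr = np.empty(iters)

    prev = None  # (proposed_idx, contested_idx, won)
    for t in range(iters):
        cdf = type_cdf if prev is not None else type_cdf_nopred
        k = min(bisect_right(cdf, u_type[t]), len(kinds) - 1)
        kind = kinds[k]
        if kind is ScientistType.REY:
            p, g, _ = prev
            rep = True
        else:
            p = min(bisect_right(cdfs[kind][state], u_prop[t]), n_models - 1)
            g = state
            rep = False
        s_p, s_g = scores[t, p], scores[t, g]
        won = bool(s_p < s_g) if p != g else False
        if rep:
            reproduced[t] = won == prev[2]
            new_state = (p if won else g) if config.rey_updates_global else state
        else:
            new_state = p if won else state
        scientists[t] = k
        proposed_arr[t] = p
        contested_arr[t] = g
        won_arr[t] = won
        is_rep[t] = rep
        s_p_arr[t] = s_p
        s_g_arr[t] = s_g
        states[t + 1] = new_state
        state = new_state
        prev = (p, g, won)

    return _finalize(
        config, space, truth_idx, states, scientists, proposed_arr,
        contested_arr, won_arr, is_rep, reproduced, s_p_arr, s_g_arr,
    )


def _finalize(
    config, space, truth_idx, states, scientists, proposed, contested,
    won, is_rep, reproduced, s_p, s_g,
) -> RunResult:
    iters, burn = config.iterations, config.burn_in
    hits = np.nonzero(states == truth_idx)[0]
    if hits.size:
        first_passage, censored = int(hits[0]), False
    else:
        first_passage, censored = None, True

    post = states[burn + 1 :]
    time_at_truth = float(np.mean(post == truth_idx))

    from_truth = states[burn:iters] == truth_idx
    if from_truth.any():
        stay = states[burn + 1 :][from_truth] == truth_idx
        emp_stick = float(np.mean(stay))
    else:
        emp_stick = None

    post_mask = np.arange(iters) >= burn
    rep_mask = is_rep & post_mask
    at_mask = rep_mask & (contested == truth_idx)
    off_mask = rep_mask & (contested != truth_idx)

    def rate(mask):
        return float(np.mean(reproduced[mask])) if mask.any() else None

    repro = ReproducibilityRates(
        overall=rate(rep_mask),
        at_truth=rate(at_mask),
        off_truth=rate(off_mask),
        n_replications=int(rep_mask.sum()),
        n_at_truth=int(at_mask.sum()),
    )
    return RunResult(
        config=config,
        space=space,
        states=states,
        scientists=scientists,
        proposed=proposed,
        contested=contested,
        proposed_won=won,
        is_replication=is_rep,
        reproduced=reproduced,
        score_proposed=s_p,
        score_global=s_g,
        first_passage_to_truth=first_passage,
        censored=censored,
        time_at_truth=time_at_truth,
        empirical_stickiness=emp_stick,
        repro=repro,
    )
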