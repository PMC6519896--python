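"""Exact Markov-chain analysis of the no-replication discovery process.

Without a replicator every step depends only on the current global model,
so the consensus trajectory is a first-order Markov chain on the model
space.  Given the per-type proposal matrices and a Monte-Carlo table of
pairwise win probabilities, the transition matrix is

    T[g -> m] = sum_types w_t * q_t(m | g) * p_win(m, g)     (m != g)
    T[g -> g] = 1 - sum_{m != g} T[g -> m]

(the diagonal collects lost contests, ties and self-proposals).  From T we
obtain the stationary distribution (long-run time at each model), mean
first passage times to the true model, and the true model's stickiness
T[truth -> truth].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from .comparison import Statistic, win_probability_table
from .datagen import TrueModelConfig
from .model_space import ConfigurationError, Model, ModelSpace
from .strategies import ScientistType, StrategyMode, proposal_matrix

__all__ = [
    "PopulationSpec",
    "TransitionMatrix",
    "ChainMetrics",
    "ReducibleChainError",
    "build_transition_matrix",
    "transition_matrix_for",
    "stationary_distribution",
    "mean_first_passage",
    "stickiness",
    "chain_metrics",
]


class ReducibleChainError(ConfigurationError):
    """No unique long-run behaviour; carries the communicating classes."""

    def __init__(self, classes, reason="chain is reducible"):
        self.classes = classes
        super().__init__(f"{reason}: {len(classes)} communicating classes")


@dataclass(frozen=True)
class PopulationSpec:
    """Proportions of scientist types in an (infinite) population."""

    weights: Mapping  # ScientistType -> float
    name: str = ""

    def __post_init__(self) -> None:
        w = {ScientistType.parse(k): float(v) for k, v in dict(self.weights).items()}
        for t in ScientistType:
            w.setdefault(t, 0.0)
        if any(v < 0 for v in w.values()):
            raise ConfigurationError("population weights must be nonnegative")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"population weights must sum to 1, got {total}")
        object.__setattr__(self, "weights", w)

    def __getitem__(self, kind) -> float:
        return self.weights[ScientistType.parse(kind)]

    @property
    def rey_free(self) -> bool:
        return self.weights[ScientistType.REY] == 0.0

    def proposer_types(self) -> list:
        return [
            t
            for t in (ScientistType.TESS, ScientistType.MAVE, ScientistType.BO)
            if self.weights[t] > 0
        ]


@dataclass(frozen=True)
class TransitionMatrix:
    """A row-stochastic transition matrix labelled by the model space."""

    space: ModelSpace
    matrix: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.matrix, dtype=float)
        m = len(self.space)
        if t.shape != (m, m):
            raise ConfigurationError(f"matrix must be {m}x{m}")
        if (t < -1e-12).any() or (t > 1 + 1e-12).any():
            raise ConfigurationError("entries must lie in [0, 1]")
        if np.abs(t.sum(axis=1) - 1.0).max() > 1e-12:
            raise ConfigurationError("rows must sum to 1")
        object.__setattr__(self, "matrix", t)

    def to_frame(self):
        import pandas as pd

        labels = self.space.labels
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


def build_transition_matrix(
    pop: PopulationSpec,
    space: ModelSpace,
    win_table: np.ndarray,
    mode: StrategyMode,
    mave_includes_global: bool = True,
) -> TransitionMatrix:
    """Assemble T from population weights, proposal matrices and win probs.

    ``win_table[p, g]`` is the probability that proposed model ``p``
    dethrones global model ``g`` (see
    :func:`scidiscovery.comparison.win_probability_table`).  Requires a
    replication-free population: with a replicator the process is no
    longer first-order Markov and must be simulated (see the ABM).
    """
    if not pop.rey_free:
        raise ConfigurationError("the Markov analysis requires a Rey-free population")
    w = np.asarray(win_table, dtype=float)
    m = len(space)
    if w.shape != (m, m):
        raise ConfigurationError("win table shape does not match the space")
    if np.isnan(w).any():
        raise ConfigurationError("win table has missing entries")
    t = np.zeros((m, m))
    for kind in pop.proposer_types():
        q = proposal_matrix(kind, space, mode, mave_includes_global)
        # q[g, p] * w[p, g]: probability this type proposes p and p wins
        t += pop[kind] * q * w.T
    np.fill_diagonal(t, 0.0)
    np.fill_diagonal(t, 1.0 - t.sum(axis=1))
    return TransitionMatrix(space=space, matrix=t)


def transition_matrix_for(
    pop: PopulationSpec,
    truth: TrueModelConfig,
    space: ModelSpace,
    stat: Statistic,
    mode: StrategyMode,
    reps: int,
    rng: np.random.Generator,
) -> TransitionMatrix:
    """Convenience: estimate the win table by Monte Carlo, then build T."""
    w = win_probability_table(truth, space, stat, reps, rng)
    return build_transition_matrix(pop, space, w, mode)


def _communicating_classes(t: np.ndarray):
    g = nx.DiGraph((int(i), int(j)) for i, j in zip(*np.nonzero(t > 0)))
    g.add_nodes_from(range(t.shape[0]))
    return [sorted(c) for c in nx.strongly_connected_components(g)]


def _closed_classes(t: np.ndarray, classes) -> list:
    out = []
    for c in classes:
        members = set(c)
        leaves = any(t[i, j] > 0 for i in c for j in range(t.shape[0]) if j not in members)
        if not leaves:
            out.append(c)
    return out


def stationary_distribution(tm: TransitionMatrix) -> np.ndarray:
    """The unique stationary distribution pi with pi T = pi.

    pi is unique exactly when the chain has a single closed communicating
    class (transient states — models whose Monte-Carlo win probability
    into the rest of the space rounded to zero — simply get pi = 0).
    With several closed classes the long-run behaviour depends on the
    start, and :class:`ReducibleChainError` reports the classes instead
    of returning a bogus distribution.
    """
    t = tm.matrix
    classes = _communicating_classes(t)
    if len(_closed_classes(t, classes)) > 1:
        raise ReducibleChainError(classes, "no unique stationary distribution")
    m = t.shape[0]
    a = t.T - np.eye(m)
    a[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def mean_first_passage(tm: TransitionMatrix, target: Model) -> np.ndarray:
    """Mean first passage time from every initial model to ``target``.

    Solves m_i = 1 + sum_{j != target} T[i, j] m_j; the entry at the
    target itself is 0.  Raises :class:`ReducibleChainError` when the
    target is not reachable from some state.
    """
    t = tm.matrix
    k = tm.space.index(target)
    m = t.shape[0]
    rest = [i for i in range(m) if i != k]
    reachable = _reaches(t, k)
    if not all(reachable[i] for i in rest):
        raise ReducibleChainError(_communicating_classes(t))
    q = t[np.ix_(rest, rest)]
    sol = np.linalg.solve(np.eye(m - 1) - q, np.ones(m - 1))
    out = np.zeros(m)
    out[rest] = sol
    return out


def _reaches(t: np.ndarray, target: int) -> np.ndarray:
    """States from which ``target`` is reachable (backward BFS)."""
    m = t.shape[0]
    seen = np.zeros(m, dtype=bool)
    seen[target] = True
    frontier = [target]
    while frontier:
        j = frontier.pop()
        for i in np.nonzero(t[:, j] > 0)[0]:
            if not seen[i]:
                seen[i] = True
                frontier.append(int(i))
    return seen


def stickiness(tm: TransitionMatrix, truth_model: Model) -> float:
    """One-step probability of staying at the true model: T[truth, truth]."""
    i = tm.space.index(truth_model)
    return float(tm.matrix[i, i])


@dataclass(frozen=True)
class ChainMetrics:
    """Derived chain quantities for one true model."""

    truth: Model
    stationary: np.ndarray
    mfpt: np.ndarray  # per initial model; 0 at the truth
    stickiness: float
    time_at_truth: float  # pi(truth)
    mean_mfpt: float  # averaged uniformly over initial models != truth


def chain_metrics(tm: TransitionMatrix, truth_model: Model) -> ChainMetrics:
    pi = stationary_distribution(tm)
    mfpt = mean_first_passage(tm, truth_model)
    i = tm.space.index(truth_model)
    others = [j for j in range(len(tm.space)) if j != i]
    return ChainMetrics(
        truth=truth_model,
        stationary=pi,
        mfpt=mfpt,
        stickiness=float(tm.matrix[i, i]),
        time_at_truth=float(pi[i]),
        mean_mfpt=float(mfpt[others].mean()),
    )
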