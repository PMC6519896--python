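"""Proposal strategies of the scientist types.

Three proposing types are defined over the model space:

* **Tess**, the theory tester — proposes uniformly among in-space models
  exactly one main-effect move away from the global model (adding a main,
  or dropping one together with every interaction containing it).
* **Mave**, the maverick — ignores the consensus and proposes uniformly
  from the whole space (including the current global model; a
  self-proposal resolves as a retain).
* **Bo**, the boundary tester — proposes uniformly among the models that
  add one interaction (plus its hierarchical closure) to the global model;
  at the full model, where no such move exists, she proposes the global
  model itself (a guaranteed retain).

**Rey**, the replicator, has no proposal distribution of her own: she
re-runs her predecessor's contest (see the ABM engine).

A *hard* strategy puts all mass on the type's strategy set; a *soft*
strategy moves a small probability epsilon onto off-strategy models,
which makes the induced Markov chain irreducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .model_space import (
    ConfigurationError,
    EmptyModelError,
    InvalidProposalError,
    Model,
    ModelSpace,
    add_main,
    drop_main,
    interaction_supersets,
)

__all__ = [
    "ScientistType",
    "StrategyMode",
    "ProposalDistribution",
    "tess_proposals",
    "mave_proposals",
    "bo_proposals",
    "strategy_set",
    "proposal_distribution",
    "proposal_matrix",
]


class ScientistType(enum.Enum):
    TESS = "tess"
    MAVE = "mave"
    BO = "bo"
    REY = "rey"

    @classmethod
    def parse(cls, value) -> "ScientistType":
        if isinstance(value, cls):
            return value
        return cls(str(value).strip().lower())


@dataclass(frozen=True)
class StrategyMode:
    """Hard or soft proposal mode.

    ``spread="complement"`` (default) puts the epsilon mass uniformly on
    models *outside* the strategy set; ``spread="all"`` mixes with a
    uniform over the whole space instead.
    """

    soft: bool = True
    epsilon: float = 0.1
    spread: str = "complement"

    def __post_init__(self) -> None:
        if self.spread not in ("complement", "all"):
            raise ConfigurationError(f"unknown spread {self.spread!r}")
        if not self.soft and self.epsilon != 0.0:
            raise ConfigurationError("hard mode requires epsilon = 0")
        if self.soft and not (0.0 <= self.epsilon < 1.0):
            raise ConfigurationError("epsilon must be in [0, 1)")

    @classmethod
    def hard(cls) -> "StrategyMode":
        return cls(soft=False, epsilon=0.0)

    @classmethod
    def make_soft(cls, epsilon: float = 0.1, spread: str = "complement") -> "StrategyMode":
        return cls(soft=True, epsilon=epsilon, spread=spread)


def tess_proposals(global_m: Model, space: ModelSpace) -> frozenset:
    """In-space models one main-effect move from the global model."""
    if global_m not in space:
        raise ConfigurationError(f"{global_m!r} not in space")
    out = set()
    for factor in range(1, space.n_factors + 1):
        main = frozenset({factor})
        try:
            if main in global_m.terms:
                candidate = drop_main(global_m, factor)
            else:
                candidate = add_main(global_m, factor)
        except (EmptyModelError, InvalidProposalError):
            continue
        if candidate in space:
            out.add(candidate)
    return frozenset(out)


def mave_proposals(space: ModelSpace, include_global: bool = True, global_m: Model | None = None) -> frozenset:
    """The whole space (optionally excluding the current global model)."""
    if include_global or global_m is None:
        return frozenset(space)
    return frozenset(m for m in space if m != global_m)


def bo_proposals(global_m: Model, space: ModelSpace) -> frozenset:
    """Interaction-adding supersets; at the full model, the global itself."""
    supersets = interaction_supersets(global_m, space)
    if supersets:
        return supersets
    return frozenset({global_m})


def strategy_set(
    kind: ScientistType,
    global_m: Model,
    space: ModelSpace,
    mave_includes_global: bool = True,
) -> frozenset:
    kind = ScientistType.parse(kind)
    if kind is ScientistType.TESS:
        return tess_proposals(global_m, space)
    if kind is ScientistType.MAVE:
        return mave_proposals(space, mave_includes_global, global_m)
    if kind is ScientistType.BO:
        return bo_proposals(global_m, space)
    raise ConfigurationError("Rey has no proposal distribution; see the ABM engine")


@dataclass(frozen=True)
class ProposalDistribution:
    """A probability distribution over space models."""

    probabilities: Mapping  # Model -> float

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
            raise ConfigurationError(f"probabilities must be a distribution (sum {total})")
        object.__setattr__(self, "probabilities", probs)

    def __getitem__(self, model: Model) -> float:
        return self.probabilities.get(model, 0.0)

    @property
    def support(self) -> frozenset:
        return frozenset(m for m, p in self.probabilities.items() if p > 0)

    def as_array(self, space: ModelSpace) -> np.ndarray:
        return np.array([self[m] for m in space])

    def sample(self, rng: np.random.Generator) -> Model:
        models = list(self.probabilities)
        probs = np.array([self.probabilities[m] for m in models])
        return models[rng.choice(len(models), p=probs / probs.sum())]


def proposal_distribution(
    kind: ScientistType,
    global_m: Model,
    space: ModelSpace,
    mode: StrategyMode,
    mave_includes_global: bool = True,
) -> ProposalDistribution:
    """The proposal distribution of a type given the current global model.

    Hard mode: uniform over the strategy set.  Soft mode: (1 - eps) times
    that uniform plus eps spread over off-strategy models (or over the
    whole space, per ``mode.spread``); when the complement is empty (Mave)
    all mass stays on the strategy set.
    """
    in_set = strategy_set(kind, global_m, space, mave_includes_global)
    if not in_set:
        raise ConfigurationError(f"empty strategy set for {kind} at {global_m!r}")
    probs = {m: 0.0 for m in space}
    if not mode.soft or mode.epsilon == 0.0:
        for m in in_set:
            probs[m] = 1.0 / len(in_set)
        return ProposalDistribution(probs)
    eps = mode.epsilon
    if mode.spread == "all":
        for m in in_set:
            probs[m] += (1.0 - eps) / len(in_set)
        for m in space:
            probs[m] += eps / len(space)
        return ProposalDistribution(probs)
    complement = [m for m in space if m not in in_set]
    if not complement:
        for m in in_set:
            probs[m] = 1.0 / len(in_set)
        return ProposalDistribution(probs)
    for m in in_set:
        probs[m] = (1.0 - eps) / len(in_set)
    for m in complement:
        probs[m] = eps / len(complement)
    return ProposalDistribution(probs)


def proposal_matrix(
    kind: ScientistType,
    space: ModelSpace,
    mode: StrategyMode,
    mave_includes_global: bool = True,
) -> np.ndarray:
    """Row-stochastic matrix Q with Q[g, m] = P(propose m | global g)."""
    q = np.zeros((len(space), len(space)))
    for g, global_m in enumerate(space):
        dist = proposal_distribution(kind, global_m, space, mode, mave_includes_global)
        q[g] = dist.as_array(space)
    return q
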