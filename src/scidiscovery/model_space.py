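"""Hierarchical linear-model space on a small number of factors.

A model is a set of predictor terms; a term is a nonempty set of factor
indices (``{1}`` is the main effect of factor 1, ``{1, 2}`` the two-way
interaction x1*x2, and so on).  All models are *hierarchical*: whenever an
interaction is present, every lower-order term it implies is present too.

The canonical space on three factors contains exactly 14 models, ranging
from the single-main-effect models up to the full 7-predictor model with
all three mains, all three two-way interactions and the three-way
interaction.  Membership in this space is what proposal strategies and the
Markov-chain analysis are defined over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Iterable, Iterator

__all__ = [
    "Term",
    "Model",
    "ModelSpace",
    "ModelSpaceError",
    "ConfigurationError",
    "InvalidProposalError",
    "EmptyModelError",
    "OutOfSpaceError",
    "term",
    "hierarchical_closure",
    "enumerate_space",
    "drop_main",
    "add_main",
    "interaction_supersets",
]


class ModelSpaceError(ValueError):
    """Base class for model-space errors."""


class ConfigurationError(ModelSpaceError):
    """Invalid configuration (e.g. a non-positive factor count)."""


class InvalidProposalError(ModelSpaceError):
    """A structural move (add/drop) whose precondition fails."""


class EmptyModelError(ModelSpaceError):
    """A move that would leave a model with no predictors."""


class OutOfSpaceError(ModelSpaceError):
    """A move whose result is not a member of the enumerated space."""


#: A predictor term: a frozenset of 1-based factor indices.
Term = frozenset


def term(*factors: int) -> Term:
    """Build a predictor term from factor indices, e.g. ``term(1, 2)`` = x1*x2."""
    if not factors:
        raise ConfigurationError("a term needs at least one factor")
    return frozenset(factors)


def _term_label(t: Term) -> str:
    return "".join(str(i) for i in sorted(t))


def _term_sort_key(t: Term) -> tuple:
    return (len(t), tuple(sorted(t)))


@dataclass(frozen=True)
class Model:
    """A hierarchical linear model, identified by its set of predictor terms.

    Models compare and hash by term-set equality, so they can be used as
    Markov-chain states and dictionary keys.  The canonical string label
    (``"1+2+12"`` for y = b1 x1 + b2 x2 + b12 x1 x2 + e) is used in CSV/JSON
    output and on the command line.
    """

    terms: frozenset  # frozenset[Term]

    @classmethod
    def from_terms(cls, terms: Iterable[Iterable[int]]) -> "Model":
        return cls(frozenset(frozenset(t) for t in terms))

    @classmethod
    def from_label(cls, label: str) -> "Model":
        """Parse a canonical label such as ``"1+2+12"``."""
        parts = [p for p in label.strip().split("+") if p]
        if not parts:
            raise ConfigurationError(f"empty model label: {label!r}")
        terms = []
        for p in parts:
            if not p.isdigit():
                raise ConfigurationError(f"bad term {p!r} in label {label!r}")
            terms.append(frozenset(int(c) for c in p))
        return cls.from_terms(terms)

    def __post_init__(self) -> None:
        if not self.terms:
            raise EmptyModelError("a model must have at least one term")
        for t in self.terms:
            if not t or any((not isinstance(i, int)) or i < 1 for i in t):
                raise ConfigurationError(f"invalid term {set(t)!r}")

    # -- structure -----------------------------------------------------
    @property
    def sorted_terms(self) -> list:
        return sorted(self.terms, key=_term_sort_key)

    @property
    def mains(self) -> frozenset:
        """Factor indices whose main effect is in the model."""
        return frozenset(next(iter(t)) for t in self.terms if len(t) == 1)

    @property
    def interactions(self) -> frozenset:
        return frozenset(t for t in self.terms if len(t) >= 2)

    @property
    def n_predictors(self) -> int:
        return len(self.terms)

    @property
    def n_interactions(self) -> int:
        return sum(1 for t in self.terms if len(t) >= 2)

    @property
    def label(self) -> str:
        return "+".join(_term_label(t) for t in self.sorted_terms)

    def is_hierarchical(self) -> bool:
        """True if every interaction's lower-order sub-terms are present."""
        for t in self.terms:
            for k in range(1, len(t)):
                for sub in combinations(sorted(t), k):
                    if frozenset(sub) not in self.terms:
                        return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Model({self.label})"


def hierarchical_closure(terms: Iterable[Iterable[int]]) -> Model:
    """Smallest hierarchical superset of ``terms``.

    Every nonempty subset of every given term is included: the closure of
    ``{x1x2x3}`` is the full 7-predictor model on three factors.
    """
    terms = [frozenset(t) for t in terms]
    if not terms:
        raise EmptyModelError("closure of the empty term set")
    closed = set()
    for t in terms:
        s = sorted(t)
        for k in range(1, len(s) + 1):
            closed.update(frozenset(c) for c in combinations(s, k))
    return Model(frozenset(closed))


@dataclass(frozen=True)
class ModelSpace:
    """The enumerated, ordered space of hierarchical models on ``n_factors``."""

    n_factors: int
    models: tuple  # tuple[Model, ...] ordered simple -> complex
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {m: i for i, m in enumerate(self.models)}
        )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[Model]:
        return iter(self.models)

    def __contains__(self, model: Model) -> bool:
        return model in self._index

    def __getitem__(self, i: int) -> Model:
        return self.models[i]

    def index(self, model: Model) -> int:
        try:
            return self._index[model]
        except KeyError:
            raise OutOfSpaceError(f"{model!r} is not in the space") from None

    @property
    def full_model(self) -> Model:
        return self.models[-1]

    @property
    def labels(self) -> list:
        return [m.label for m in self.models]

    @property
    def max_predictors(self) -> int:
        return max(m.n_predictors for m in self.models)

    def interaction_terms(self) -> list:
        """All interaction terms available in this space, low order first."""
        out = {t for m in self.models for t in m.terms if len(t) >= 2}
        return sorted(out, key=_term_sort_key)


def _model_sort_key(m: Model) -> tuple:
    # simple -> complex: predictor count, then interaction count, then label
    return (m.n_predictors, m.n_interactions, tuple(map(_term_sort_key, m.sorted_terms)))


def enumerate_space(n_factors: int) -> ModelSpace:
    """Enumerate the hierarchical model space on ``n_factors`` factors.

    The space consists of the hierarchical closures of every set
    "subset of main effects, plus at most one interaction term".  For three
    factors this yields exactly 14 distinct models: the 7 nonempty subsets
    of mains, the 3 models {xi, xj, xixj}, the 3 models
    {x1, x2, x3, xixj}, and the full 7-predictor model.  Factor counts
    other than 3 are supported but are outside the canonical analysis.
    """
    if not isinstance(n_factors, int) or n_factors < 1:
        raise ConfigurationError(f"n_factors must be a positive integer, got {n_factors!r}")
    factors = range(1, n_factors + 1)
    main_subsets = list(
        chain.from_iterable(combinations(factors, k) for k in range(0, n_factors + 1))
    )
    interactions = [
        frozenset(c)
        for k in range(2, n_factors + 1)
        for c in combinations(factors, k)
    ]
    seen = set()
    for mains in main_subsets:
        base = [frozenset({i}) for i in mains]
        if base:
            seen.add(hierarchical_closure(base))
        for inter in interactions:
            seen.add(hierarchical_closure(base + [inter]))
    models = tuple(sorted(seen, key=_model_sort_key))
    return ModelSpace(n_factors=n_factors, models=models)


def drop_main(model: Model, factor: int) -> Model:
    """Drop a main effect, and with it every interaction containing it.

    Raises ``InvalidProposalError`` if the main effect is absent and
    ``EmptyModelError`` if nothing would remain (callers must exclude the
    empty model from proposal sets).
    """
    if frozenset({factor}) not in model.terms:
        raise InvalidProposalError(f"main effect x{factor} not in {model!r}")
    remaining = frozenset(t for t in model.terms if factor not in t)
    if not remaining:
        raise EmptyModelError(f"dropping x{factor} from {model!r} leaves no predictors")
    return Model(remaining)


def add_main(model: Model, factor: int, space: ModelSpace | None = None) -> Model:
    """Add a main effect.  With ``space`` given, the result must be a member."""
    if frozenset({factor}) in model.terms:
        raise InvalidProposalError(f"main effect x{factor} already in {model!r}")
    result = Model(model.terms | {frozenset({factor})})
    if space is not None and result not in space:
        raise OutOfSpaceError(f"{result!r} is not in the space")
    return result


def interaction_supersets(model: Model, space: ModelSpace) -> frozenset:
    """In-space models formed by adding one interaction (plus its closure).

    For each interaction term not in ``model``, take the hierarchical
    closure of model-plus-term and keep it if it is a space member.  The
    result is empty exactly at the full model.
    """
    if model not in space:
        raise OutOfSpaceError(f"{model!r} is not in the space")
    out = set()
    for t in space.interaction_terms():
        if t in model.terms:
            continue
        candidate = hierarchical_closure(list(model.terms) + [t])
        if candidate != model and candidate in space:
            out.add(candidate)
    return frozenset(out)
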