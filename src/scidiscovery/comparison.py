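"""Gaussian linear-model fitting and AIC/SC model contests.

A proposed model dethrones the global model only when its statistic is
strictly smaller on the freshly generated data; ties and losses retain the
global model.  Both statistics are likelihood-based with the MLE error
variance sigma^2 = RSS/n, and k counts the error variance as a fitted
parameter (k = predictors + 1) — a convention that cancels in contests
between models that differ only in their predictors.

    AIC = 2 k - 2 logL_max        SC = k log(n) - 2 logL_max
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datagen import Dataset, TrueModelConfig, simulate_batch
from .model_space import Model, ModelSpace, ModelSpaceError

__all__ = [
    "Statistic",
    "FitResult",
    "WinEstimate",
    "DegenerateFitError",
    "design_matrix",
    "fit_mle",
    "score",
    "contest",
    "win_probability",
    "win_probability_table",
    "batched_rss",
    "score_matrix",
]

#: Relative RSS threshold under which a fit is treated as perfect (rss = 0).
_ZERO_RSS_RTOL = 1e-12


class DegenerateFitError(ModelSpaceError):
    """Rank-deficient design matrix."""


class Statistic(enum.Enum):
    """Model-comparison statistic; smaller is better."""

    AIC = "aic"
    SC = "sc"

    @classmethod
    def parse(cls, value) -> "Statistic":
        if isinstance(value, cls):
            return value
        return cls(str(value).strip().lower())

    def penalty(self, k: int, n: int) -> float:
        if self is Statistic.AIC:
            return 2.0 * k
        return k * math.log(n)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one model to one dataset."""

    model: Model
    coefficients: dict  # Term -> estimate
    rss: float
    max_loglik: float  # +inf sentinel when rss == 0
    k: int  # predictors + 1 (error variance counted)
    n: int

    @property
    def perfect(self) -> bool:
        return math.isinf(self.max_loglik)


def design_matrix(model: Model, predictors: np.ndarray) -> np.ndarray:
    """Column for each term (interaction = product of factor columns).

    Columns follow ``model.sorted_terms``; no intercept column is added.
    Accepts batched predictors (leading axes preserved).
    """
    cols = []
    for t in model.sorted_terms:
        col = np.ones(predictors.shape[:-1])
        for j in t:
            col = col * predictors[..., j - 1]
        cols.append(col)
    return np.stack(cols, axis=-1)


def fit_mle(model: Model, data: Dataset) -> FitResult:
    """Least-squares / Gaussian-MLE fit of ``model`` to ``data``.

    max logL = -(n/2) (log(2 pi sigma_hat^2) + 1) with sigma_hat^2 = RSS/n.
    A zero-RSS (perfect) fit gets a +inf log-likelihood sentinel; contests
    involving perfect fits are decided by parameter count alone.
    """
    x = design_matrix(model, data.predictors)
    y = data.response
    n, p = x.shape
    if n <= p:
        raise DegenerateFitError(f"n={n} too small for {p} predictors")
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < p:
        raise DegenerateFitError(f"design matrix of {model!r} is rank deficient")
    resid = y - x @ beta
    rss = float(resid @ resid)
    scale = float(y @ y) + 1.0
    if rss <= _ZERO_RSS_RTOL * scale:
        rss, loglik = 0.0, math.inf
    else:
        loglik = -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)
    coeffs = dict(zip(model.sorted_terms, beta.tolist()))
    return FitResult(model=model, coefficients=coeffs, rss=rss, max_loglik=loglik, k=p + 1, n=n)


def score(fit: FitResult, stat: Statistic) -> float:
    """AIC or SC of a fit; ``-inf`` for a perfect (rss = 0) fit."""
    stat = Statistic.parse(stat)
    if fit.perfect:
        return -math.inf
    return stat.penalty(fit.k, fit.n) - 2.0 * fit.max_loglik


def _proposed_wins(fit_p: FitResult, fit_g: FitResult, stat: Statistic) -> bool:
    # perfect fits: likelihood term dominates, then the penalty decides
    if fit_p.perfect and fit_g.perfect:
        return fit_p.k < fit_g.k
    s_p, s_g = score(fit_p, stat), score(fit_g, stat)
    return s_p < s_g


def contest(
    proposed: Model, global_m: Model, data: Dataset, stat: Statistic
) -> Model:
    """Run one proposed-vs-global contest on ``data``.

    The proposed model wins iff its statistic is strictly smaller;
    otherwise (including self-proposals and exact ties) the global model
    remains the consensus.
    """
    if proposed == global_m:
        return global_m
    stat = Statistic.parse(stat)
    fit_p = fit_mle(proposed, data)
    fit_g = fit_mle(global_m, data)
    return proposed if _proposed_wins(fit_p, fit_g, stat) else global_m


@dataclass(frozen=True)
class WinEstimate:
    """Monte-Carlo estimate of a win probability, with binomial SE."""

    probability: float
    se: float
    reps: int


def win_probability(
    proposed: Model,
    global_m: Model,
    truth: TrueModelConfig,
    stat: Statistic,
    reps: int,
    rng: np.random.Generator,
    chunk: int = 5000,
) -> WinEstimate:
    """Estimate P(proposed dethrones global) over independent datasets."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    stat = Statistic.parse(stat)
    if proposed == global_m:
        return WinEstimate(0.0, 0.0, reps)
    wins = 0
    done = 0
    models = [proposed, global_m]
    while done < reps:
        r = min(chunk, reps - done)
        x, y = simulate_batch(truth, r, rng)
        s = score_matrix(models, x, y, stat)
        wins += int(np.sum(s[:, 0] < s[:, 1]))
        done += r
    p = wins / reps
    se = math.sqrt(p * (1.0 - p) / reps)
    return WinEstimate(p, se, reps)


def batched_rss(models: Sequence[Model], x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """RSS of each model on each of a batch of datasets.

    ``x`` is (reps, n, n_factors), ``y`` is (reps, n); returns
    (reps, len(models)).  All models' design columns are taken from one
    shared Gram matrix of the union of terms, so the cost is one
    einsum plus a small batched solve per model.
    """
    all_terms = sorted(
        {t for m in models for t in m.terms}, key=lambda t: (len(t), tuple(sorted(t)))
    )
    col_of = {t: i for i, t in enumerate(all_terms)}
    f = np.empty(x.shape[:-1] + (len(all_terms),))  # (reps, n, P)
    for i, t in enumerate(all_terms):
        c = np.ones(x.shape[:-1])
        for j in t:
            c = c * x[..., j - 1]
        f[..., i] = c
    ft = f.transpose(0, 2, 1)
    gram = ft @ f
    xty = (ft @ y[..., None])[..., 0]
    yty = np.einsum("rn,rn->r", y, y)
    out = np.empty((x.shape[0], len(models)))
    for j, m in enumerate(models):
        idx = [col_of[t] for t in m.sorted_terms]
        g = gram[:, idx][:, :, idx]
        c = xty[:, idx]
        beta = np.linalg.solve(g, c[..., None])[..., 0]
        rss = yty - np.einsum("ri,ri->r", beta, c)
        out[:, j] = np.maximum(rss, 0.0)
    return out


def score_matrix(
    models: Sequence[Model], x: np.ndarray, y: np.ndarray, stat: Statistic
) -> np.ndarray:
    """AIC/SC of each model on each dataset of a batch; (reps, n_models).

    Zero-RSS fits map to ``-inf`` minus a parameter-count tiebreak so that
    elementwise ``<`` reproduces the contest rule (smaller k wins among
    perfect fits).  With positive noise variance zero RSS has probability
    zero, so the branch only matters in deterministic limiting runs.
    """
    stat = Statistic.parse(stat)
    n = y.shape[-1]
    rss = batched_rss(models, x, y)
    ks = np.array([m.n_predictors + 1 for m in models])
    scale = np.einsum("rn,rn->r", y, y)[:, None] + 1.0
    zero = rss <= _ZERO_RSS_RTOL * scale
    with np.errstate(divide="ignore"):
        m2ll = n * (np.log(2.0 * math.pi * rss / n) + 1.0)
    pen = np.array([stat.penalty(int(k), n) for k in ks])
    s = m2ll + pen[None, :]
    if zero.any():
        # perfect fits: strictly below every finite score, ordered by k
        s = np.where(zero, -1e18 + ks[None, :].astype(float), s)
    return s


def win_probability_table(
    truth: TrueModelConfig,
    space: ModelSpace,
    stat: Statistic,
    reps: int,
    rng: np.random.Generator,
    chunk: int = 5000,
) -> np.ndarray:
    """Monte-Carlo win probabilities for every (proposed, global) pair.

    Returns W with ``W[p, g]`` = estimated probability that model ``p``
    dethrones global model ``g`` under ``truth`` (diagonal 0).  One shared
    batch of datasets scores all models at once, so each pair's estimate
    uses the same ``reps`` datasets.
    """
    stat = Statistic.parse(stat)
    m = len(space)
    wins = np.zeros((m, m), dtype=np.int64)
    done = 0
    models = list(space)
    while done < reps:
        r = min(chunk, reps - done)
        x, y = simulate_batch(truth, r, rng)
        s = score_matrix(models, x, y, stat)
        wins += np.sum(s[:, :, None] < s[:, None, :], axis=0)
        done += r
    w = wins / reps
    np.fill_diagonal(w, 0.0)
    return w
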