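"""Synthetic data generation from a configured true linear model.

Each simulated experiment draws a fresh dataset: predictor rows i.i.d.
from a configurable law (default: each factor Normal(mean 1, sd 1)), and
the response y = sum_T theta_T prod_{j in T} x_j + eps with Gaussian noise.

The error variance is not set directly but *calibrated* through the
noise-to-signal ratio sigma^2 : E(y|mu_x), where E(y|mu_x) is the
deterministic part of the model evaluated at the predictor means.  A ratio
of 1:4 therefore means sigma^2 = E(y|mu_x) / 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model_space import ConfigurationError, Model, Term

__all__ = [
    "CalibrationError",
    "PredictorLaw",
    "TrueModelConfig",
    "Dataset",
    "parse_ratio",
    "expected_value_at_mean",
    "calibrate_sigma2",
    "generate_dataset",
    "simulate_batch",
    "deterministic_response",
]


class CalibrationError(ValueError):
    """The noise calibration is undefined (E(y|mu_x) <= 0)."""


def parse_ratio(ratio) -> float:
    """Convert a noise ratio to a float rho with sigma^2 = rho * E(y|mu_x).

    Accepts a number (returned as-is) or a string like ``"1:4"`` meaning
    sigma^2 : E(y|mu_x) = 1 : 4, i.e. rho = 0.25.
    """
    if isinstance(ratio, str):
        left, sep, right = ratio.partition(":")
        if not sep:
            rho = float(left)
        else:
            rho = float(left) / float(right)
    else:
        rho = float(ratio)
    if rho < 0:
        raise ConfigurationError(f"noise ratio must be nonnegative, got {ratio!r}")
    return rho


def ratio_label(rho: float) -> str:
    """Human-readable label for common ratios (``0.25`` -> ``"1:4"``)."""
    for num, den in ((1, 4), (1, 2), (1, 1), (2, 1), (4, 1)):
        if math.isclose(rho, num / den):
            return f"{num}:{den}"
    return f"{rho:g}:1"


@dataclass(frozen=True)
class PredictorLaw:
    """I.i.d. sampling law for the factor columns.

    ``kind`` is ``"normal"`` (mean/scale = mean and standard deviation) or
    ``"uniform"`` (mean/scale = midpoint and half-width).  A scalar mean or
    scale applies to every factor.
    """

    kind: str = "normal"
    mean: float | tuple = 1.0
    scale: float | tuple = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "uniform"):
            raise ConfigurationError(f"unknown predictor law {self.kind!r}")

    def means(self, n_factors: int) -> np.ndarray:
        m = np.broadcast_to(np.asarray(self.mean, dtype=float), (n_factors,))
        return np.array(m)

    def scales(self, n_factors: int) -> np.ndarray:
        s = np.broadcast_to(np.asarray(self.scale, dtype=float), (n_factors,))
        return np.array(s)

    def sample(self, shape: tuple, n_factors: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an array of factor values of shape ``shape + (n_factors,)``."""
        mu = self.means(n_factors)
        sc = self.scales(n_factors)
        if self.kind == "normal":
            return rng.normal(mu, sc, size=shape + (n_factors,))
        return rng.uniform(mu - sc, mu + sc, size=shape + (n_factors,))


def _default_coefficients(model: Model) -> dict:
    return {t: 1.0 for t in model.terms}


@dataclass(frozen=True)
class TrueModelConfig:
    """The data-generating mechanism: true model, coefficients, noise, n.

    ``noise_ratio`` is rho = sigma^2 / E(y|mu_x); pass a string like
    ``"1:4"`` via :func:`parse_ratio`.  Defaults follow the canonical
    study conditions: every coefficient 1.0, n = 100, predictors i.i.d.
    Normal(1, 1).
    """

    model: Model
    coefficients: Mapping = None  # Term -> float
    noise_ratio: float = 0.25
    sample_size: int = 100
    predictor_law: PredictorLaw = field(default_factory=PredictorLaw)
    n_factors: int = 3

    def __post_init__(self) -> None:
        coeffs = self.coefficients
        if coeffs is None:
            coeffs = _default_coefficients(self.model)
        coeffs = {frozenset(t): float(v) for t, v in dict(coeffs).items()}
        if set(coeffs) != set(self.model.terms):
            raise ConfigurationError(
                "coefficients must be keyed exactly by the model's terms"
            )
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "noise_ratio", parse_ratio(self.noise_ratio))
        if self.sample_size < self.model.n_predictors + 1:
            raise ConfigurationError(
                f"sample_size {self.sample_size} too small for "
                f"{self.model.n_predictors} predictors"
            )
        if any(max(t) > self.n_factors for t in self.model.terms):
            raise ConfigurationError("model uses factors beyond n_factors")

    @property
    def sigma2(self) -> float:
        return calibrate_sigma2(self)


@dataclass(frozen=True)
class Dataset:
    """One simulated dataset: an (n, n_factors) predictor matrix and y."""

    predictors: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.predictors, dtype=float)
        y = np.asarray(self.response, dtype=float)
        if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.shape[0]:
            raise ConfigurationError("predictors must be (n, k) and response (n,)")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ConfigurationError("dataset contains non-finite values")
        object.__setattr__(self, "predictors", x)
        object.__setattr__(self, "response", y)

    @property
    def n(self) -> int:
        return self.response.shape[0]

    def to_frame(self):
        import pandas as pd

        cols = {f"x{i + 1}": self.predictors[:, i] for i in range(self.predictors.shape[1])}
        cols["y"] = self.response
        return pd.DataFrame(cols)


def expected_value_at_mean(config: TrueModelConfig) -> float:
    """E(y|mu_x): the deterministic part evaluated at the predictor means."""
    mu = config.predictor_law.means(config.n_factors)
    total = 0.0
    for t, theta in config.coefficients.items():
        prod = 1.0
        for j in t:
            prod *= mu[j - 1]
        total += theta * prod
    if total <= 0:
        raise CalibrationError(
            f"E(y|mu_x) = {total:g} <= 0; the noise ratio is undefined"
        )
    return total


def calibrate_sigma2(config: TrueModelConfig) -> float:
    """Error variance implied by the noise ratio: sigma^2 = rho * E(y|mu_x)."""
    return config.noise_ratio * expected_value_at_mean(config)


def deterministic_response(model: Model, coefficients: Mapping, x: np.ndarray) -> np.ndarray:
    """Evaluate sum_T theta_T prod_{j in T} x_j row-wise.

    ``x`` has factor columns on its last axis; any leading batch axes are
    preserved.
    """
    out = np.zeros(x.shape[:-1])
    for t, theta in coefficients.items():
        prod = np.ones(x.shape[:-1])
        for j in t:
            prod = prod * x[..., j - 1]
        out += theta * prod
    return out


def generate_dataset(config: TrueModelConfig, rng: np.random.Generator) -> Dataset:
    """Draw one dataset of ``config.sample_size`` rows from the true model."""
    x, y = simulate_batch(config, 1, rng)
    return Dataset(predictors=x[0], response=y[0])


def simulate_batch(
    config: TrueModelConfig, reps: int, rng: np.random.Generator
) -> tuple:
    """Draw ``reps`` independent datasets at once.

    Returns ``(x, y)`` with shapes ``(reps, n, n_factors)`` and
    ``(reps, n)``.  This is the vectorized path used by the Monte-Carlo
    win-probability tables and the ABM precomputation.
    """
    n = config.sample_size
    x = config.predictor_law.sample((reps, n), config.n_factors, rng)
    mean = deterministic_response(config.model, config.coefficients, x)
    sigma2 = calibrate_sigma2(config)
    if sigma2 > 0:
        y = mean + rng.normal(0.0, math.sqrt(sigma2), size=(reps, n))
    else:
        y = mean
    return x, y
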