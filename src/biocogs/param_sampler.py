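"""Stochastic inputs for the uncertainty analyses.

Parameter uncertainty is modelled with triangular distributions whose
(minimum, mode, maximum) equal the worst/base/best scenario limits:
fermentation titer ~ Triangular(0.392, 0.484, 0.577) g/L and the DSP-yield
perturbation ~ Triangular(-10, 0, +10) percentage points; an optional
material-cost multiplier ~ Triangular(0.75, 1.00, 1.25) is available but
held at 1 by default.  Draws use an explicit inverse-CDF transform of
uniforms from numpy's seeded PCG64 generator, so identical seeds give
identical sequences on any platform.

`synthetic_mc_surface` generates a noisy linear CoG/g response surface with
known coefficients, used to validate the surrogate fitter independently of
the cost engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flowsheet import ConfigurationError

__all__ = [
    "TriangularDist",
    "ParameterDraw",
    "sample_triangular",
    "synthetic_mc_surface",
    "TITER_DIST",
    "DSP_YIELD_DELTA_DIST",
    "MATERIAL_MULTIPLIER_DIST",
]


@dataclass(frozen=True)
class TriangularDist:
    """Triangular distribution on [low, high] with the given mode."""

    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.mode <= self.high:
            raise ConfigurationError(
                f"need low <= mode <= high, got ({self.low}, {self.mode}, {self.high})"
            )
        if self.low == self.high:
            raise ConfigurationError("degenerate distribution: low == high")

    @property
    def mean(self) -> float:
        return (self.low + self.mode + self.high) / 3.0

    @property
    def variance(self) -> float:
        a, m, b = self.low, self.mode, self.high
        return (a * a + m * m + b * b - a * m - a * b - m * b) / 18.0

    def cdf(self, x: float) -> float:
        a, m, b = self.low, self.mode, self.high
        if x <= a:
            return 0.0
        if x >= b:
            return 1.0
        if x <= m:
            return (x - a) ** 2 / ((b - a) * (m - a)) if m > a else 0.0
        return 1.0 - (b - x) ** 2 / ((b - a) * (b - m))

    def ppf(self, q: np.ndarray | float) -> np.ndarray:
        """Inverse CDF (quantile function), vectorised."""
        q = np.asarray(q, dtype=float)
        a, m, b = self.low, self.mode, self.high
        fc = (m - a) / (b - a)
        left = a + np.sqrt(np.clip(q, 0.0, 1.0) * (b - a) * (m - a))
        right = b - np.sqrt(np.clip(1.0 - q, 0.0, 1.0) * (b - a) * (b - m))
        return np.where(q < fc, left, right)


#: Packaged distributions (scenario limits as triangular parameters).
TITER_DIST = TriangularDist(0.392, 0.484, 0.577)
DSP_YIELD_DELTA_DIST = TriangularDist(-10.0, 0.0, 10.0)
MATERIAL_MULTIPLIER_DIST = TriangularDist(0.75, 1.0, 1.25)


@dataclass(frozen=True)
class ParameterDraw:
    """One sampled parameter triple for a Monte Carlo run."""

    titer: float
    dsp_yield_delta: float
    material_multiplier: float = 1.0
    seed_index: int = 0


def sample_triangular(dist: TriangularDist, n: int, seed: int) -> np.ndarray:
    """``n`` reproducible triangular draws via inverse-CDF of PCG64 uniforms."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return dist.ppf(rng.random(n))


def synthetic_mc_surface(
    surrogate_truth: tuple[float, float, float],
    dists: tuple[TriangularDist, TriangularDist],
    n: int,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Synthetic (titer, dsp_yield_delta, cog) table from a known plane.

    ``cog = intercept + beta_titer * titer + beta_yield * delta + N(0, sd)``
    with ``surrogate_truth = (intercept, beta_titer, beta_yield)``.  Used to
    test the surrogate fitter without the cost engine.
    """
    if n < 3:
        raise ConfigurationError("n must be >= 3 to identify a plane")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    intercept, beta_titer, beta_yield = surrogate_truth
    titer_dist, delta_dist = dists
    rng = np.random.default_rng(seed)
    titer = titer_dist.ppf(rng.random(n))
    delta = delta_dist.ppf(rng.random(n))
    cog = intercept + beta_titer * titer + beta_yield * delta
    if noise_sd > 0:
        cog = cog + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"titer": titer, "dsp_yield_delta": delta, "cog": cog})


def standard_error_of_mean(dist: TriangularDist, n: int) -> float:
    """SE of the sample mean of ``n`` iid draws — handy for statistical tests."""
    return math.sqrt(dist.variance / n)
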