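"""Monte Carlo uncertainty analysis of CoG/g.

Titer and DSP-yield perturbations are drawn jointly and independently from
their triangular distributions, the cost engine is evaluated per draw, and a
cumulative moving average of CoG/g is tracked.  The run is declared
converged at the first index where the moving average changes by less than a
relative tolerance over a trailing window (defaults: window 50 runs,
tolerance 0.5%) — reported, not imposed; sampling always continues to
``n_max`` so the full cost cloud is available downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cost_engine
from .cost_engine import CostModelConfig
from .flowsheet import ConfigurationError, Flowsheet
from .param_sampler import (
    DSP_YIELD_DELTA_DIST,
    TITER_DIST,
    ParameterDraw,
    TriangularDist,
)

__all__ = ["MCResult", "run_monte_carlo", "convergence_check"]

DEFAULT_N_MAX = 1000
DEFAULT_WINDOW = 50
DEFAULT_TOL = 0.005


@dataclass(frozen=True)
class MCResult:
    draws: list[tuple[ParameterDraw, float]]
    moving_average: np.ndarray
    converged_at: int | None
    seed: int
    n_rejected: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "run": np.arange(1, len(self.draws) + 1),
            "titer": [d.titer for d, _ in self.draws],
            "dsp_yield_delta": [d.dsp_yield_delta for d, _ in self.draws],
            "material_multiplier": [d.material_multiplier for d, _ in self.draws],
            "cog": [c for _, c in self.draws],
            "moving_average": self.moving_average,
        }
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        cogs = np.array([c for _, c in self.draws])
        return {
            "seed": self.seed,
            "n_runs": int(len(cogs)),
            "converged_at": self.converged_at,
            "n_rejected": self.n_rejected,
            "mean": float(cogs.mean()),
            "sd": float(cogs.std(ddof=1)) if len(cogs) > 1 else 0.0,
            "min": float(cogs.min()),
            "max": float(cogs.max()),
        }


def run_monte_carlo(
    flowsheet: Flowsheet,
    config: CostModelConfig,
    dists: dict[str, TriangularDist] | None = None,
    n_max: int = DEFAULT_N_MAX,
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
    tol: float = DEFAULT_TOL,
) -> MCResult:
    """Drive the cost engine over ``n_max`` sampled parameter sets.

    ``dists`` may provide "titer", "dsp_yield_delta" and optionally
    "material_multiplier" distributions; by default the packaged titer and
    yield distributions vary and the material multiplier is held at 1.
    Draws whose yield perturbation leaves (0, 1] are rejected and resampled.
    Deterministic given ``seed``.
    """
    if n_max < 1:
        raise ConfigurationError("n_max must be >= 1")
    dists = dict(dists or {})
    titer_dist = dists.get("titer", TITER_DIST)
    delta_dist = dists.get("dsp_yield_delta", DSP_YIELD_DELTA_DIST)
    mult_dist = dists.get("material_multiplier")

    rng = np.random.default_rng(seed)
    draws: list[tuple[ParameterDraw, float]] = []
    n_rejected = 0
    while len(draws) < n_max:
        titer = float(titer_dist.ppf(rng.random()))
        delta = float(delta_dist.ppf(rng.random()))
        mult = float(mult_dist.ppf(rng.random())) if mult_dist is not None else 1.0
        try:
            result = cost_engine.cog_per_gram(
                flowsheet,
                config,
                titer=titer,
                dsp_yield_delta=delta,
                material_multiplier=mult,
            )
        except ConfigurationError:
            n_rejected += 1
            if n_rejected > 100 * n_max:
                raise ConfigurationError(
                    "rejection rate implausibly high; check distributions"
                )
            continue
        draw = ParameterDraw(titer, delta, mult, seed_index=len(draws))
        draws.append((draw, result.cog_per_gram))

    cogs = np.array([c for _, c in draws])
    moving_average = np.cumsum(cogs) / np.arange(1, len(cogs) + 1)
    converged = convergence_check(moving_average, window=window, tol=tol)
    return MCResult(
        draws=draws,
        moving_average=moving_average,
        converged_at=converged,
        seed=seed,
        n_rejected=n_rejected,
    )


def convergence_check(
    ma_series: np.ndarray, window: int = DEFAULT_WINDOW, tol: float = DEFAULT_TOL
) -> int | None:
    """First index ``n`` (0-based) where the moving average has stabilised.

    Stability means ``|MA_n - MA_{n-window}| / MA_n < tol``; the earliest
    checkable index is ``window``.  ``None`` if the series never satisfies
    the rule (or is shorter than the window).
    """
    if window < 2:
        raise ConfigurationError("window must be >= 2")
    ma = np.asarray(ma_series, dtype=float)
    for n in range(window, len(ma)):
        if abs(ma[n] - ma[n - window]) < tol * abs(ma[n]):
            return n
    return None
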