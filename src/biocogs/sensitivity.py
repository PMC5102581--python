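"""One-at-a-time scenario sensitivity analysis with tornado ranking.

Each variable (fermentation titer, DSP yield, material cost, labor location)
takes its best/base/worst scenario value while everything else is held at
base; the span ``|CoG/g(worst) - CoG/g(best)|`` ranks the variables in a
tornado plot ordering.  Note the labor scenarios carry the case study's
printed wage tables verbatim, in which the nominal "best" location's wages
are not uniformly the lowest — spans are absolute differences, so the
ranking is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import pandas as pd

from . import cost_engine
from .cost_engine import CostModelConfig
from .flowsheet import ConfigurationError, Flowsheet

__all__ = [
    "Scenario",
    "TornadoEntry",
    "uricase_scenarios",
    "run_scenarios",
    "tornado_rank",
]

SCENARIO_VARIABLES = ("titer", "dsp_yield", "material_cost", "labor_location")


@dataclass(frozen=True)
class Scenario:
    """Best/base/worst values of one sensitivity variable."""

    variable: str
    best_value: Any
    base_value: Any
    worst_value: Any

    def __post_init__(self) -> None:
        if self.variable not in SCENARIO_VARIABLES:
            raise ConfigurationError(
                f"unknown scenario variable {self.variable!r}; "
                f"expected one of {SCENARIO_VARIABLES}"
            )


@dataclass(frozen=True)
class TornadoEntry:
    variable: str
    cog_best: float
    cog_base: float
    cog_worst: float

    @property
    def span(self) -> float:
        return abs(self.cog_worst - self.cog_best)


def uricase_scenarios() -> list[Scenario]:
    """The packaged scenario grid.

    Titer in g/L; DSP yield as additive percentage points on the composite
    yield; material cost as a multiplier on the named material lines; labor
    as a wage-table location.
    """
    return [
        Scenario("titer", 0.577, 0.484, 0.392),
        Scenario("dsp_yield", +10.0, 0.0, -10.0),
        Scenario("material_cost", 0.75, 1.0, 1.25),
        Scenario("labor_location", "Mexico", "UK", "USA"),
    ]


def _evaluate(
    flowsheet: Flowsheet, config: CostModelConfig, variable: str, value: Any
) -> float:
    kwargs: dict[str, Any] = {}
    if variable == "titer":
        kwargs["titer"] = value
    elif variable == "dsp_yield":
        kwargs["dsp_yield_delta"] = value
    elif variable == "material_cost":
        kwargs["material_multiplier"] = value
    elif variable == "labor_location":
        kwargs["labor_location"] = value
    return cost_engine.cog_per_gram(flowsheet, config, **kwargs).cog_per_gram


def run_scenarios(
    flowsheet: Flowsheet,
    config: CostModelConfig,
    scenarios: list[Scenario] | None = None,
) -> list[TornadoEntry]:
    """Evaluate every scenario one variable at a time, others at base."""
    scenarios = scenarios if scenarios is not None else uricase_scenarios()
    entries = []
    for sc in scenarios:
        entries.append(
            TornadoEntry(
                variable=sc.variable,
                cog_best=_evaluate(flowsheet, config, sc.variable, sc.best_value),
                cog_base=_evaluate(flowsheet, config, sc.variable, sc.base_value),
                cog_worst=_evaluate(flowsheet, config, sc.variable, sc.worst_value),
            )
        )
    return entries


def tornado_rank(entries: list[TornadoEntry]) -> list[TornadoEntry]:
    """Entries sorted by span, largest first; ties broken alphabetically."""
    if not entries:
        raise ConfigurationError("tornado_rank needs at least one entry")
    return sorted(entries, key=lambda e: (-e.span, e.variable))


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [e.variable for e in entries],
            "cog_best": [e.cog_best for e in entries],
            "cog_base": [e.cog_base for e in entries],
            "cog_worst": [e.cog_worst for e in entries],
            "span": [e.span for e in entries],
        }
    )
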