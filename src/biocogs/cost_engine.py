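"""Transparent cost-of-goods engine.

Annual production cost is modelled as a fixed + per-batch-variable structure
over five categories::

    annual_cost = capital + other + labor
                  + batches x (materials_per_batch + consumables_per_batch)
    CoG/g       = annual_cost / annual_mass

with the batch count set by a constant annual target output,

    batches = target_output / (V x titer x dsp_yield),

so that higher titer or DSP yield spreads the variable costs over fewer
batches while fixed costs are spread over constant output.  UF/DF filter
consumables are volume-driven: the feed volume of the terminal UF/DF step
(from the flowsheet stream propagation) divided by the per-filter capacity,
rounded up.  Labor enters as a wage set (four roles per location) times a
headcount equivalent.

The engine is calibrated rather than bottom-up: per-category shares and the
base CoG/g total pin down the fixed costs and the residual variable lines
(`calibrate_fixture`), after which scenario, Monte Carlo and recycle analyses
are pure arithmetic on the calibrated structure.  For a flowsheet containing
a back-extraction operation the named ATPS material lines are charged at
their steady-state fresh-demand fractions and the (larger) diluted UF/DF
feed drives the filter count — the recycle economics therefore *emerge* from
the non-recycle calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .atps_model import RecycleSpec
from .flowsheet import ConfigurationError, Flowsheet, chain_yield, ufdf_feed_volume

__all__ = [
    "CalibrationError",
    "COST_CATEGORIES",
    "LABOR_ROLES",
    "CostModelConfig",
    "CoGResult",
    "batches_required",
    "ufdf_filter_count",
    "cog_per_gram",
    "breakdown_shares",
    "calibrate_fixture",
]


class CalibrationError(ValueError):
    """The requested calibration targets are infeasible."""


COST_CATEGORIES = ("capital", "materials", "consumables", "labor", "other")
LABOR_ROLES = ("production_operator", "production_supervisor", "quality_assurance", "qc")


@dataclass(frozen=True)
class CostModelConfig:
    """Calibrated cost structure for one flowsheet family.

    Monetary values are USD.  ``material_lines`` / ``consumable_lines`` are
    per-batch dollar lines; lines listed in ``scenario_material_items`` are
    the ones the +/-25% material-cost scenario (and the Monte Carlo material
    multiplier) touches.
    """

    annual_fixed: Mapping[str, float]  # {"capital": $, "other": $} per year
    labor_wages: Mapping[str, Mapping[str, float]]  # location -> role -> $/yr
    labor_base_location: str
    labor_headcount_equivalent: float
    material_lines: Mapping[str, float]  # per-batch $
    consumable_lines: Mapping[str, float]  # per-batch $, excluding UF/DF filters
    scenario_material_items: tuple[str, ...]
    ufdf_filter_capacity: float  # L per filter
    ufdf_filter_cost: float  # $ per filter
    target_output: float  # g per year
    batches_continuous: bool = True
    recycle: RecycleSpec = field(default_factory=RecycleSpec)

    def __post_init__(self) -> None:
        for cat in ("capital", "other"):
            if self.annual_fixed[cat] < 0:
                raise ConfigurationError(f"annual_fixed[{cat!r}] must be >= 0")
        for lines in (self.material_lines, self.consumable_lines):
            for name, value in lines.items():
                if value < 0:
                    raise ConfigurationError(f"cost line {name!r} must be >= 0")
        if self.labor_headcount_equivalent <= 0:
            raise ConfigurationError("labor_headcount_equivalent must be > 0")
        if self.ufdf_filter_capacity <= 0:
            raise ConfigurationError("ufdf_filter_capacity must be > 0")
        if self.ufdf_filter_cost < 0:
            raise ConfigurationError("ufdf_filter_cost must be >= 0")
        if self.target_output <= 0:
            raise ConfigurationError("target_output must be > 0")
        if self.labor_base_location not in self.labor_wages:
            raise ConfigurationError(
                f"labor_base_location {self.labor_base_location!r} missing from wage table"
            )

    def mean_wage(self, location: str) -> float:
        try:
            wages = self.labor_wages[location]
        except KeyError:
            raise ConfigurationError(
                f"unknown labor location {location!r}; have {sorted(self.labor_wages)}"
            ) from None
        return sum(wages.values()) / len(wages)

    def labor_annual(self, location: str | None = None) -> float:
        location = location or self.labor_base_location
        return self.labor_headcount_equivalent * self.mean_wage(location)


@dataclass(frozen=True)
class CoGResult:
    cog_per_gram: float
    category_costs: dict[str, float]  # $ per year per category
    annual_mass: float  # g
    batches: float

    def __post_init__(self) -> None:
        total = sum(self.category_costs.values())
        if any(v < 0 for v in self.category_costs.values()):
            raise ConfigurationError("category costs must be >= 0")
        if not math.isclose(self.cog_per_gram * self.annual_mass, total, rel_tol=1e-9):
            raise ConfigurationError(
                "CoG/g x annual mass must equal the summed category costs"
            )


def batches_required(
    target_output: float,
    fermenter_volume: float,
    titer: float,
    dsp_yield: float,
    continuous: bool = True,
) -> float:
    """Batches per year needed to hit the target output.

    ``target_output / (V x titer x dsp_yield)``; fractional in continuous
    mode, otherwise rounded up to whole batches.
    """
    if target_output <= 0 or fermenter_volume <= 0 or titer <= 0 or dsp_yield <= 0:
        raise ConfigurationError("batches_required arguments must all be > 0")
    if dsp_yield > 1.0:
        raise ConfigurationError("dsp_yield must be <= 1")
    n = target_output / (fermenter_volume * titer * dsp_yield)
    return n if continuous else float(math.ceil(n))


def ufdf_filter_count(volume: float, capacity: float) -> int:
    """Filters consumed to process ``volume`` litres at ``capacity`` L/filter."""
    if volume < 0:
        raise ConfigurationError("volume must be >= 0")
    if capacity <= 0:
        raise ConfigurationError("capacity must be > 0")
    return math.ceil(volume / capacity)


def _has_back_extraction(flowsheet: Flowsheet) -> bool:
    return any(op.category == "back_extraction" for op in flowsheet.operations)


def _fresh_factor(config: CostModelConfig, flowsheet: Flowsheet, line: str) -> float:
    """Steady-state fresh-demand fraction for a material line (1 without recycle)."""
    if not _has_back_extraction(flowsheet):
        return 1.0
    fractions = {
        "peg2000": 1.0 - config.recycle.r_peg,
        "ammonium_sulfate": 1.0 - config.recycle.r_as,
        "nacl": 1.0 - config.recycle.r_nacl,
    }
    return fractions.get(line, 1.0)


def materials_per_batch(
    config: CostModelConfig,
    flowsheet: Flowsheet,
    material_multiplier: float = 1.0,
) -> float:
    total = 0.0
    for line, cost in config.material_lines.items():
        m = material_multiplier if line in config.scenario_material_items else 1.0
        total += cost * m * _fresh_factor(config, flowsheet, line)
    return total


def consumables_per_batch(
    config: CostModelConfig,
    flowsheet: Flowsheet,
    material_multiplier: float = 1.0,
) -> float:
    filters = ufdf_filter_count(ufdf_feed_volume(flowsheet), config.ufdf_filter_capacity)
    m = material_multiplier if "ufdf_filters" in config.scenario_material_items else 1.0
    total = filters * config.ufdf_filter_cost * m
    total += sum(config.consumable_lines.values())
    return total


def cog_per_gram(
    flowsheet: Flowsheet,
    config: CostModelConfig,
    titer: float | None = None,
    dsp_yield_delta: float = 0.0,
    material_multiplier: float = 1.0,
    labor_location: str | None = None,
) -> CoGResult:
    """Cost of goods per gram under the given scenario parameters.

    ``dsp_yield_delta`` is additive in percentage points on the flowsheet's
    composite DSP yield (e.g. 43.2% -> 33.2% at delta = -10).
    """
    titer = flowsheet.titer if titer is None else titer
    if titer <= 0:
        raise ConfigurationError("titer must be > 0")
    if material_multiplier <= 0:
        raise ConfigurationError("material_multiplier must be > 0")
    dsp_yield = chain_yield(flowsheet) + dsp_yield_delta / 100.0
    if not 0.0 < dsp_yield <= 1.0:
        raise ConfigurationError(
            f"dsp_yield_delta {dsp_yield_delta:+g} points drives the DSP yield to "
            f"{dsp_yield:.4f}, outside (0, 1]"
        )
    batches = batches_required(
        config.target_output,
        flowsheet.fermenter_volume,
        titer,
        dsp_yield,
        config.batches_continuous,
    )
    category_costs = {
        "capital": float(config.annual_fixed["capital"]),
        "other": float(config.annual_fixed["other"]),
        "labor": config.labor_annual(labor_location),
        "materials": batches * materials_per_batch(config, flowsheet, material_multiplier),
        "consumables": batches
        * consumables_per_batch(config, flowsheet, material_multiplier),
    }
    annual_mass = batches * flowsheet.fermenter_volume * titer * dsp_yield
    total = sum(category_costs.values())
    return CoGResult(
        cog_per_gram=total / annual_mass,
        category_costs=category_costs,
        annual_mass=annual_mass,
        batches=batches,
    )


def breakdown_shares(result: CoGResult) -> dict[str, float]:
    """Fractional contribution of each cost category (sums to 1)."""
    total = sum(result.category_costs.values())
    if total <= 0:
        raise ConfigurationError("total cost must be > 0")
    return {cat: cost / total for cat, cost in result.category_costs.items()}


def calibrate_fixture(
    flowsheet: Flowsheet,
    target_cog: float,
    target_shares: Mapping[str, float],
    template: CostModelConfig,
) -> CostModelConfig:
    """Anchor a cost configuration to a printed base-case CoG/g and shares.

    Fixed categories (capital, other) and the labor headcount equivalent are
    set directly from the share vector; the residual per-batch ``materials``
    and ``consumables`` lines absorb whatever the named lines (media, ATPS
    chemicals, UF/DF filters) do not account for.  The returned config
    reproduces ``target_cog`` and ``target_shares`` exactly at base
    parameters (up to floating point).
    """
    if target_cog <= 0:
        raise CalibrationError("target_cog must be > 0")
    missing = set(COST_CATEGORIES) - set(target_shares)
    if missing:
        raise CalibrationError(f"target_shares missing categories: {sorted(missing)}")
    if not math.isclose(sum(target_shares.values()), 1.0, abs_tol=1e-9):
        raise CalibrationError(
            f"target_shares must sum to 1 (got {sum(target_shares.values()):.6f})"
        )
    if any(v < 0 for v in target_shares.values()):
        raise CalibrationError("target_shares must be non-negative")

    total_annual = target_cog * template.target_output
    batches = batches_required(
        template.target_output,
        flowsheet.fermenter_volume,
        flowsheet.titer,
        chain_yield(flowsheet),
        continuous=True,
    )

    headcount = target_shares["labor"] * total_annual / template.mean_wage(
        template.labor_base_location
    )
    if headcount <= 0:
        raise CalibrationError(
            "labor share inconsistent with the wage set: non-positive headcount"
        )

    named_materials = sum(
        cost for line, cost in template.material_lines.items() if line != "other_materials"
    )
    materials_budget = target_shares["materials"] * total_annual / batches
    other_materials = materials_budget - named_materials
    if other_materials < 0:
        raise CalibrationError(
            f"materials share {target_shares['materials']:.3f} leaves a negative "
            f"residual line (named lines ${named_materials:,.2f}/batch exceed the "
            f"budget ${materials_budget:,.2f}/batch)"
        )

    filters = ufdf_filter_count(ufdf_feed_volume(flowsheet), template.ufdf_filter_capacity)
    named_consumables = sum(
        cost
        for line, cost in template.consumable_lines.items()
        if line != "other_consumables"
    )
    consumables_budget = target_shares["consumables"] * total_annual / batches
    other_consumables = (
        consumables_budget - filters * template.ufdf_filter_cost - named_consumables
    )
    if other_consumables < 0:
        raise CalibrationError(
            f"consumables share {target_shares['consumables']:.3f} leaves a negative "
            f"residual line (UF/DF filters ${filters * template.ufdf_filter_cost:,.2f}"
            f"/batch exceed the budget ${consumables_budget:,.2f}/batch)"
        )

    material_lines = dict(template.material_lines)
    material_lines["other_materials"] = other_materials
    consumable_lines = dict(template.consumable_lines)
    consumable_lines["other_consumables"] = other_consumables

    return replace(
        template,
        annual_fixed={
            "capital": target_shares["capital"] * total_annual,
            "other": target_shares["other"] * total_annual,
        },
        labor_headcount_equivalent=headcount,
        material_lines=material_lines,
        consumable_lines=consumable_lines,
    )
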