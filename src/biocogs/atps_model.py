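"""Mass and volume balance for ATPS extraction and PEG/salt back-extraction.

The first aqueous two-phase system (ATPS) is built by mixing the clarified
homogenate with PEG2000 and ammonium sulfate; uricase partitions to the
PEG-rich top phase and the bottom phase is discarded.  In the recycle
variant a second system is then constructed from that top phase plus fresh
ammonium sulfate and dilution water, chosen so the salt fraction exceeds the
polymer fraction and the bottom phase is the larger one; the product is
forced into the bottom (salt-rich) phase while the second top phase returns
60% of the PEG and 20% of each salt to the next batch.

Everything here operates at the yield/volume level: partitioning is
all-or-nothing for the product (scaled by a recovery yield) and component
splits are fixed fractions, with density treated as 1 kg/L.  No binodal or
tie-line thermodynamics is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .flowsheet import ConfigurationError

__all__ = [
    "PhaseComposition",
    "Phase",
    "ATPSSpec",
    "RecycleSpec",
    "BackExtractionResult",
    "split_system",
    "back_extract",
    "steady_state_fresh_demand",
    "build_uricase_atps",
    "packaged_back_extraction",
]

COMPONENTS = ("peg2000", "ammonium_sulfate", "nacl")

#: Second-system volume per litre of original sample, fixed so that the
#: collected bottom phase (56% of the system) is exactly 10x the sample input.
SECOND_SYSTEM_VOLUME_PER_SAMPLE = 10.0 / 0.56


@dataclass(frozen=True)
class PhaseComposition:
    """%w/w of phase-forming components, plus the product mass carried."""

    peg: float
    ammonium_sulfate: float
    nacl: float
    product_mass: float = 0.0

    def __post_init__(self) -> None:
        for name in ("peg", "ammonium_sulfate", "nacl"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"PhaseComposition.{name} must be >= 0")
        if self.peg + self.ammonium_sulfate + self.nacl >= 100.0:
            raise ConfigurationError(
                "component percentages must sum to < 100 %w/w"
            )


@dataclass(frozen=True)
class Phase:
    """One phase of a system: volume plus absolute component/product masses."""

    volume: float  # L
    component_mass_kg: dict[str, float]
    product_mass: float = 0.0  # g

    @property
    def composition(self) -> PhaseComposition:
        """%w/w composition with density 1 kg/L."""
        total_kg = self.volume  # 1 kg/L
        pct = {c: 100.0 * self.component_mass_kg.get(c, 0.0) / total_kg for c in COMPONENTS}
        return PhaseComposition(
            peg=pct["peg2000"],
            ammonium_sulfate=pct["ammonium_sulfate"],
            nacl=pct["nacl"],
            product_mass=self.product_mass,
        )


@dataclass(frozen=True)
class ATPSSpec:
    """Geometry and component behaviour of the first ATPS.

    ``component_charge_per_sample_l`` is the kg of each phase-forming
    component added per litre of sample, and ``top_split`` the fraction of
    each component that reports to the top phase.
    """

    system_volume_multiplier: float = 12.0
    top_fraction: float = 0.4
    product_destination: str = "top"
    component_charge_per_sample_l: Mapping[str, float] = None  # type: ignore[assignment]
    top_split: Mapping[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 10.0 <= self.system_volume_multiplier <= 20.0:
            raise ConfigurationError(
                "system_volume_multiplier must lie in [10, 20] "
                f"(got {self.system_volume_multiplier})"
            )
        if not 0.0 < self.top_fraction < 1.0:
            raise ConfigurationError("top_fraction must be in (0, 1)")
        if self.product_destination not in ("top", "bottom"):
            raise ConfigurationError("product_destination must be 'top' or 'bottom'")
        if self.component_charge_per_sample_l is None:
            # Packaged charges: PEG2000 15 %w/w, (NH4)2SO4 13.3 %w/w and NaCl
            # 8 %w/w of the 12x system, expressed per litre of sample.
            object.__setattr__(
                self,
                "component_charge_per_sample_l",
                {"peg2000": 1.8, "ammonium_sulfate": 1.6, "nacl": 0.96},
            )
        if self.top_split is None:
            object.__setattr__(
                self,
                "top_split",
                {"peg2000": 0.65, "ammonium_sulfate": 0.35, "nacl": 0.5},
            )
        for c, f in self.top_split.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"top_split[{c!r}] must be in [0, 1]")


@dataclass(frozen=True)
class RecycleSpec:
    """Fractions of each per-batch component inventory reused via the
    second-system top phase, and the collected bottom fraction."""

    r_peg: float = 0.60
    r_as: float = 0.20
    r_nacl: float = 0.20
    bottom_fraction_second_system: float = 0.56
    #: Fresh ammonium sulfate added to the second system, kg per litre of sample.
    fresh_as_per_sample_l: float = 62.0 / 3.0 / 25.0

    def __post_init__(self) -> None:
        for name in ("r_peg", "r_as", "r_nacl", "bottom_fraction_second_system"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"RecycleSpec.{name} must be in [0, 1]")

    def fraction_for(self, component: str) -> float:
        return {
            "peg2000": self.r_peg,
            "ammonium_sulfate": self.r_as,
            "nacl": self.r_nacl,
        }[component]


@dataclass(frozen=True)
class BackExtractionResult:
    bottom_volume: float  # L, collected for UF/DF
    dilution_factor: float  # collected bottom volume / initial sample volume
    recycled_stream: Phase  # second-system top phase returned to system 1
    fresh_demand: dict[str, float]  # kg per batch at steady state
    bottom_phase: Phase
    second_system_volume: float

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1.0:
            raise ConfigurationError(
                "packaged back-extraction must dilute the sample (dilution_factor > 1)"
            )


def split_system(
    sample_volume: float, spec: ATPSSpec, recovery: float
) -> tuple[Phase, Phase]:
    """Construct the first ATPS and split it into (top, bottom) phases.

    Total system volume is ``system_volume_multiplier x sample_volume``;
    the product reports to ``spec.product_destination`` scaled by
    ``recovery``; component masses split per ``spec.top_split``.
    """
    if sample_volume <= 0:
        raise ConfigurationError("sample_volume must be > 0")
    if not 0.0 < recovery <= 1.0:
        raise ConfigurationError("recovery must be in (0, 1]")
    total_volume = spec.system_volume_multiplier * sample_volume
    top_volume = spec.top_fraction * total_volume
    bottom_volume = total_volume - top_volume
    charges = {
        c: spec.component_charge_per_sample_l[c] * sample_volume for c in COMPONENTS
    }
    top_mass = {c: charges[c] * spec.top_split[c] for c in COMPONENTS}
    bottom_mass = {c: charges[c] - top_mass[c] for c in COMPONENTS}
    # Product partition is all-or-nothing to the destination phase, scaled by
    # the step recovery; the mass is normalised to a unit input.
    to_top = recovery if spec.product_destination == "top" else 0.0
    top = Phase(top_volume, top_mass, to_top)
    bottom = Phase(bottom_volume, bottom_mass, recovery - to_top)
    return top, bottom


def back_extract(
    first_top: Phase,
    recycle: RecycleSpec,
    second_system_volume: float,
    *,
    sample_volume: float,
    fresh_ammonium_sulfate_kg: float,
    batch_inventory_kg: Mapping[str, float],
) -> BackExtractionResult:
    """Build the second ATPS from the first top phase and split it.

    The second system = first top phase + fresh (NH4)2SO4 + dilution water.
    The product migrates to the (larger, salt-rich) bottom phase which is
    collected for UF/DF; the top phase carries ``r_c x inventory_c`` of each
    component back to the first system of the next batch.
    """
    if second_system_volume < first_top.volume + fresh_ammonium_sulfate_kg:
        raise ConfigurationError(
            "second_system_volume smaller than its inputs; dilution water negative"
        )
    charges = {
        c: first_top.component_mass_kg.get(c, 0.0) for c in COMPONENTS
    }
    charges["ammonium_sulfate"] += fresh_ammonium_sulfate_kg

    # Preconditions printed for a working back-extraction.
    peg_pct = 100.0 * charges["peg2000"] / second_system_volume
    salt_pct = 100.0 * charges["ammonium_sulfate"] / second_system_volume
    if salt_pct <= peg_pct:
        raise ConfigurationError(
            "back-extraction requires salt %w/w > polymer %w/w in the second "
            f"system (got (NH4)2SO4 {salt_pct:.2f}% vs PEG {peg_pct:.2f}%)"
        )
    if recycle.bottom_fraction_second_system <= 0.5:
        raise ConfigurationError(
            "back-extraction requires the bottom phase to exceed the top phase "
            "(bottom_fraction_second_system > 0.5)"
        )

    bottom_volume = recycle.bottom_fraction_second_system * second_system_volume
    top_volume = second_system_volume - bottom_volume

    recycled_mass: dict[str, float] = {}
    bottom_mass: dict[str, float] = {}
    for c in COMPONENTS:
        target = recycle.fraction_for(c) * batch_inventory_kg[c]
        if target > charges[c] * (1.0 + 1e-12):
            raise ConfigurationError(
                f"recycle target for {c} ({target:.3f} kg) exceeds the mass "
                f"reaching the second system ({charges[c]:.3f} kg)"
            )
        recycled_mass[c] = target
        bottom_mass[c] = charges[c] - target

    recycled = Phase(top_volume, recycled_mass, 0.0)
    bottom = Phase(bottom_volume, bottom_mass, first_top.product_mass)
    fresh = steady_state_fresh_demand(recycle, batch_inventory_kg)
    return BackExtractionResult(
        bottom_volume=bottom_volume,
        dilution_factor=bottom_volume / sample_volume,
        recycled_stream=recycled,
        fresh_demand=fresh,
        bottom_phase=bottom,
        second_system_volume=second_system_volume,
    )


def steady_state_fresh_demand(
    recycle: RecycleSpec, per_batch_inventory: Mapping[str, float]
) -> dict[str, float]:
    """Fresh component demand per batch once recycling reaches steady state.

    With a fraction ``r`` of the inventory returned each batch, the fresh
    make-up is ``(1 - r) x inventory`` — the fixed point of the batch
    recursion, reached after the very first recycled batch.
    """
    return {
        c: (1.0 - recycle.fraction_for(c)) * per_batch_inventory[c]
        for c in per_batch_inventory
    }


def build_uricase_atps() -> tuple[ATPSSpec, RecycleSpec]:
    """The packaged first-system and recycle specifications."""
    return ATPSSpec(), RecycleSpec()


def batch_inventory_kg(
    spec: ATPSSpec, recycle: RecycleSpec, sample_volume: float
) -> dict[str, float]:
    """Total per-batch component inventory (first system charge + second-system
    fresh ammonium sulfate), in kg."""
    inv = {c: spec.component_charge_per_sample_l[c] * sample_volume for c in COMPONENTS}
    inv["ammonium_sulfate"] += recycle.fresh_as_per_sample_l * sample_volume
    return inv


def packaged_back_extraction(sample_volume: float = 25.0) -> BackExtractionResult:
    """Run the packaged two-stage configuration end to end.

    The second-system volume scales with the sample so the printed outputs
    (56% bottom collection, 10x dilution) hold at any scale.
    """
    spec, recycle = build_uricase_atps()
    top, _ = split_system(sample_volume, spec, recovery=1.0)
    inventory = batch_inventory_kg(spec, recycle, sample_volume)
    return back_extract(
        top,
        recycle,
        SECOND_SYSTEM_VOLUME_PER_SAMPLE * sample_volume,
        sample_volume=sample_volume,
        fresh_ammonium_sulfate_kg=recycle.fresh_as_per_sample_l * sample_volume,
        batch_inventory_kg=inventory,
    )
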