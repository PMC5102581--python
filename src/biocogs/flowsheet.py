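"""Bioprocess flowsheets as ordered unit operations.

A flowsheet is a purely economic abstraction of a bioprocess train: each unit
operation carries a step recovery yield and a volume factor, and the product
stream is propagated through them to obtain the composite downstream (DSP)
yield and the volumes that size volume-driven consumables (UF/DF filters).
No kinetics or physical modelling is attempted.

The packaged fixtures describe three routes to purified uricase from a 25 L
E. coli fermentation at ~0.5 g/L:

* ``chromatography`` — centrifuge, homogenizer, centrifuge, three sequential
  chromatography columns, UF/DF; composite DSP yield 43.2%.
* ``atps``           — the three columns replaced by a single aqueous
  two-phase extraction; composite DSP yield 66%.
* ``atps_recycle``   — the ATPS route with a back-extraction (second ATPS)
  inserted after the first, enabling PEG/salt recycle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "ConfigurationError",
    "UnitOperation",
    "Flowsheet",
    "StreamState",
    "chain_yield",
    "propagate_stream",
    "build_uricase_flowsheets",
    "CATEGORIES",
    "PROCESS_IDS",
]


class ConfigurationError(ValueError):
    """A flowsheet or configuration value violates its schema."""


CATEGORIES = frozenset(
    {
        "fermentation",
        "centrifugation",
        "homogenization",
        "chromatography",
        "atps",
        "back_extraction",
        "ufdf",
    }
)

PROCESS_IDS = ("chromatography", "atps", "atps_recycle")

#: Standard fermentation scale of the packaged uricase case study.
BASE_FERMENTER_VOLUME_L = 25.0
#: Base-scenario fermentation titer, g/L.
BASE_TITER_G_PER_L = 0.484
#: Composite DSP yields of the packaged routes.
CHROM_CHAIN_YIELD = 0.432
ATPS_CHAIN_YIELD = 0.66

# Recovery steps (centrifuges, homogenizer, UF/DF) are assigned a common
# generic yield; the column / ATPS yields are then solved so the composites
# come out at exactly 0.432 and 0.66.  Only the composites are observable.
_RECOVERY_STEP_YIELD = 0.95
#: Ratio of total first-ATPS system volume to sample input volume.
ATPS_SYSTEM_VOLUME_MULTIPLIER = 12.0
#: Fraction of the first-ATPS system volume forming the (product-rich) top phase.
ATPS_TOP_FRACTION = 0.4


@dataclass(frozen=True)
class UnitOperation:
    """One costed process step.

    ``step_yield`` is the fraction of product mass recovered by the step and
    ``volume_factor`` multiplies the incoming stream volume (e.g. the ATPS
    step dilutes the stream into the polymer/salt system; most steps are
    volume-neutral at this level of abstraction).
    """

    name: str
    category: str
    step_yield: float = 1.0
    volume_factor: float = 1.0
    material_items: tuple[str, ...] = ()
    consumable_items: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigurationError(
                f"operation {self.name!r}: category {self.category!r} is not one of "
                f"{sorted(CATEGORIES)}"
            )
        if not 0.0 < self.step_yield <= 1.0:
            raise ConfigurationError(
                f"operation {self.name!r}: step_yield must be in (0, 1], got {self.step_yield}"
            )
        if self.volume_factor <= 0.0:
            raise ConfigurationError(
                f"operation {self.name!r}: volume_factor must be > 0, got {self.volume_factor}"
            )


@dataclass(frozen=True)
class Flowsheet:
    process_id: str
    fermenter_volume: float
    titer: float
    operations: tuple[UnitOperation, ...]

    def __post_init__(self) -> None:
        if self.fermenter_volume <= 0:
            raise ConfigurationError("fermenter_volume must be > 0")
        if self.titer <= 0:
            raise ConfigurationError("titer must be > 0")
        if not self.operations:
            raise ConfigurationError(f"flowsheet {self.process_id!r} has no operations")
        if self.operations[0].category != "fermentation":
            raise ConfigurationError(
                f"flowsheet {self.process_id!r} must begin with a fermentation operation"
            )
        if self.operations[-1].category != "ufdf":
            raise ConfigurationError(
                f"flowsheet {self.process_id!r} must end with a UF/DF operation"
            )

    def downstream_operations(self) -> tuple[UnitOperation, ...]:
        """All operations after (and excluding) the initial fermentation."""
        return self.operations[1:]


@dataclass(frozen=True)
class StreamState:
    """Product stream leaving an operation: litres and grams of product."""

    volume: float
    product_mass: float


def chain_yield(flowsheet: Flowsheet) -> float:
    """Composite DSP yield: product of step yields downstream of fermentation.

    For the packaged routes this is 0.432 (chromatography) and 0.66 (ATPS and
    ATPS-with-recycle).
    """
    if not flowsheet.operations:  # pragma: no cover - unreachable via the type
        raise ConfigurationError("empty operation list")
    y = 1.0
    for op in flowsheet.downstream_operations():
        y *= op.step_yield
    return y


def propagate_stream(flowsheet: Flowsheet) -> list[StreamState]:
    """Propagate (volume, product mass) through every operation in order.

    The stream enters the first operation with the fermenter volume and the
    fermentation mass ``V x titer``; each operation then multiplies mass by its
    ``step_yield`` and volume by its ``volume_factor``.  The final entry's
    volume is the UF/DF feed used to size filter consumables.
    """
    volume = flowsheet.fermenter_volume
    mass = flowsheet.fermenter_volume * flowsheet.titer
    states: list[StreamState] = []
    for op in flowsheet.operations:
        if op.category != "fermentation":
            mass *= op.step_yield
        volume *= op.volume_factor
        states.append(StreamState(volume=volume, product_mass=mass))
    return states


def ufdf_feed_volume(flowsheet: Flowsheet) -> float:
    """Volume (L) entering the terminal UF/DF step."""
    states = propagate_stream(flowsheet)
    if len(states) < 2:
        return flowsheet.fermenter_volume
    return states[-2].volume


def _recovery_ops() -> list[UnitOperation]:
    ops = [
        UnitOperation("biomass recovery centrifuge", "centrifugation", _RECOVERY_STEP_YIELD),
        UnitOperation("high-pressure homogenizer", "homogenization", _RECOVERY_STEP_YIELD),
        UnitOperation("debris removal centrifuge", "centrifugation", _RECOVERY_STEP_YIELD),
    ]
    return ops


def build_uricase_flowsheets(
    fermenter_volume: float = BASE_FERMENTER_VOLUME_L,
    titer: float = BASE_TITER_G_PER_L,
) -> dict[str, Flowsheet]:
    """The three packaged uricase flowsheets, keyed by process id.

    Per-step yields are not individually observable; recovery steps are set to
    a generic 0.95 and the column/ATPS yields solved so the composite DSP
    yields equal exactly 0.432 and 0.66.
    """
    ferm = UnitOperation("E. coli fermentation", "fermentation", 1.0, 1.0)
    ufdf = UnitOperation(
        "UF/DF concentration & buffer exchange", "ufdf", _RECOVERY_STEP_YIELD, 1.0,
        consumable_items=("ufdf_filters",),
    )
    n_recovery = 4  # two centrifuges, homogenizer, UF/DF

    column_yield = (CHROM_CHAIN_YIELD / _RECOVERY_STEP_YIELD**n_recovery) ** (1.0 / 3.0)
    columns = [
        UnitOperation(f"chromatography column {i}", "chromatography", column_yield,
                      consumable_items=("resin",))
        for i in (1, 2, 3)
    ]
    chrom = Flowsheet(
        "chromatography",
        fermenter_volume,
        titer,
        tuple([ferm, *_recovery_ops(), *columns, ufdf]),
    )

    atps_yield = ATPS_CHAIN_YIELD / _RECOVERY_STEP_YIELD**n_recovery
    # The downstream stream leaving the ATPS step is the product-rich top
    # phase: system multiplier x top fraction = 12 x 0.4 = 4.8x the sample.
    atps_op = UnitOperation(
        "ATPS extraction", "atps", atps_yield,
        ATPS_SYSTEM_VOLUME_MULTIPLIER * ATPS_TOP_FRACTION,
        material_items=("peg2000", "ammonium_sulfate", "nacl"),
    )
    atps = Flowsheet(
        "atps",
        fermenter_volume,
        titer,
        tuple([ferm, *_recovery_ops(), atps_op, ufdf]),
    )

    # Back-extraction collects 56% of the second system, a stream 10x the
    # original sample input: 25 L -> 250 L, i.e. 250/120 of the top phase.
    back_extraction_volume_factor = 10.0 / (
        ATPS_SYSTEM_VOLUME_MULTIPLIER * ATPS_TOP_FRACTION
    )
    back_op = UnitOperation(
        "back-extraction (second ATPS)", "back_extraction", 1.0,
        back_extraction_volume_factor,
        material_items=("ammonium_sulfate",),
    )
    ops = list(atps.operations)
    ops.insert(ops.index(atps_op) + 1, back_op)
    atps_recycle = Flowsheet("atps_recycle", fermenter_volume, titer, tuple(ops))

    return {"chromatography": chrom, "atps": atps, "atps_recycle": atps_recycle}


def with_titer(flowsheet: Flowsheet, titer: float) -> Flowsheet:
    """A copy of ``flowsheet`` at a different fermentation titer."""
    return replace(flowsheet, titer=titer)
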