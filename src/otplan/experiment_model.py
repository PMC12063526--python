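"""In-memory model of the OT-2 deck and the stock inventory index.

Builds three things from validated records: a nested component → sample index
for resolving which stock row serves which sample (a stock row serves every
sample from its own sample index until the next row of the same component — a
step function), the initial :class:`DeckState` with each stock's well charged
with its available volume, and the row-major allocation of destination wells
on the Final labware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .csv_schemas import (
    LabwareRecord,
    StockRecord,
    split_well_location,
    well_grid,
    well_names,
)

__all__ = [
    "WellAddress",
    "LiquidState",
    "DeckState",
    "InventoryIndex",
    "ModelError",
    "build_inventory_index",
    "initialize_deck",
    "allocate_destination_wells",
    "deck_to_tsv",
]


class ModelError(ValueError):
    """Structural problem while building the deck or inventory model."""


@dataclass(frozen=True, order=True)
class WellAddress:
    labware_name: str
    well_id: str  # letter row + 1-based column, Opentrons convention (A1, B12, ...)

    def __str__(self) -> str:
        return f"{self.labware_name}:{self.well_id}"


def parse_well_address(location: str) -> WellAddress:
    parts = split_well_location(location)
    if parts is None:
        raise ModelError(f"malformed well location {location!r}; expected labware:well")
    return WellAddress(*parts)


@dataclass
class LiquidState:
    """Contents of one well: a volume and per-component 'mass-like' amounts.

    Amounts are concentration × volume totals in whatever unit the component's
    stock concentration carries, so amount / volume recovers a concentration
    in the same unit.
    """

    volume: float = 0.0
    composition: dict[str, float] = field(default_factory=dict)


@dataclass
class DeckState:
    slots: dict[int, LabwareRecord]
    labware_by_name: dict[str, LabwareRecord]
    wells: dict[WellAddress, LiquidState] = field(default_factory=dict)

    def well(self, addr: WellAddress) -> LiquidState:
        if addr.labware_name not in self.labware_by_name:
            raise ModelError(f"unknown labware {addr.labware_name!r}")
        lw = self.labware_by_name[addr.labware_name]
        if addr.well_id not in well_names(lw.labware_def):
            raise ModelError(f"well {addr} outside the {lw.labware_def} grid")
        return self.wells.setdefault(addr, LiquidState())

    def working_volume(self, addr: WellAddress) -> float:
        return self.labware_by_name[addr.labware_name].working_volume

    def copy(self) -> "DeckState":
        return DeckState(
            slots=dict(self.slots),
            labware_by_name=dict(self.labware_by_name),
            wells={a: LiquidState(s.volume, dict(s.composition)) for a, s in self.wells.items()},
        )

    def total_amounts(self) -> dict[str, float]:
        """Per-component amount summed over the whole deck (conservation check)."""
        totals: dict[str, float] = {}
        for state in self.wells.values():
            for comp, amt in state.composition.items():
                totals[comp] = totals.get(comp, 0.0) + amt
        return totals


@dataclass
class InventoryIndex:
    by_component: dict[str, dict[int, StockRecord]]
    component_order: list[str]  # first-occurrence order in the Stock Inventory file

    def resolve(self, component: str, sample: int) -> StockRecord:
        try:
            return self.by_component[component][sample]
        except KeyError:
            raise ModelError(f"no stock row serves component {component!r}, sample {sample}") from None


def build_inventory_index(stocks: list[StockRecord], n_samples: int) -> InventoryIndex:
    """Map every (component, sample) to its serving stock row.

    The row with the largest sample_index ≤ s serves sample s; a component
    whose first row starts above sample 0 leaves earlier samples unserved,
    which is an error (should have been caught by validation; raised
    defensively here).
    """
    rows_by_component: dict[str, list[StockRecord]] = {}
    order: list[str] = []
    for s in stocks:
        if s.component not in rows_by_component:
            order.append(s.component)
        rows_by_component.setdefault(s.component, []).append(s)

    by_component: dict[str, dict[int, StockRecord]] = {}
    for comp, rows in rows_by_component.items():
        rows = sorted(rows, key=lambda r: r.sample_index)
        if rows[0].sample_index > 0 and n_samples > 0:
            raise ModelError(
                f"component {comp!r}: first stock row starts at sample "
                f"{rows[0].sample_index}; samples 0..{rows[0].sample_index - 1} unserved"
            )
        mapping: dict[int, StockRecord] = {}
        k = 0
        for sample in range(n_samples):
            while k + 1 < len(rows) and rows[k + 1].sample_index <= sample:
                k += 1
            mapping[sample] = rows[k]
        by_component[comp] = mapping
    return InventoryIndex(by_component=by_component, component_order=order)


def initialize_deck(labware: list[LabwareRecord], stocks: list[StockRecord]) -> DeckState:
    """Place labware on slots and charge every stock well with its volume.

    Two rows of the *same* component in the same well pool their volumes
    (per-sample aliquots of one physical stock); two different components in
    one well is a collision and an error.
    """
    deck = DeckState(
        slots={lw.slot: lw for lw in labware},
        labware_by_name={lw.name: lw for lw in labware},
    )
    owner: dict[WellAddress, str] = {}
    for s in stocks:
        addr = parse_well_address(s.well_location)
        if addr in owner and owner[addr] != s.component:
            raise ModelError(
                f"well {addr} claimed by both {owner[addr]!r} and {s.component!r}"
            )
        owner[addr] = s.component
        state = deck.well(addr)
        state.volume += s.volume_available
        if s.stock_concentration > 0:
            state.composition[s.component] = (
                state.composition.get(s.component, 0.0)
                + s.stock_concentration * s.volume_available
            )
        if state.volume > deck.working_volume(addr):
            raise ModelError(
                f"stock volume {state.volume} µL in {addr} exceeds working volume "
                f"{deck.working_volume(addr)} µL"
            )
    return deck


def allocate_destination_wells(
    n_samples: int,
    final_labware: list[LabwareRecord],
    target_volume: float | None = None,
) -> dict[int, WellAddress]:
    """Assign samples to Final labware wells row-major, overflowing in file order."""
    finals = [lw for lw in final_labware if lw.is_final]
    if not finals:
        raise ModelError("no labware flagged as Final destination")
    if target_volume is not None:
        for lw in finals:
            if target_volume > lw.working_volume:
                raise ModelError(
                    f"target volume {target_volume} µL exceeds working volume "
                    f"{lw.working_volume} µL of final labware {lw.name!r}"
                )
    allocation: dict[int, WellAddress] = {}
    sample = 0
    for lw in finals:
        for well in well_names(lw.labware_def):
            if sample >= n_samples:
                return allocation
            allocation[sample] = WellAddress(lw.name, well)
            sample += 1
    if sample < n_samples:
        capacity = sum(len(well_names(lw.labware_def)) for lw in finals)
        raise ModelError(
            f"{n_samples} samples exceed the {capacity} wells available on Final labware"
        )
    return allocation


def deck_to_tsv(deck: DeckState) -> str:
    """Debug dump: one line per (well, component) with volume and amount."""
    lines = ["well\tvolume_ul\tcomponent\tamount"]
    for addr in sorted(deck.wells):
        state = deck.wells[addr]
        if not state.composition:
            lines.append(f"{addr}\t{state.volume:g}\t\t")
        for comp in sorted(state.composition):
            lines.append(f"{addr}\t{state.volume:g}\t{comp}\t{state.composition[comp]:g}")
    return "\n".join(lines) + "\n"
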