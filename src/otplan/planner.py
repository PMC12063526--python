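"""Transfer planning: dilution arithmetic, pipette choice and step ordering.

The core arithmetic is the C1·V1 = C2·V2 volume balance: to reach a target
concentration Ct in a final volume Vt from a stock at Cs, transfer
Vt·Ct/Cs µL of stock and make up the difference with diluent. The planner
applies this per (reagent, sample), walks reagents in Stock Inventory file
order (reagent-major: all samples of reagent A before any of reagent B),
assigns each step the pipette whose volume envelope fits best, splits volumes
too large for any pipette into equal parts, and pre-dilutes stocks whose
per-sample volumes would fall below the smallest pipettable volume.

All planning arithmetic runs on unrounded floats; volumes are rounded to
0.01 µL only when a plan is exported or rendered into a protocol script.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .csv_schemas import (
    ExperimentalDesign,
    LabwareRecord,
    PipetteConfig,
    StockRecord,
)
from .experiment_model import (
    DeckState,
    InventoryIndex,
    WellAddress,
    parse_well_address,
    well_names,
)

__all__ = [
    "Quantity",
    "PlanningError",
    "DilutionSpec",
    "TransferStep",
    "TransferPlan",
    "compute_transfer_volume",
    "compute_diluent_topup",
    "plan_predilution",
    "select_pipette",
    "build_transfer_plan",
    "plan_to_tsv",
    "plan_to_json",
]

EXPORT_DECIMALS = 2  # volumes exported / emitted at 0.01 µL resolution
_EPS = 1e-9


class Quantity(NamedTuple):
    """A concentration value with its unit tag ('' means dimensionless)."""

    value: float
    unit: str = ""


class PlanningError(ValueError):
    pass


@dataclass(frozen=True)
class DilutionSpec:
    """One pre-dilution: stock → intermediate at stock_concentration / factor."""

    component: str
    stock_concentration: float
    target_concentration: float
    target_volume: float  # intermediate volume built in the mixing well, µL
    transfer_volume: float  # stock aliquot moved into the mixing well, µL
    factor: float
    mixing_well: WellAddress


@dataclass(frozen=True)
class TransferStep:
    ordinal: int
    component: str
    source: WellAddress
    dest: WellAddress
    volume: float
    pipette_mount: str
    aspirate_rate: float
    dispense_rate: float
    purpose: str  # reagent | diluent_topup | predilution
    sample: int | None = None
    new_tip: bool = True
    pipette_min: float = 0.0
    pipette_max: float = math.inf


@dataclass
class PlanSummary:
    per_sample_volume: dict[int, float] = field(default_factory=dict)
    delivered_amount: dict[tuple[int, str], float] = field(default_factory=dict)


@dataclass
class TransferPlan:
    steps: list[TransferStep]
    predilutions: list[DilutionSpec]
    summary: PlanSummary
    sample_wells: dict[int, WellAddress]
    target_volumes: dict[int, float]


# ---------------------------------------------------------------------------
# elementary operations


def compute_transfer_volume(
    stock_concentration: Quantity | float,
    target_concentration: Quantity | float,
    target_volume: float,
) -> float:
    """Stock volume carrying the target amount: Vt·Ct/Cs (C1V1 = C2V2).

    A zero target returns 0 (the reagent is skipped for that sample); a target
    above the stock concentration is an impossible dilution.
    """
    cs = stock_concentration if isinstance(stock_concentration, Quantity) else Quantity(float(stock_concentration))
    ct = target_concentration if isinstance(target_concentration, Quantity) else Quantity(float(target_concentration))
    if cs.unit != ct.unit:
        raise PlanningError(
            f"unit mismatch: stock in {cs.unit or 'dimensionless'!r}, "
            f"target in {ct.unit or 'dimensionless'!r}"
        )
    if ct.value == 0:
        return 0.0
    if cs.value <= 0:
        raise PlanningError("stock concentration must be > 0 for a non-zero target")
    if target_volume <= 0:
        raise PlanningError("target volume must be > 0")
    if ct.value > cs.value:
        raise PlanningError(
            f"impossible dilution: target {ct.value} exceeds stock {cs.value}"
        )
    return ct.value * target_volume / cs.value


def compute_diluent_topup(target_volume: float, reagent_volumes: list[float]) -> float:
    """Diluent volume bringing a sample to its target volume (may be 0)."""
    if any(v < 0 for v in reagent_volumes):
        raise PlanningError("reagent volumes must be ≥ 0")
    total = math.fsum(reagent_volumes)
    remainder = target_volume - total
    if remainder < -_EPS * max(1.0, target_volume):
        raise PlanningError(
            f"over-specified sample: reagent volumes sum to {total:g} µL, "
            f"exceeding the {target_volume:g} µL target volume"
        )
    return max(remainder, 0.0)


def select_pipette(
    volume: float, pipettes: list[PipetteConfig]
) -> list[tuple[PipetteConfig, float]]:
    """Assign a pipette (splitting into equal parts when needed) to one volume.

    Rule: minimise the number of aspirate/dispense cycles; among pipettes
    achieving that minimum prefer the smallest max_volume (least relative
    error), ties broken toward the left mount. A volume in range of some
    pipette therefore goes to the smallest-max pipette that holds it in one
    go; a volume above every max is split into ceil(v / max) equal parts on
    the largest pipette. Equal parts avoid a remainder below min_volume.
    """
    if not pipettes:
        raise PlanningError("no pipette configured")
    if volume <= 0:
        raise PlanningError(f"cannot transfer a non-positive volume ({volume:g} µL)")

    candidates: list[tuple[int, float, int, PipetteConfig, float]] = []
    for p in pipettes:
        n = max(1, math.ceil(volume / p.max_volume - _EPS))
        sub = volume / n
        if p.min_volume - _EPS <= sub <= p.max_volume + _EPS:
            candidates.append((n, p.max_volume, 0 if p.mount == "left" else 1, p, sub))
    if not candidates:
        lo = min(p.min_volume for p in pipettes)
        if volume < lo:
            raise PlanningError(
                f"volume {volume:g} µL is below every pipette's minimum ({lo:g} µL); "
                "the stock needs pre-dilution (set its Diluent flag)"
            )
        raise PlanningError(f"no pipette can transfer {volume:g} µL")
    n, _, _, p, sub = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    return [(p, sub)] * n


def plan_predilution(
    stock: StockRecord,
    required_volumes: list[float],
    min_pipettable: float,
    mixing_labware: LabwareRecord,
    dilutant: StockRecord,
    mixing_well: WellAddress | None = None,
    pipettes: list[PipetteConfig] | None = None,
) -> tuple[DilutionSpec, list[TransferStep]]:
    """Build an intermediate dilution so per-sample volumes become pipettable.

    Chooses the smallest power-of-10 factor f with min(v)·f ≥ min_pipettable
    over the non-zero required volumes, then assembles stock + dilutant in one
    mixing well. The intermediate volume is the sum of the scaled per-sample
    draws, floored at min_pipettable·f so the stock aliquot itself (volume/f)
    stays pipettable. With f = 1 no steps are emitted.
    """
    positive = [v for v in required_volumes if v > 0]
    if mixing_well is None:
        mixing_well = WellAddress(mixing_labware.name, well_names(mixing_labware.labware_def)[0])
    if not positive or min(positive) >= min_pipettable:
        spec = DilutionSpec(
            component=stock.component,
            stock_concentration=stock.stock_concentration,
            target_concentration=stock.stock_concentration,
            target_volume=0.0,
            transfer_volume=0.0,
            factor=1.0,
            mixing_well=mixing_well,
        )
        return spec, []

    factor = 1.0
    while min(positive) * factor < min_pipettable - _EPS:
        factor *= 10.0
    intermediate = max(math.fsum(v * factor for v in positive), min_pipettable * factor)
    if intermediate > mixing_labware.working_volume + _EPS:
        raise PlanningError(
            f"pre-dilution of {stock.component!r} needs a {intermediate:g} µL intermediate "
            f"(factor {factor:g}), exceeding the {mixing_labware.working_volume:g} µL "
            f"working volume of mixing labware {mixing_labware.name!r}"
        )
    stock_part = intermediate / factor
    dilutant_part = intermediate - stock_part
    spec = DilutionSpec(
        component=stock.component,
        stock_concentration=stock.stock_concentration,
        target_concentration=stock.stock_concentration / factor,
        target_volume=intermediate,
        transfer_volume=stock_part,
        factor=factor,
        mixing_well=mixing_well,
    )
    steps: list[TransferStep] = []
    for comp, src, vol in (
        (stock.component, parse_well_address(stock.well_location), stock_part),
        (dilutant.component, parse_well_address(dilutant.well_location), dilutant_part),
    ):
        if vol <= 0:
            continue
        parts = select_pipette(vol, pipettes) if pipettes else [(None, vol)]
        for pip, sub in parts:
            steps.append(
                TransferStep(
                    ordinal=len(steps),
                    component=comp,
                    source=src,
                    dest=mixing_well,
                    volume=sub,
                    pipette_mount=pip.mount if pip else "",
                    aspirate_rate=(stock.speed or (pip.aspirate_rate if pip else 0.0)),
                    dispense_rate=(stock.speed or (pip.dispense_rate if pip else 0.0)),
                    purpose="predilution",
                    pipette_min=pip.min_volume if pip else 0.0,
                    pipette_max=pip.max_volume if pip else math.inf,
                )
            )
    return spec, steps


# ---------------------------------------------------------------------------
# full-plan assembly


@dataclass
class _Draft:
    component: str
    source: WellAddress
    dest: WellAddress
    volume: float
    purpose: str
    sample: int | None
    speed: float | None


def _sample_target_volume(
    index: InventoryIndex, components: list[str], sample: int
) -> float:
    volumes = {index.resolve(c, sample).target_volume for c in components}
    if len(volumes) > 1:
        raise PlanningError(
            f"sample {sample}: stock rows disagree on Target Volume ({sorted(volumes)})"
        )
    return volumes.pop()


def build_transfer_plan(
    design: ExperimentalDesign,
    index: InventoryIndex,
    deck: DeckState,
    labware: list[LabwareRecord],
    pipettes: list[PipetteConfig],
    dest_wells: dict[int, WellAddress],
    diluent_first: bool = False,
) -> TransferPlan:
    """Assemble the ordered transfer plan for a whole design.

    Reagents are walked in Stock Inventory file order and, within a reagent,
    samples in index order — reagent-major, so all of reagent A is dispensed
    before reagent B is touched. Zero design targets emit no step. A stock
    row's Transfer Volume overrides the computed dilution volume; its Speed
    overrides both pipette rates. Stock volumes are decremented per step and
    depletion is an error (rows are per-sample assignments; the planner never
    silently switches to another row). After the reagents one diluent top-up
    per sample brings it to its target volume; ``diluent_first`` moves those
    steps to the front of the plan instead.
    """
    if not pipettes:
        raise PlanningError("no pipette configured")
    n = design.n_samples
    min_pipettable = min(p.min_volume for p in pipettes)
    mixing = [lw for lw in labware if lw.is_mixing]

    reagent_components = [c for c in index.component_order if c in design.reagent_names]
    dilutants = [
        index.by_component[c][0]
        for c in index.component_order
        if index.by_component[c] and next(iter(index.by_component[c].values())).is_dilutant
    ]
    dilutant_rows = {c: index.by_component[c] for c in index.component_order
                     if any(r.is_dilutant for r in index.by_component[c].values())}

    target_volumes = {
        s: _sample_target_volume(index, reagent_components or list(index.component_order), s)
        for s in range(n)
    }

    remaining: dict[int, float] = {id(r): r.volume_available
                                   for rows in index.by_component.values()
                                   for r in set(rows.values())}

    def draw(row: StockRecord, volume: float, what: str) -> None:
        key = id(row)
        if remaining[key] < volume - _EPS:
            raise PlanningError(
                f"stock of {row.component!r} depleted: {what} needs {volume:g} µL but "
                f"only {remaining[key]:g} µL of the {row.volume_available:g} µL remains"
            )
        remaining[key] -= volume

    drafts: list[_Draft] = []
    predilutions: list[DilutionSpec] = []
    per_sample_volumes: dict[int, list[float]] = {s: [] for s in range(n)}
    summary = PlanSummary(per_sample_volume={}, delivered_amount={})
    mixing_cursor = 0

    for comp in reagent_components:
        ridx = design.reagent_names.index(comp)
        rows = index.by_component[comp]
        # per-sample required volumes straight from C1V1=C2V2 (or the override)
        required: dict[int, float] = {}
        for s in range(n):
            row = rows[s]
            target = design.targets[s][ridx]
            if target == 0:
                continue  # reagent skipped for this sample
            if row.transfer_volume_override is not None:
                if row.needs_predilution:
                    raise PlanningError(
                        f"component {comp!r}: Transfer Volume override cannot be combined "
                        "with the Diluent (pre-dilution) flag"
                    )
                required[s] = row.transfer_volume_override
            else:
                required[s] = compute_transfer_volume(
                    Quantity(row.stock_concentration, row.concentration_unit),
                    Quantity(target, row.concentration_unit),
                    target_volumes[s],
                )
        any_row = rows[0] if rows else None
        needs_predilution = any(rows[s].needs_predilution for s in required)

        factor = 1.0
        intermediate_source: WellAddress | None = None
        if needs_predilution and required:
            if not mixing:
                raise PlanningError(
                    f"component {comp!r} needs pre-dilution but no Mixing labware is defined"
                )
            if not dilutants:
                raise PlanningError(
                    f"component {comp!r} needs pre-dilution but no Dilutant reagent is defined"
                )
            mix_lw = mixing[0]
            mix_names = well_names(mix_lw.labware_def)
            if mixing_cursor >= len(mix_names):
                raise PlanningError("out of mixing wells for pre-dilutions")
            row0 = rows[min(required)]
            dil = dilutant_rows[dilutants[0].component][min(required)]
            spec, steps = plan_predilution(
                row0,
                list(required.values()),
                min_pipettable,
                mix_lw,
                dil,
                mixing_well=WellAddress(mix_lw.name, mix_names[mixing_cursor]),
                pipettes=pipettes,
            )
            factor = spec.factor
            if factor > 1.0:
                mixing_cursor += 1
                predilutions.append(spec)
                intermediate_source = spec.mixing_well
                draw(row0, spec.transfer_volume, f"pre-dilution of {comp!r}")
                dil_vol = spec.target_volume - spec.transfer_volume
                if dil_vol > 0:
                    draw(dil, dil_vol, f"pre-dilution of {comp!r}")
                for st in steps:
                    drafts.append(
                        _Draft(st.component, st.source, st.dest, st.volume,
                               "predilution", None, row0.speed)
                    )

        for s in sorted(required):
            row = rows[s]
            vol = required[s]
            if factor > 1.0:
                source = intermediate_source
                vol = vol * factor  # intermediate is 1/f the concentration
                conc = row.stock_concentration / factor
            else:
                source = parse_well_address(row.well_location)
                conc = row.stock_concentration
                draw(row, vol, f"sample {s}")
            per_sample_volumes[s].append(vol)
            summary.delivered_amount[(s, comp)] = (
                summary.delivered_amount.get((s, comp), 0.0) + conc * vol
            )
            drafts.append(_Draft(comp, source, dest_wells[s], vol, "reagent", s, row.speed))

    # one diluent top-up per sample, balancing to the target volume
    topups: list[_Draft] = []
    for s in range(n):
        topup = compute_diluent_topup(target_volumes[s], per_sample_volumes[s])
        if topup <= 0:
            summary.per_sample_volume[s] = math.fsum(per_sample_volumes[s])
            continue
        if not dilutants:
            raise PlanningError(
                f"sample {s} needs a {topup:g} µL diluent top-up but no Dilutant reagent is defined"
            )
        dil_row = dilutant_rows[dilutants[0].component][s]
        draw(dil_row, topup, f"top-up of sample {s}")
        if dil_row.stock_concentration > 0:
            summary.delivered_amount[(s, dil_row.component)] = (
                summary.delivered_amount.get((s, dil_row.component), 0.0)
                + dil_row.stock_concentration * topup
            )
        topups.append(
            _Draft(dil_row.component, parse_well_address(dil_row.well_location),
                   dest_wells[s], topup, "diluent_topup", s, dil_row.speed)
        )
        summary.per_sample_volume[s] = math.fsum(per_sample_volumes[s]) + topup

    ordered = topups + drafts if diluent_first else drafts + topups

    # expand to pipette-assigned steps, then decide tips on the final order
    steps: list[TransferStep] = []
    occupied = {addr for addr, st in deck.wells.items() if st.volume > 0}
    prev_component: str | None = None
    for d in ordered:
        for pip, sub in select_pipette(d.volume, pipettes):
            new_tip = d.component != prev_component or d.dest in occupied
            steps.append(
                TransferStep(
                    ordinal=len(steps),
                    component=d.component,
                    source=d.source,
                    dest=d.dest,
                    volume=sub,
                    pipette_mount=pip.mount,
                    aspirate_rate=d.speed if d.speed is not None else pip.aspirate_rate,
                    dispense_rate=d.speed if d.speed is not None else pip.dispense_rate,
                    purpose=d.purpose,
                    sample=d.sample,
                    new_tip=new_tip,
                    pipette_min=pip.min_volume,
                    pipette_max=pip.max_volume,
                )
            )
            prev_component = d.component
            occupied.add(d.dest)

    # destination capacity check against the final labware working volume
    for s, total in summary.per_sample_volume.items():
        wv = deck.working_volume(dest_wells[s])
        if total > wv + _EPS:
            raise PlanningError(
                f"sample {s} volume {total:g} µL exceeds working volume {wv:g} µL"
            )

    return TransferPlan(
        steps=steps,
        predilutions=predilutions,
        summary=summary,
        sample_wells=dict(dest_wells),
        target_volumes=target_volumes,
    )


# ---------------------------------------------------------------------------
# exports (volumes rounded to 0.01 µL here, and only here)


def _round(v: float) -> float:
    return round(v, EXPORT_DECIMALS)


def plan_to_tsv(plan: TransferPlan) -> str:
    cols = ("ordinal", "purpose", "component", "source_labware", "source_well",
            "dest_labware", "dest_well", "volume_ul", "pipette_mount",
            "aspirate_rate", "dispense_rate")
    lines = ["\t".join(cols)]
    for st in plan.steps:
        lines.append("\t".join(str(x) for x in (
            st.ordinal, st.purpose, st.component,
            st.source.labware_name, st.source.well_id,
            st.dest.labware_name, st.dest.well_id,
            f"{_round(st.volume):.2f}", st.pipette_mount,
            f"{st.aspirate_rate:g}", f"{st.dispense_rate:g}",
        )))
    return "\n".join(lines) + "\n"


def plan_to_json(plan: TransferPlan) -> str:
    payload = {
        "steps": [
            {
                "ordinal": st.ordinal,
                "purpose": st.purpose,
                "component": st.component,
                "source": str(st.source),
                "dest": str(st.dest),
                "volume_ul": _round(st.volume),
                "pipette_mount": st.pipette_mount,
                "aspirate_rate": st.aspirate_rate,
                "dispense_rate": st.dispense_rate,
            }
            for st in plan.steps
        ],
        "predilutions": [
            {
                "component": d.component,
                "mixing_well": str(d.mixing_well),
                "factor": d.factor,
                "intermediate_volume_ul": _round(d.target_volume),
            }
            for d in plan.predilutions
        ],
        "per_sample_volume_ul": {str(s): _round(v) for s, v in plan.summary.per_sample_volume.items()},
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
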