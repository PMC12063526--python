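"""Seeded generator of coherent four-CSV input sets for testing and demos.

Emulates what a design-of-experiments screening array looks like when it
reaches the bench: each reagent (factor) has a small set of concentration
levels spanning a ~10× range, each sample (run) picks one level per factor —
or zero, meaning the factor is left out of that run — and everything is
assembled from single concentrated stocks plus a water diluent. Stock
concentrations carry a 2× safety factor over the largest level scaled by the
number of reagents, which guarantees per-sample volumes stay inside the
pipette envelope and samples never overfill: the generator's feasible regime.

Adversarial variants (``infeasibility`` tag) plant exactly one defect each,
aimed at a specific validation layer:

* ``bad_slot``        — a deck slot of 12 (parser)
* ``missing_tiprack`` — pipette references an absent tip rack (cross-validator)
* ``sample_overrun``  — stock row for a sample past the design (cross-validator)
* ``overfill``        — Transfer Volume override over-specifies a sample (planner)
* ``depletion``       — a stock too small for its total draw (planner)

Same spec + same seed → byte-identical CSVs.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, asdict
from pathlib import Path

from .csv_schemas import well_names

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "write_fixture", "INFEASIBILITY_TAGS"]

INFEASIBILITY_TAGS = ("overfill", "depletion", "bad_slot", "missing_tiprack", "sample_overrun")

SAFETY_FACTOR = 2.0  # stock concentration headroom over the worst-case design
LEVELS_PER_FACTOR = 3  # DoE screening shape: low / mid / high spanning 10×


@dataclass(frozen=True)
class FixtureSpec:
    n_samples: int = 4
    n_reagents: int = 3
    target_volume: float = 100.0
    concentration_levels: tuple[tuple[float, ...], ...] | None = None  # per reagent
    seed: int = 0
    infeasibility: str | None = None
    predilute: bool = False  # add one reagent that needs a 10× pre-dilution
    zero_fraction: float = 0.2  # probability a design cell is 0 (factor left out)


@dataclass(frozen=True)
class Fixture:
    experimental_parameters: str
    labware_inventory: str
    stock_inventory: str
    pipette_settings: str
    manifest: dict

    def as_dict(self) -> dict[str, str]:
        return {
            "experimental_parameters": self.experimental_parameters,
            "labware_inventory": self.labware_inventory,
            "stock_inventory": self.stock_inventory,
            "pipette_settings": self.pipette_settings,
        }


def _fmt(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(round(float(x), 6))


def generate_fixture(spec: FixtureSpec) -> Fixture:
    if spec.n_samples < 1 or spec.n_reagents < 1:
        raise ValueError("need at least one sample and one reagent")
    if spec.n_samples > 192:
        raise ValueError("generator supports at most two 96-well final plates (192 samples)")
    if spec.infeasibility is not None and spec.infeasibility not in INFEASIBILITY_TAGS:
        raise ValueError(f"unknown infeasibility tag {spec.infeasibility!r}")
    if spec.infeasibility == "overfill" and spec.n_reagents < 2:
        raise ValueError("overfill tag needs at least two reagents")
    rng = random.Random(spec.seed)

    reagents = [f"R{i + 1}" for i in range(spec.n_reagents)]
    if spec.concentration_levels is not None:
        levels = [tuple(ls) for ls in spec.concentration_levels]
        if len(levels) != spec.n_reagents:
            raise ValueError("one level set per reagent required")
    else:
        levels = []
        for _ in reagents:
            base = round(rng.uniform(1.0, 10.0), 3)
            levels.append(tuple(round(base * 10 ** (k / (LEVELS_PER_FACTOR - 1)), 4)
                                for k in range(LEVELS_PER_FACTOR)))

    # design matrix: each cell one of the factor's levels, or 0 (skip)
    targets: list[list[float]] = []
    for _ in range(spec.n_samples):
        row = []
        for ls in levels:
            if rng.random() < spec.zero_fraction:
                row.append(0.0)
            else:
                row.append(rng.choice(ls))
        targets.append(row)
    # keep every reagent used somewhere, and sample 0 rich enough for overfill
    for j in range(spec.n_reagents):
        if all(t[j] == 0 for t in targets):
            targets[rng.randrange(spec.n_samples)][j] = levels[j][-1]
    if spec.infeasibility == "overfill":
        targets[0][0] = levels[0][-1]
        targets[0][1] = levels[1][-1]

    units = ["ng/ul", "mM", "%", "uM", ""]
    unit_of = {r: units[i % len(units)] for i, r in enumerate(reagents)}

    # stocks: concentration scaled so the sum of per-sample draws can never
    # overfill, then eased so the smallest non-zero draw clears the 1 µL
    # pipette floor with ~10% headroom (keeps the regime feasible at any
    # reagent count the generator supports)
    stock_conc: dict[str, float] = {}
    for j, (r, ls) in enumerate(zip(reagents, levels)):
        conc = SAFETY_FACTOR * spec.n_reagents * max(ls)
        nonzero = [t[j] for t in targets if t[j] > 0]
        min_draw = min(nonzero) * spec.target_volume / conc
        if min_draw < 1.1:
            conc *= min_draw / 1.1
        stock_conc[r] = round(conc, 6)
    draws = {
        r: [t[j] * spec.target_volume / stock_conc[r] for t in targets]
        for j, r in enumerate(reagents)
    }
    stock_need = {r: sum(draws[r]) for r in reagents}
    worst_fill = sum(max(ls) * spec.target_volume / stock_conc[r]
                     for r, ls in zip(reagents, levels))
    if spec.infeasibility is None and worst_fill > 0.9 * spec.target_volume:
        raise ValueError(
            "infeasible spec: target_volume too small for this many reagents at "
            "pipettable volumes; increase target_volume or reduce n_reagents"
        )

    tube_wells = well_names("opentrons_24_tuberack_nest_1.5ml_snapcap")
    stock_rows: list[list[str]] = []
    for i, r in enumerate(reagents):
        volume = min(1400.0, round(stock_need[r] * 1.5 + 100.0, 3))
        if spec.infeasibility == "depletion" and i == 0:
            volume = round(stock_need[r] * 0.5, 4)  # strictly below the total draw
        override = ""
        if spec.infeasibility == "overfill" and i == 0:
            override = _fmt(spec.target_volume)  # forces the sample past its target
            volume = 1400.0  # keep the defect an over-fill, not a depletion
        stock_rows.append([
            r, "0", f"srctubes:{tube_wells[i]}", _fmt(volume),
            f"{_fmt(stock_conc[r])} {unit_of[r]}".strip(), _fmt(spec.target_volume),
            "", override, "N", "N",
        ])
    n_wells_used = spec.n_reagents

    if spec.predilute:
        # a reagent so concentrated its raw per-sample draw is sub-µL
        name = "Rtrace"
        reagents_all = reagents + [name]
        trace_level = 1.0
        conc = trace_level * spec.target_volume / 0.1  # raw draw exactly 0.1 µL
        stock_rows.append([
            name, "0", f"srctubes:{tube_wells[n_wells_used]}", "500",
            f"{_fmt(conc)} ng/ul", _fmt(spec.target_volume), "", "", "N", "Y",
        ])
        n_wells_used += 1
        for t in targets:
            t.append(trace_level if rng.random() >= spec.zero_fraction else 0.0)
        if all(t[-1] == 0 for t in targets):
            targets[0][-1] = trace_level
    else:
        reagents_all = reagents

    water_volume = min(1400.0, round(spec.n_samples * spec.target_volume + 100.0, 3))
    stock_rows.append([
        "water", "0", f"srctubes:{tube_wells[n_wells_used]}", _fmt(water_volume),
        "0", _fmt(spec.target_volume), "", "", "Y", "N",
    ])
    if spec.infeasibility == "sample_overrun":
        stock_rows.insert(1, [
            "", str(spec.n_samples), f"srctubes:{tube_wells[n_wells_used + 1]}",
            "100", f"{_fmt(stock_conc[reagents[0]])} {unit_of[reagents[0]]}".strip(),
            _fmt(spec.target_volume), "", "", "N", "N",
        ])

    final_slot = "12" if spec.infeasibility == "bad_slot" else "3"
    labware_rows = [
        ["srctubes", "opentrons_24_tuberack_nest_1.5ml_snapcap", "1", "1400", "Y", "N", "N"],
        ["mixplate", "corning_96_wellplate_360ul_flat", "2", "200", "N", "Y", "N"],
        ["finalplate", "corning_96_wellplate_360ul_flat", final_slot, "200", "N", "N", "Y"],
        ["tips20", "opentrons_96_tiprack_20ul", "4", "0", "N", "N", "N"],
        ["tips300", "opentrons_96_tiprack_300ul", "5", "0", "N", "N", "N"],
        ["trash", "agilent_1_reservoir_290ml", "11", "0", "N", "N", "N"],
    ]
    if spec.n_samples > 96:
        labware_rows.insert(3, ["finalplate2", "corning_96_wellplate_360ul_flat", "6", "200", "N", "N", "Y"])

    tip20 = "tips_missing" if spec.infeasibility == "missing_tiprack" else "tips20"
    pipette_rows = [
        ["Pipette", "P20", "P300"],
        ["Mount", "left", "right"],
        ["Aspirate Rate", "7.5", "150"],
        ["Dispense Rate", "7.5", "300"],
        ["Tip Rack", tip20, "tips300"],
        ["Trash Container", "trash", "trash"],
    ]

    def csv_join(rows: list[list[str]]) -> str:
        return "\n".join(",".join(r) for r in rows) + "\n"

    params = csv_join([reagents_all] + [[_fmt(v) for v in t] for t in targets])
    labware = csv_join(
        [["Name", "Labware", "Slot", "Working Volume", "Source", "Mixing", "Final"]] + labware_rows
    )
    stock = csv_join(
        [["Component", "Sample", "Well Location", "Volume", "Concentration",
          "Target Volume", "Speed", "Transfer Volume", "Dilutant", "Diluent"]] + stock_rows
    )
    pipettes = csv_join(pipette_rows)
    manifest = {"spec": asdict(spec), "reagents": reagents_all, "generator": "otplan.fixtures"}
    return Fixture(params, labware, stock, pipettes, manifest)


def write_fixture(fixture: Fixture, directory) -> dict[str, Path]:
    """Write the four CSVs plus a manifest JSON into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    names = {
        "experimental_parameters": "experimental_parameters.csv",
        "labware_inventory": "labware_inventory.csv",
        "stock_inventory": "stock_inventory.csv",
        "pipette_settings": "pipette_settings.csv",
    }
    for key, fname in names.items():
        p = directory / fname
        p.write_text(getattr(fixture, key), encoding="utf-8", newline="\n")
        paths[key] = p
    mp = directory / "manifest.json"
    mp.write_text(json.dumps(fixture.manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["manifest"] = mp
    return paths
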