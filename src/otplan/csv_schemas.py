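"""Read, validate and write the four CSV files that define an experiment.

Every downstream stage (deck model, planner, codegen, simulator) consumes only
the typed records produced here. The four files are:

* **Experimental Parameters** — one row per sample, one column per reagent,
  cells are target final concentrations. The first data row is Sample 0.
* **Labware Inventory** — one row per deck item, seven columns
  (Name, Labware, Slot, Working Volume, Source, Mixing, Final).
* **Stock Inventory** — one row per (reagent, first-sample) assignment, ten
  columns; blank Component cells inherit the previous named entry.
* **Pipette Settings** — transposed layout: one row per setting, one column
  per mounted pipette (at most two).

All parse problems are collected into :class:`SchemaError` with a
``(file, row, column)`` location per finding so a user can fix the cell in a
spreadsheet editor; nothing is silently coerced.
"""

from __future__ import annotations

import io
import csv
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Issue",
    "SchemaError",
    "LabwareRecord",
    "StockRecord",
    "ExperimentalDesign",
    "PipetteConfig",
    "ValidationReport",
    "PIPETTE_MODELS",
    "parse_labware_inventory",
    "parse_stock_inventory",
    "parse_experimental_parameters",
    "parse_pipette_settings",
    "validate_cross_file",
    "write_labware_inventory",
    "write_stock_inventory",
    "write_experimental_parameters",
    "write_pipette_settings",
    "well_grid",
]

LABWARE_COLUMNS = ("Name", "Labware", "Slot", "Working Volume", "Source", "Mixing", "Final")
STOCK_COLUMNS = (
    "Component",
    "Sample",
    "Well Location",
    "Volume",
    "Concentration",
    "Target Volume",
    "Speed",
    "Transfer Volume",
    "Dilutant",
    "Diluent",
)
PIPETTE_ROWS = ("Pipette", "Mount", "Aspirate Rate", "Dispense Rate", "Tip Rack", "Trash Container")

N_DECK_SLOTS = 11  # the OT-2 deck has 11 fixed labware positions

# Volume envelope (min µL, max µL) per single-channel pipette model, keyed by
# the Opentrons API load name. Shorthand aliases (column 2) are accepted in the
# Pipette Settings file and resolved to the canonical load name.
PIPETTE_MODELS: dict[str, tuple[float, float]] = {
    "p10_single": (1.0, 10.0),
    "p20_single_gen2": (1.0, 20.0),
    "p50_single": (5.0, 50.0),
    "p300_single_gen2": (20.0, 300.0),
    "p1000_single_gen2": (100.0, 1000.0),
}
_PIPETTE_ALIASES = {
    "p10": "p10_single",
    "p20": "p20_single_gen2",
    "p50": "p50_single",
    "p300": "p300_single_gen2",
    "p1000": "p1000_single_gen2",
}


@dataclass(frozen=True)
class Issue:
    """One located finding: the file, 1-based row and the column it points at."""

    file: str
    row: int
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.file}:row {self.row}:{self.column}: {self.message}"


class SchemaError(ValueError):
    """Raised by a parser when one or more cells violate the schema."""

    def __init__(self, issues: list[Issue]):
        self.issues = list(issues)
        super().__init__("; ".join(str(i) for i in issues))


@dataclass(frozen=True)
class LabwareRecord:
    name: str
    labware_def: str
    slot: int
    working_volume: float
    is_source: bool
    is_mixing: bool
    is_final: bool


@dataclass(frozen=True)
class StockRecord:
    component: str
    sample_index: int
    well_location: str  # "labware:well", e.g. "tubes:A1"
    volume_available: float
    stock_concentration: float
    concentration_unit: str  # normalised suffix ("%", "ng/ul", "mM", ... or "" for bare)
    target_volume: float
    speed: float | None  # µL/s override for aspirate+dispense; None → pipette default
    transfer_volume_override: float | None
    is_dilutant: bool
    needs_predilution: bool


@dataclass(frozen=True)
class ExperimentalDesign:
    reagent_names: tuple[str, ...]
    targets: tuple[tuple[float, ...], ...]  # [sample][reagent]
    n_samples: int

    def target(self, sample: int, reagent: str) -> float:
        return self.targets[sample][self.reagent_names.index(reagent)]


@dataclass(frozen=True)
class PipetteConfig:
    model: str  # canonical Opentrons API load name
    mount: str  # "left" | "right"
    aspirate_rate: float
    dispense_rate: float
    tip_rack_name: str
    trash_name: str
    min_volume: float
    max_volume: float


@dataclass
class ValidationReport:
    errors: list[Issue] = field(default_factory=list)
    warnings: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# low-level helpers


def _rows(csv_text: str) -> list[list[str]]:
    return [row for row in csv.reader(io.StringIO(csv_text))]


def _norm(cell: str) -> str:
    return cell.strip().lower()


def _parse_yn(cell: str) -> bool | None:
    """Strict Y/N parse; returns None for anything else (caller reports)."""
    c = cell.strip()
    if c in ("Y", "y"):
        return True
    if c in ("N", "n"):
        return False
    return None


def _parse_number(cell: str) -> float | None:
    try:
        return float(cell.strip())
    except ValueError:
        return None


_CONC_RE = re.compile(r"^\s*([0-9.eE+\-]+)\s*(.*?)\s*$")


def _parse_concentration(cell: str) -> tuple[float, str] | None:
    """Split a concentration cell into (value, normalised unit suffix).

    Accepted suffixes: ``%``; mass per µL (``ng/ul`` etc., µ spelled u or µ);
    molar (``M``, ``mM``, ``uM``, ``nM``). A bare number carries the empty
    (dimensionless) unit, which only requires stock and design to agree.
    """
    m = _CONC_RE.match(cell)
    if not m:
        return None
    value = _parse_number(m.group(1))
    if value is None:
        return None
    unit = m.group(2).replace("µ", "u").replace(" ", "")
    low = unit.lower()
    if unit == "":
        return value, ""
    if unit == "%":
        return value, "%"
    if re.fullmatch(r"[numkg]?g/ul", low):
        return value, low
    if re.fullmatch(r"[numk]?m", low):
        return value, low
    return None


def well_grid(labware_def: str) -> tuple[int, int]:
    """Infer (rows, columns) of a labware's well grid from its load name.

    Opentrons load names embed the well count (``corning_96_wellplate_...``).
    Standard SBS shapes are mapped to their grids; reservoirs are a single
    row; unknown counts fall back to one row of n wells.
    """
    counts = {1: (1, 1), 6: (2, 3), 12: (3, 4), 15: (3, 5), 24: (4, 6),
              48: (6, 8), 96: (8, 12), 384: (16, 24)}
    n = None
    for token in labware_def.split("_"):
        if token.isdigit():
            n = int(token)
            break
    if n is None:
        return (8, 12)  # assume SBS 96 if the name carries no count
    if "reservoir" in labware_def.lower():
        return (1, n)
    return counts.get(n, (1, n))


def well_names(labware_def: str) -> list[str]:
    """Row-major well labels (A1, A2, ... B1 ...) for a labware's grid."""
    nrow, ncol = well_grid(labware_def)
    return [f"{chr(ord('A') + r)}{c + 1}" for r in range(nrow) for c in range(ncol)]


def split_well_location(cell: str) -> tuple[str, str] | None:
    """Split ``labware:well`` into its parts; None when malformed."""
    if cell.count(":") != 1:
        return None
    name, well = (p.strip() for p in cell.split(":"))
    if not name or not re.fullmatch(r"[A-Pa-p][0-9]{1,2}", well):
        return None
    return name, well.upper()


def _check_header(
    row: list[str], expected: tuple[str, ...], file: str, issues: list[Issue]
) -> bool:
    got = [c.strip() for c in row]
    if [g.lower() for g in got] == [e.lower() for e in expected]:
        return True
    issues.append(
        Issue(file, 1, "header",
              f"expected columns {', '.join(expected)} in order; got {', '.join(got) or '(empty)'}")
    )
    return False


# ---------------------------------------------------------------------------
# parsers


def parse_labware_inventory(csv_text: str, file: str = "Labware Inventory") -> list[LabwareRecord]:
    """Parse the seven-column labware file into records in file order."""
    rows = _rows(csv_text)
    issues: list[Issue] = []
    if not rows:
        raise SchemaError([Issue(file, 1, "header", "empty file")])
    if not _check_header(rows[0], LABWARE_COLUMNS, file, issues):
        raise SchemaError(issues)

    records: list[LabwareRecord] = []
    seen_names: dict[str, int] = {}
    seen_slots: dict[int, int] = {}
    for i, row in enumerate(rows[1:], start=2):
        if not any(c.strip() for c in row):
            continue
        if len(row) != len(LABWARE_COLUMNS):
            issues.append(Issue(file, i, "row", f"expected {len(LABWARE_COLUMNS)} cells, got {len(row)}"))
            continue
        name = row[0].strip()
        labware_def = row[1].strip()
        slot = _parse_number(row[2])
        wv = _parse_number(row[3])
        flags = [_parse_yn(c) for c in row[4:7]]
        if not name:
            issues.append(Issue(file, i, "Name", "blank labware name"))
        if slot is None or slot != int(slot):
            issues.append(Issue(file, i, "Slot", f"not an integer: {row[2]!r}"))
            slot = None
        elif not 1 <= int(slot) <= N_DECK_SLOTS:
            issues.append(Issue(file, i, "Slot", f"slot {int(slot)} outside 1..{N_DECK_SLOTS}"))
            slot = None
        if wv is None or wv < 0:
            issues.append(Issue(file, i, "Working Volume", f"not a volume ≥ 0: {row[3]!r}"))
            wv = None
        for col, val in zip(LABWARE_COLUMNS[4:], flags):
            if val is None:
                issues.append(Issue(file, i, col, "expected Y or N"))
        if name:
            if name in seen_names:
                issues.append(Issue(file, i, "Name", f"duplicate name {name!r} (first at row {seen_names[name]})"))
            else:
                seen_names[name] = i
        if slot is not None:
            s = int(slot)
            if s in seen_slots:
                issues.append(Issue(file, i, "Slot", f"duplicate slot {s} (first at row {seen_slots[s]})"))
            else:
                seen_slots[s] = i
        if slot is not None and wv is not None and None not in flags and name:
            records.append(
                LabwareRecord(name, labware_def, int(slot), wv, *flags)  # type: ignore[arg-type]
            )
    if issues:
        raise SchemaError(issues)
    return records


def parse_stock_inventory(csv_text: str, file: str = "Stock Inventory") -> list[StockRecord]:
    """Parse the ten-column stock file; blank Component cells fill down."""
    rows = _rows(csv_text)
    issues: list[Issue] = []
    if not rows:
        raise SchemaError([Issue(file, 1, "header", "empty file")])
    if not _check_header(rows[0], STOCK_COLUMNS, file, issues):
        raise SchemaError(issues)

    records: list[StockRecord] = []
    previous_component: str | None = None
    last_sample: dict[str, int] = {}
    unit_of: dict[str, str] = {}
    for i, row in enumerate(rows[1:], start=2):
        if not any(c.strip() for c in row):
            continue
        if len(row) != len(STOCK_COLUMNS):
            issues.append(Issue(file, i, "row", f"expected {len(STOCK_COLUMNS)} cells, got {len(row)}"))
            continue
        component = row[0].strip()
        if not component:
            if previous_component is None:
                issues.append(Issue(file, i, "Component", "first data row has a blank Component; nothing to inherit"))
                continue
            component = previous_component  # fill-down
        previous_component = component

        ok = True
        sample = _parse_number(row[1])
        if sample is None or sample != int(sample) or sample < 0:
            issues.append(Issue(file, i, "Sample", f"not an integer ≥ 0: {row[1]!r}"))
            ok = False
        else:
            s = int(sample)
            if component in last_sample and s <= last_sample[component]:
                issues.append(
                    Issue(file, i, "Sample",
                          f"sample index {s} not strictly increasing within component {component!r}")
                )
                ok = False
            else:
                last_sample[component] = s

        if split_well_location(row[2]) is None:
            issues.append(Issue(file, i, "Well Location", f"expected labware:well (e.g. tubes:A1), got {row[2]!r}"))
            ok = False
        volume = _parse_number(row[3])
        if volume is None or volume <= 0:
            issues.append(Issue(file, i, "Volume", f"not a volume > 0: {row[3]!r}"))
            ok = False

        conc_unit = _parse_concentration(row[4])
        if conc_unit is None:
            issues.append(Issue(file, i, "Concentration", f"unparseable concentration: {row[4]!r}"))
            ok = False
            conc, unit = 0.0, ""
        else:
            conc, unit = conc_unit
            if conc < 0:
                issues.append(Issue(file, i, "Concentration", "negative concentration"))
                ok = False
            if component in unit_of and unit_of[component] != unit:
                issues.append(
                    Issue(file, i, "Concentration",
                          f"unit {unit or 'dimensionless'!r} conflicts with earlier "
                          f"{unit_of[component] or 'dimensionless'!r} for component {component!r}")
                )
                ok = False
            else:
                unit_of.setdefault(component, unit)

        tvol = _parse_number(row[5])
        if tvol is None or tvol <= 0:
            issues.append(Issue(file, i, "Target Volume", f"not a volume > 0: {row[5]!r}"))
            ok = False

        speed: float | None = None
        if row[6].strip():
            speed = _parse_number(row[6])
            if speed is None or speed <= 0:
                issues.append(Issue(file, i, "Speed", f"not a rate > 0: {row[6]!r}"))
                ok = False
        override: float | None = None
        if row[7].strip():
            override = _parse_number(row[7])
            if override is None or override <= 0:
                issues.append(Issue(file, i, "Transfer Volume", f"not a volume > 0: {row[7]!r}"))
                ok = False

        dilutant = _parse_yn(row[8])
        if dilutant is None:
            issues.append(Issue(file, i, "Dilutant", "expected Y or N"))
            ok = False
        prediluted = _parse_yn(row[9])
        if prediluted is None:
            issues.append(Issue(file, i, "Diluent", "expected Y or N"))
            ok = False

        if ok and conc == 0 and not dilutant:
            issues.append(Issue(file, i, "Concentration", f"zero concentration for non-dilutant component {component!r}"))
            ok = False

        if ok:
            records.append(
                StockRecord(
                    component=component,
                    sample_index=int(sample),  # type: ignore[arg-type]
                    well_location=f"{split_well_location(row[2])[0]}:{split_well_location(row[2])[1]}",  # type: ignore[index]
                    volume_available=volume,  # type: ignore[arg-type]
                    stock_concentration=conc,
                    concentration_unit=unit,
                    target_volume=tvol,  # type: ignore[arg-type]
                    speed=speed,
                    transfer_volume_override=override,
                    is_dilutant=bool(dilutant),
                    needs_predilution=bool(prediluted),
                )
            )
    if issues:
        raise SchemaError(issues)
    return records


def parse_experimental_parameters(csv_text: str, file: str = "Experimental Parameters") -> ExperimentalDesign:
    """Parse the design matrix; the first data row is Sample 0."""
    rows = _rows(csv_text)
    issues: list[Issue] = []
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise SchemaError([Issue(file, 1, "header", "empty file")])
    reagents = tuple(c.strip() for c in rows[0])
    if any(not r for r in reagents):
        issues.append(Issue(file, 1, "header", "blank reagent name in header"))
    if len(set(reagents)) != len(reagents):
        issues.append(Issue(file, 1, "header", "duplicate reagent name in header"))
    if len(rows) < 2:
        issues.append(Issue(file, 1, "row", "no sample rows"))
    targets: list[tuple[float, ...]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(reagents):
            issues.append(Issue(file, i, "row", f"ragged row: {len(row)} cells, header has {len(reagents)}"))
            continue
        vals: list[float] = []
        for col, cell in zip(reagents, row):
            v = _parse_number(cell)
            if v is None:
                issues.append(Issue(file, i, col, f"not a number: {cell!r}"))
            elif v < 0:
                issues.append(Issue(file, i, col, "negative target concentration"))
            else:
                vals.append(v)
        if len(vals) == len(reagents):
            targets.append(tuple(vals))
    if issues:
        raise SchemaError(issues)
    return ExperimentalDesign(reagent_names=reagents, targets=tuple(targets), n_samples=len(targets))


def parse_pipette_settings(csv_text: str, file: str = "Pipette Settings") -> list[PipetteConfig]:
    """Parse the transposed pipette file (one column per pipette, ≤2)."""
    rows = _rows(csv_text)
    issues: list[Issue] = []
    rows = [r for r in rows if any(c.strip() for c in r)]
    if len(rows) != len(PIPETTE_ROWS) or any(
        _norm(r[0]) != e.lower() for r, e in zip(rows, PIPETTE_ROWS)
    ):
        raise SchemaError(
            [Issue(file, 1, "rows", f"expected rows {', '.join(PIPETTE_ROWS)} in order")]
        )
    width = max(len(r) for r in rows) - 1
    cols: list[list[str]] = []
    for j in range(width):
        col = [(r[j + 1].strip() if len(r) > j + 1 else "") for r in rows]
        if any(col):
            cols.append(col)
    if len(cols) > 2:
        raise SchemaError(
            [Issue(file, 1, "columns", f"{len(cols)} pipette columns; the OT-2 mounts at most 2 pipettes")]
        )
    if not cols:
        raise SchemaError([Issue(file, 1, "columns", "no pipette columns")])

    configs: list[PipetteConfig] = []
    mounts_seen: set[str] = set()
    for j, col in enumerate(cols, start=1):
        model_raw = col[0].strip().lower()
        model = _PIPETTE_ALIASES.get(model_raw, model_raw)
        if model not in PIPETTE_MODELS:
            issues.append(Issue(file, 1, f"Pipette {j}", f"unknown pipette model {col[0]!r}"))
            continue
        mount = col[1].strip().lower()
        if mount not in ("left", "right"):
            issues.append(Issue(file, 2, f"Mount {j}", f"mount must be left or right, got {col[1]!r}"))
            continue
        if mount in mounts_seen:
            issues.append(Issue(file, 2, f"Mount {j}", f"duplicate mount {mount!r}"))
            continue
        mounts_seen.add(mount)
        asp = _parse_number(col[2])
        disp = _parse_number(col[3])
        if asp is None or asp <= 0:
            issues.append(Issue(file, 3, f"Aspirate Rate {j}", f"not a rate > 0: {col[2]!r}"))
            continue
        if disp is None or disp <= 0:
            issues.append(Issue(file, 4, f"Dispense Rate {j}", f"not a rate > 0: {col[3]!r}"))
            continue
        if not col[4]:
            issues.append(Issue(file, 5, f"Tip Rack {j}", "blank tip rack name"))
            continue
        if not col[5]:
            issues.append(Issue(file, 6, f"Trash Container {j}", "blank trash name"))
            continue
        lo, hi = PIPETTE_MODELS[model]
        configs.append(
            PipetteConfig(model, mount, asp, disp, col[4], col[5], lo, hi)
        )
    if issues:
        raise SchemaError(issues)
    return sorted(configs, key=lambda c: c.mount != "left")  # left mount first


# ---------------------------------------------------------------------------
# cross-file validation


def validate_cross_file(
    labware: list[LabwareRecord],
    stocks: list[StockRecord],
    design: ExperimentalDesign,
    pipettes: list[PipetteConfig],
) -> ValidationReport:
    """Check every reference between the four files; findings, not exceptions."""
    report = ValidationReport()
    by_name = {lw.name: lw for lw in labware}

    for j, p in enumerate(pipettes, start=1):
        if p.tip_rack_name not in by_name:
            report.errors.append(
                Issue("Pipette Settings", 5, f"Tip Rack {j}",
                      f"tip rack {p.tip_rack_name!r} not found in Labware Inventory")
            )
        if p.trash_name not in by_name:
            report.errors.append(
                Issue("Pipette Settings", 6, f"Trash Container {j}",
                      f"trash {p.trash_name!r} not found in Labware Inventory")
            )

    components = {s.component for s in stocks}
    for reagent in design.reagent_names:
        if reagent not in components:
            report.errors.append(
                Issue("Experimental Parameters", 1, reagent,
                      f"design reagent {reagent!r} has no Stock Inventory rows")
            )

    for i, s in enumerate(stocks, start=2):
        loc = split_well_location(s.well_location)
        if loc is None:
            continue  # parser already rejected
        lw_name, well = loc
        lw = by_name.get(lw_name)
        if lw is None:
            report.errors.append(
                Issue("Stock Inventory", i, "Well Location",
                      f"labware {lw_name!r} not found in Labware Inventory")
            )
        else:
            if not lw.is_source:
                report.errors.append(
                    Issue("Stock Inventory", i, "Well Location",
                          f"labware {lw_name!r} is not flagged as Source")
                )
            if well not in well_names(lw.labware_def):
                report.errors.append(
                    Issue("Stock Inventory", i, "Well Location",
                          f"well {well} outside the {lw.labware_def} grid")
                )
        if s.sample_index >= design.n_samples:
            report.errors.append(
                Issue("Stock Inventory", i, "Sample",
                      f"sample index {s.sample_index} but Experimental Parameters has "
                      f"only {design.n_samples} samples (0..{design.n_samples - 1})")
            )

    has_dilutant = any(s.is_dilutant for s in stocks)
    for i, s in enumerate(stocks, start=2):
        if s.needs_predilution and not has_dilutant:
            report.errors.append(
                Issue("Stock Inventory", i, "Diluent",
                      f"component {s.component!r} needs pre-dilution but no Dilutant reagent is defined")
            )

    if not any(lw.is_final for lw in labware):
        report.errors.append(
            Issue("Labware Inventory", 1, "Final", "no labware flagged as Final destination")
        )
    return report


# ---------------------------------------------------------------------------
# writers (byte-stable: LF endings, no trailing delimiter)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


def _emit(rows: list[list[str]]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerows(rows)
    return buf.getvalue()


def write_labware_inventory(records: list[LabwareRecord]) -> str:
    rows = [list(LABWARE_COLUMNS)]
    for r in records:
        rows.append([
            r.name, r.labware_def, str(r.slot), _fmt(r.working_volume),
            "Y" if r.is_source else "N", "Y" if r.is_mixing else "N", "Y" if r.is_final else "N",
        ])
    return _emit(rows)


def write_stock_inventory(records: list[StockRecord]) -> str:
    rows = [list(STOCK_COLUMNS)]
    for r in records:
        conc = _fmt(r.stock_concentration)
        if r.concentration_unit:
            conc = f"{conc} {r.concentration_unit}"
        rows.append([
            r.component, str(r.sample_index), r.well_location, _fmt(r.volume_available),
            conc, _fmt(r.target_volume),
            "" if r.speed is None else _fmt(r.speed),
            "" if r.transfer_volume_override is None else _fmt(r.transfer_volume_override),
            "Y" if r.is_dilutant else "N", "Y" if r.needs_predilution else "N",
        ])
    return _emit(rows)


def write_experimental_parameters(design: ExperimentalDesign) -> str:
    rows = [list(design.reagent_names)]
    for sample in design.targets:
        rows.append([_fmt(v) for v in sample])
    return _emit(rows)


def write_pipette_settings(configs: list[PipetteConfig]) -> str:
    rows = [[label] for label in PIPETTE_ROWS]
    for c in configs:
        rows[0].append(c.model)
        rows[1].append(c.mount)
        rows[2].append(_fmt(c.aspirate_rate))
        rows[3].append(_fmt(c.dispense_rate))
        rows[4].append(c.tip_rack_name)
        rows[5].append(c.trash_name)
    return _emit(rows)
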