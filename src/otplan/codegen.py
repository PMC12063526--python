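"""Emit a standalone Opentrons Protocol API v2 script from a transfer plan.

The emitted script is fully static: every labware load, instrument load and
aspirate/dispense pair is a literal, so the file is self-contained, byte-
deterministic for identical inputs, and archivable alongside the experiment's
data as a record of exactly what the robot was asked to do. A header comment
embeds SHA-256 digests of the four input CSVs so a script can always be
matched back to the inputs that produced it.

``extract_transfers`` and ``count_load_statements`` parse the emitted source
back with :mod:`ast`; they exist so tests can prove the script is a faithful
rendering of the plan rather than trusting the emitter.
"""

from __future__ import annotations

import ast
import hashlib
from dataclasses import dataclass

from . import __version__
from .csv_schemas import LabwareRecord, PipetteConfig
from .planner import EXPORT_DECIMALS, TransferPlan

__all__ = [
    "ProtocolScript",
    "CodegenError",
    "emit_protocol",
    "write_protocol",
    "extract_transfers",
    "count_load_statements",
    "digest_inputs",
]

API_LEVEL = "2.13"


class CodegenError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolScript:
    text: str
    metadata: dict


def digest_inputs(csv_texts: dict[str, str]) -> dict[str, str]:
    """SHA-256 hex digest per input file name, sorted for stable emission."""
    return {name: hashlib.sha256(text.encode()).hexdigest()
            for name, text in sorted(csv_texts.items())}


def _fmt_rate(r: float) -> str:
    return str(int(r)) if float(r) == int(r) else repr(float(r))


def emit_protocol(
    plan: TransferPlan,
    labware: list[LabwareRecord],
    pipettes: list[PipetteConfig],
    protocol_name: str = "otplan_protocol",
    input_digests: dict[str, str] | None = None,
) -> ProtocolScript:
    """Render the plan as an Opentrons Python Protocol API v2 script.

    One ``load_labware`` call per labware row (in file order, with its slot),
    one ``load_instrument`` per pipette (with mount and tip rack), then the
    transfer steps in ordinal order, each an aspirate/dispense pair carrying
    its volume (0.01 µL resolution) and flow rates. Tip handling follows the
    plan's per-step ``new_tip`` flags.
    """
    if not plan.steps:
        raise CodegenError("refusing to emit a protocol for an empty plan")
    lw_names = {lw.name for lw in labware}
    mounts = {p.mount for p in pipettes}
    for st in plan.steps:
        if st.source.labware_name not in lw_names or st.dest.labware_name not in lw_names:
            raise CodegenError(
                f"step {st.ordinal} references labware outside the Labware Inventory"
            )
        if st.pipette_mount not in mounts:
            raise CodegenError(f"step {st.ordinal} uses unconfigured mount {st.pipette_mount!r}")

    digests = dict(input_digests or {})
    lines: list[str] = []
    lines.append(f"# Generated by otplan {__version__} — do not edit; regenerate from the CSVs.")
    lines.append("# Input digests (sha256):")
    for name, dig in sorted(digests.items()):
        lines.append(f"#   {name}: {dig}")
    lines.append(f"# Steps: {len(plan.steps)}; samples: {len(plan.sample_wells)}")
    lines.append("")
    lines.append("from opentrons import protocol_api")
    lines.append("")
    lines.append("metadata = {")
    lines.append(f'    "protocolName": {protocol_name!r},')
    lines.append(f'    "apiLevel": {API_LEVEL!r},')
    lines.append(f'    "source": "otplan {__version__}",')
    lines.append("}")
    lines.append("")
    lines.append("")
    lines.append("def run(protocol: protocol_api.ProtocolContext):")
    lines.append("    deck = {}")
    for lw in labware:
        lines.append(
            f'    deck[{lw.name!r}] = protocol.load_labware({lw.labware_def!r}, {lw.slot})'
        )
    lines.append("    pips = {}")
    for p in pipettes:
        lines.append(
            f'    pips[{p.mount!r}] = protocol.load_instrument('
            f'{p.model!r}, {p.mount!r}, tip_racks=[deck[{p.tip_rack_name!r}]])'
        )
    trash_of = {p.mount: p.trash_name for p in pipettes}
    holding: dict[str, bool] = {p.mount: False for p in pipettes}
    lines.append("")
    for st in plan.steps:
        m = st.pipette_mount
        vol = f"{round(st.volume, EXPORT_DECIMALS):.2f}"
        tag = f"# step {st.ordinal}: {st.purpose} {st.component}"
        if st.sample is not None:
            tag += f" -> sample {st.sample}"
        lines.append(f"    {tag}")
        if st.new_tip and holding[m]:
            lines.append(f'    pips[{m!r}].drop_tip(deck[{trash_of[m]!r}]["A1"])')
            holding[m] = False
        if not holding[m]:
            lines.append(f"    pips[{m!r}].pick_up_tip()")
            holding[m] = True
        lines.append(f"    pips[{m!r}].flow_rate.aspirate = {_fmt_rate(st.aspirate_rate)}")
        lines.append(f"    pips[{m!r}].flow_rate.dispense = {_fmt_rate(st.dispense_rate)}")
        lines.append(
            f'    pips[{m!r}].aspirate({vol}, '
            f'deck[{st.source.labware_name!r}][{st.source.well_id!r}])'
        )
        lines.append(
            f'    pips[{m!r}].dispense({vol}, '
            f'deck[{st.dest.labware_name!r}][{st.dest.well_id!r}])'
        )
    for m in sorted(holding):
        if holding[m]:
            lines.append(f'    pips[{m!r}].drop_tip(deck[{trash_of[m]!r}]["A1"])')
    text = "\n".join(lines) + "\n"
    meta = {
        "protocolName": protocol_name,
        "apiLevel": API_LEVEL,
        "generator_version": __version__,
        "input_digests": digests,
        "n_steps": len(plan.steps),
    }
    # the emitter's own sanity gate: never hand out a script that will not parse
    ast.parse(text)
    return ProtocolScript(text=text, metadata=meta)


def write_protocol(script: ProtocolScript, path) -> None:
    """Write the script to ``path``, unconditionally overwriting."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(script.text)


# ---------------------------------------------------------------------------
# re-extraction (test surface)


def _well_ref(node: ast.expr) -> str | None:
    # deck['plate']['A1'] → "plate:A1"
    if (
        isinstance(node, ast.Subscript)
        and isinstance(node.slice, ast.Constant)
        and isinstance(node.value, ast.Subscript)
        and isinstance(node.value.slice, ast.Constant)
        and isinstance(node.value.value, ast.Name)
        and node.value.value.id == "deck"
    ):
        return f"{node.value.slice.value}:{node.slice.value}"
    return None


def extract_transfers(script_text: str) -> list[tuple[float, str, str]]:
    """Recover (volume, source, dest) triples from an emitted script's AST."""
    tree = ast.parse(script_text)
    events: list[tuple[str, float, str]] = []
    for node in ast.walk(tree):
        if (
            isinstance(node, ast.Call)
            and isinstance(node.func, ast.Attribute)
            and node.func.attr in ("aspirate", "dispense")
            and len(node.args) == 2
            and isinstance(node.args[0], ast.Constant)
        ):
            ref = _well_ref(node.args[1])
            if ref is not None:
                events.append((node.func.attr, float(node.args[0].value), ref))
    transfers: list[tuple[float, str, str]] = []
    pending: tuple[float, str] | None = None
    for kind, vol, ref in events:
        if kind == "aspirate":
            pending = (vol, ref)
        elif pending is not None:
            transfers.append((pending[0], pending[1], ref))
            pending = None
    return transfers


def count_load_statements(script_text: str) -> tuple[int, int]:
    """(labware loads, instrument loads) in the emitted script."""
    tree = ast.parse(script_text)
    n_lw = n_pip = 0
    for node in ast.walk(tree):
        if isinstance(node, ast.Call) and isinstance(node.func, ast.Attribute):
            if node.func.attr == "load_labware":
                n_lw += 1
            elif node.func.attr == "load_instrument":
                n_pip += 1
    return n_lw, n_pip
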