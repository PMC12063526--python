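"""Abstract execution of a transfer plan against the deck — the internal oracle.

Each step moves a volume and the proportional share of every component amount
from its source well to its destination well. Transfers move liquid, they
never create or destroy it, so per-component totals over the deck are
conserved exactly (up to float rounding). After execution the per-sample
achieved concentrations (amount / volume) are compared against the design
targets; the pipeline is exact rational arithmetic up to float rounding, so
the default tolerance is 1e-9 relative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .csv_schemas import ExperimentalDesign, Issue, PipetteConfig, ValidationReport
from .experiment_model import DeckState, ModelError
from .planner import TransferPlan

__all__ = ["SimulationResult", "simulate_plan", "verify_against_design", "result_to_json"]

_EPS = 1e-9


@dataclass
class SimulationResult:
    final_deck: DeckState
    per_sample: dict[int, tuple[float, dict[str, float]]]  # sample → (volume, conc by component)
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def simulate_plan(
    plan: TransferPlan,
    deck: DeckState,
    pipettes: list[PipetteConfig] | None = None,
) -> SimulationResult:
    """Execute every step on a copy of the deck and collect violations.

    Violations recorded: a source drawn below zero, a destination filled past
    its working volume, and (when the pipette table is supplied) a step volume
    outside its assigned pipette's envelope. Unknown wells are structural
    errors and raise instead.
    """
    state = deck.copy()
    violations: list[str] = []
    by_mount = {p.mount: p for p in (pipettes or [])}

    for step in plan.steps:
        src = state.well(step.source)  # raises ModelError on unknown wells
        dst = state.well(step.dest)
        if pipettes is not None:
            p = by_mount.get(step.pipette_mount)
            if p is None:
                raise ModelError(f"step {step.ordinal}: no pipette on mount {step.pipette_mount!r}")
            if not (p.min_volume - _EPS <= step.volume <= p.max_volume + _EPS):
                violations.append(
                    f"step {step.ordinal}: volume {step.volume:g} µL outside "
                    f"{p.model} envelope {p.min_volume:g}–{p.max_volume:g} µL"
                )
        if step.volume > src.volume + _EPS:
            violations.append(
                f"step {step.ordinal}: aspirating {step.volume:g} µL from {step.source} "
                f"holding only {src.volume:g} µL"
            )
            moved_fraction = 1.0
        else:
            moved_fraction = step.volume / src.volume if src.volume > 0 else 0.0
        for comp, amount in list(src.composition.items()):
            moved = amount * moved_fraction
            src.composition[comp] = amount - moved
            if src.composition[comp] <= 0:
                del src.composition[comp]
            dst.composition[comp] = dst.composition.get(comp, 0.0) + moved
        src.volume = max(src.volume - step.volume, 0.0)
        dst.volume += step.volume
        cap = state.working_volume(step.dest)
        if dst.volume > cap + _EPS:
            violations.append(
                f"step {step.ordinal}: {step.dest} at {dst.volume:g} µL exceeds "
                f"working volume {cap:g} µL"
            )

    per_sample: dict[int, tuple[float, dict[str, float]]] = {}
    for sample, addr in plan.sample_wells.items():
        well = state.well(addr)
        concs = (
            {c: a / well.volume for c, a in well.composition.items()}
            if well.volume > 0
            else {}
        )
        per_sample[sample] = (well.volume, concs)
    return SimulationResult(final_deck=state, per_sample=per_sample, violations=violations)


def verify_against_design(
    result: SimulationResult,
    design: ExperimentalDesign,
    target_volume: float | dict[int, float],
    rel_tol: float = 1e-9,
) -> ValidationReport:
    """Compare the simulated end state with the design, finding by finding.

    For every sample the final volume must hit its target and every reagent's
    achieved concentration must hit the design entry, both within ``rel_tol``
    relative; a zero design entry must leave the reagent exactly absent from
    that sample.
    """
    report = ValidationReport()
    for v in result.violations:
        report.errors.append(Issue("simulation", 0, "step", v))
    for sample in range(design.n_samples):
        if sample not in result.per_sample:
            report.errors.append(Issue("simulation", sample, "sample", "no destination well simulated"))
            continue
        volume, concs = result.per_sample[sample]
        tv = target_volume[sample] if isinstance(target_volume, dict) else target_volume
        if abs(volume - tv) > rel_tol * max(tv, 1.0):
            report.errors.append(
                Issue("simulation", sample, "volume",
                      f"final volume {volume!r} µL, target {tv!r} µL")
            )
        for j, reagent in enumerate(design.reagent_names):
            designed = design.targets[sample][j]
            achieved = concs.get(reagent, 0.0)
            if designed == 0:
                if achieved > 0:
                    report.errors.append(
                        Issue("simulation", sample, reagent,
                              f"designed 0 (skip) but {achieved!r} delivered")
                    )
            elif abs(achieved - designed) > rel_tol * max(designed, _EPS):
                report.errors.append(
                    Issue("simulation", sample, reagent,
                          f"achieved {achieved!r}, designed {designed!r}")
                )
    return report


def result_to_json(result: SimulationResult, report: ValidationReport | None = None) -> str:
    payload = {
        "ok": result.ok and (report.ok if report is not None else True),
        "violations": list(result.violations),
        "per_sample": {
            str(s): {"volume_ul": vol, "concentrations": concs}
            for s, (vol, concs) in sorted(result.per_sample.items())
        },
    }
    if report is not None:
        payload["findings"] = [str(i) for i in report.errors]
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def result_to_text(result: SimulationResult, report: ValidationReport | None = None) -> str:
    lines = []
    for s, (vol, concs) in sorted(result.per_sample.items()):
        parts = ", ".join(f"{c}={v:g}" for c, v in sorted(concs.items()))
        lines.append(f"sample {s}: {vol:g} µL ({parts})")
    for v in result.violations:
        lines.append(f"VIOLATION: {v}")
    if report is not None:
        for i in report.errors:
            lines.append(f"FINDING: {i}")
        lines.append("ok" if report.ok and result.ok else "NOT OK")
    return "\n".join(lines) + "\n"
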