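# Methods

## Pipeline model

`otplan` is a compiler with a verification pass. The stages are:

1. **Parse** the four CSVs into typed records. Every violation is reported
   with a `(file, row, column)` triple; all four files are parsed before any
   error is raised, so one run surfaces every problem at once.
2. **Cross-validate** references between files: tip racks and trash must name
   labware rows, stock wells must sit on Source-flagged labware inside the
   labware's well grid, every design reagent needs stock rows, stock rows may
   not address samples past the design, pre-dilution needs a dilutant, and at
   least one labware must be Final.
3. **Model** the deck: labware on slots 1–11, every stock well charged with
   `volume_available` and the "mass-like" amount
   `stock_concentration × volume_available`. Amounts are tracked in
   concentration × volume units, so amount/volume recovers a concentration in
   whatever unit family the stock used — the whole pipeline is unit-agnostic
   as long as a reagent's stock and design entries share one unit.
4. **Plan** transfers (below), 5. **simulate** the plan by exact mass
   balance, 6. **verify** the simulated end state against the design, and
   only then 7. **emit** the protocol script. A failed stage aborts with all
   findings and writes nothing.

## Stock row semantics

A stock row lists the *first* sample it serves; the row with the largest
`Sample` value ≤ s serves sample s (a step function over samples). A single
row at sample 0 therefore serves the whole design, which is the common case:
one concentrated stock, many target concentrations. Rows are per-sample
assignments, so a depleted row is an error rather than a silent switch to a
different row (which could hold a different concentration).

Two rows of the same component may share a physical well (per-sample
aliquots of one stock; their volumes pool at deck initialisation); two
different components in one well is a collision and an error.

## Planning rules

* **Transfer volume** `V = Ct·Vt/Cs`; a `Transfer Volume` override replaces
  the computed value verbatim; `Ct > Cs` is an impossible dilution and an
  error; `Ct = 0` emits no step.
* **Diluent top-up** per sample: `Vt − Σ V_reagent`, emitted after all
  reagents by default because it is only known once all reagent volumes are.
  `--diluent-first` reorders the same steps to put top-ups first. A negative
  remainder (over-specified sample) is an error.
* **Pipette selection** minimises the number of aspirate/dispense cycles
  (`n = ⌈V / V_max⌉` with all `V/n` inside the envelope); ties prefer the
  smaller `V_max` (smaller relative volumetric error), then the left mount.
  Over-range volumes split into *equal* parts — max-then-remainder could
  leave a remainder below `V_min`. Built-in envelopes (µL): P10 1–10,
  P20 1–20, P50 5–50, P300 20–300, P1000 100–1000.
* **Pre-dilution** (stock `Diluent` flag): the smallest power-of-ten factor
  `f` with `min(V_sample)·f ≥ V_min,pipette` is chosen; the intermediate of
  volume `max(Σ V_sample·f, V_min·f)` — the floor keeps the stock aliquot
  `V_int/f` itself pipettable — is assembled in the next free mixing well,
  and per-sample draws come from it at `f×` volume and `Cs/f` concentration,
  delivering identical amounts. An intermediate that cannot fit the mixing
  labware's working volume is an error (larger factors only grow it).
  A sub-minimum volume on a stock *without* the flag is an error that
  suggests setting the flag, rather than a silent automatic dilution.
* **Rates**: a stock row's `Speed` sets both aspirate and dispense rate for
  its steps; otherwise the assigned pipette's defaults apply.
* **Tips**: a fresh tip at every component change, plus a fresh tip for any
  step dispensing into an already non-empty well (prevents carrying sample
  material back into stocks). Within one reagent's distribution into fresh
  wells a tip is reused.
* **Ordering**: reagent-major in Stock Inventory file order; pre-dilution
  steps immediately precede their component's distribution block.

All arithmetic runs on unrounded 64-bit floats; volumes are rounded to
0.01 µL only in the TSV/JSON exports and the emitted script. Verification
runs pre-rounding with a default relative tolerance of 1e-9 — the pipeline
is exact rational arithmetic up to float rounding, and observed errors are
at the 1e-16 level; 1e-9 leaves five orders of headroom without masking
logic faults.

## Dilutant handling

The reagent flagged `Dilutant` supplies top-ups and pre-dilutions. A pure
solvent (concentration 0) contributes volume but no amount. A dilutant with
its own design column is dispensed as a normal reagent first and reused for
top-ups; if it also has a non-zero concentration its top-up contribution adds
real amount, and verification will flag samples whose achieved concentration
then overshoots the design — intentionally, since that is a real formulation
inconsistency.

## Code generation

The emitted script targets Protocol API v2 (apiLevel pinned to 2.13 in the
metadata) and contains only static literals: one `load_labware` per labware
row, one `load_instrument` per pipette, and one aspirate/dispense pair per
plan step, with tip handling per the plan's flags. No timestamps or
environment state enter the text, so identical inputs give byte-identical
scripts; the header embeds SHA-256 digests of the four input CSVs for
archival traceability. `codegen.extract_transfers` re-parses emitted scripts
with `ast` so tests prove faithfulness instead of trusting the emitter.

Well grids are inferred from the Opentrons load name's embedded well count
(96 → 8×12, 24 → 4×6, …; reservoirs are one row). The model knows nothing of
labware geometry beyond the grid and the working volume.

## Synthetic data generator

`otplan.fixtures` emulates the shape of a DoE screening array reaching the
bench: each reagent gets 3 concentration levels spanning a 10× range (typical
screening design), each design cell draws one level or 0 (probability 0.2,
factor left out of that run), samples are assembled to 100 µL from single
stocks plus a water dilutant, with a P20/P300 pair. Stock concentrations are
set to 2 × n_reagents × max(level), then eased so the smallest non-zero draw
clears the 1 µL pipette floor with ~10 % headroom — together this guarantees
per-sample volumes are pipettable and samples cannot overfill (the feasible
regime). The optional `predilute` flag adds a trace reagent whose raw draw is
0.1 µL, exercising the 10× pre-dilution path. Five `infeasibility` tags each
plant exactly one defect aimed at a specific layer (parser, cross-validator
or planner).

The generator emulates the logical structure of real inputs, not their
physics: no pipetting CV, dead volumes, evaporation or viscosity effects.
Passing tests therefore demonstrate that plans are *logically* correct
(exact mass balance, capacity and envelope compliance), not that a physical
robot achieves the concentrations — that depends on hardware calibration
outside this package's scope.

## Problem sizes

The test suite and the acceptance script sweep 200 seeded fixtures of up to
8 samples × 5 reagents (plus a pre-diluted trace reagent in every 7th), a
size chosen to cover every code path — multi-level designs, zero cells,
volume splitting, pre-dilution, both pipettes — while the whole suite runs
in a few seconds.

## Known limitations

* No multi-dispense (one aspirate feeding several wells), air gaps, blow-out
  or travel-time optimisation.
* Unit tags are matched, never converted: a stock in mM with design entries
  meant as µM is a user error the tool cannot see (it would flag it only if
  two stock rows of one component disagree).
* Destination wells fill row-major across Final labware in file order; there
  is no plate-layout customisation.
* The original workflow's robot upload step and LAP-format export are out of
  scope.
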