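# otplan

Compile design-of-experiments (DoE) CSV arrays into verified liquid-handling
protocols for the Opentrons OT-2.

## The problem

Multifactorial experiments — media optimisation, buffer screens, cell-free
expression arrays — are specified as a DoE table: one row per experimental
run, one column per factor, each cell a target final concentration. Turning
such a table into robot code by hand means computing, for every (sample,
reagent) pair, the stock volume to transfer and the diluent top-up, then
writing hundreds of aspirate/dispense calls. That transcription step is slow,
error-prone, and has to be redone at every DoE iteration.

`otplan` takes four user-edited CSV files:

| file | contents |
|---|---|
| **Experimental Parameters** | samples × reagents matrix of target final concentrations; the first data row is Sample 0; a `0` cell skips that reagent |
| **Labware Inventory** | seven columns (Name, Labware, Slot, Working Volume, Source, Mixing, Final), one row per deck item, slots 1–11 |
| **Stock Inventory** | ten columns per stock row: component (blank = same as previous row), first sample served, well location, available volume, concentration (`%`, mass/µL or molar), target sample volume, optional speed and transfer-volume overrides, Dilutant / Diluent flags |
| **Pipette Settings** | one column per mounted pipette (≤ 2): model, mount, rates, tip rack, trash |

and produces a deterministic transfer plan plus a standalone Opentrons
Protocol API v2 script. Between DoE iterations only the Experimental
Parameters file changes.

## The core calculation

Each transfer volume comes from the dilution balance C₁V₁ = C₂V₂: for stock
concentration C_s, design target C_t and sample target volume V_t,

```
V_transfer = C_t · V_t / C_s,        V_diluent = V_t − Σ V_transfer
```

Reagents are dispensed reagent-major in Stock Inventory order (all samples of
reagent A before reagent B), the pipette for each step is chosen as the
smallest-range pipette that holds the volume (over-range volumes are split
into equal parts), and stocks flagged for pre-dilution are first diluted by
the smallest power-of-ten factor that lifts every per-sample volume above the
smallest pipettable volume.

Before anything is written, a mass-balance simulator executes the plan on a
virtual deck and verifies every sample reaches its designed volume and
concentrations to 1 part in 10⁹ — a compile-time proof that the protocol
does what the design table says.

## Worked example

Generate a synthetic 4-sample × 3-reagent screening array and compile it:

```
otplan fixtures --out-dir demo --seed 7
otplan compile --params demo/experimental_parameters.csv \
               --labware demo/labware_inventory.csv \
               --stock demo/stock_inventory.csv \
               --pipettes demo/pipette_settings.csv \
               --out demo/protocol.py --plan-out demo/plan.tsv
```

which prints:

```
samples: 4
steps: 13
total R1: 20.00 µL
total R2: 12.21 µL
total R3: 50.00 µL
total water: 317.79 µL
wrote demo/protocol.py
```

13 steps assemble the four 100 µL samples: nine reagent transfers (three of
the twelve design cells are 0 and are skipped) and four water top-ups that
bring each sample to its 100 µL target volume. `demo/protocol.py` is a
self-contained OT-2 script whose header records the SHA-256 digest of each
input CSV, so an archived script can always be matched to the exact inputs
that produced it; `demo/plan.tsv` lists every step with volume, wells,
pipette and rates. `otplan validate`, `otplan plan` and `otplan simulate`
run the earlier pipeline stages on their own.

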