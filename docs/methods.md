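# Methods

## Scope and model

`ergorula` implements observational ergonomic screening in three layers:

1. **RULA engine** (`ergorula.rula`): the Rapid Upper Limb Assessment —
   ordinal banding of body-segment postures, the published lookup Tables
   A/B/C, muscle-use and force/load adjustments, the grand score (1–7) and
   its action level (1–4).
2. **Exposure extension** (`ergorula.exposure`): per-task exposure value
   EV = D × RAL + V, where RAL is the worker-averaged action level for the
   task, D an ordinal duration band of daily task hours, V a binary
   vibration flag; EV is classified low / medium / high / very high.
3. **Action priority matrix** (`ergorula.priority`): worker-level 2×2 grid
   crossing exposure group (A: any high/very-high task; B: otherwise) with
   daily working hours (> 3 h or not), yielding one of four intervention
   actions.

The model's central assumption is that a single modal posture per
worker-task episode (the posture sustained longest) is representative; the
inputs are trained-observer walkthrough records, not instrumented angle
traces. All scores are ordinal; no arithmetic beyond the defined
combinations is meaningful.

## Lookup tables as data assets

Tables A (6×3×4×2), B (6×6×2) and C (8×7) are shipped as CSV assets under
`ergorula/data/` with SHA-256 checksums (`checksums.json`) verified at load
time, because single-source transcription error is the dominant correctness
risk for worksheet tools. The transcription was cross-checked against
multiple published reproductions of the worksheet; the test suite pins
corner and interior cells and sweeps both tables exhaustively for totality
and monotonicity in every argument. Table C inputs clamp to the printed
margins (C at 8+, D at 7+).

## Banding and boundary conventions

Worksheet band boundaries are applied lower-inclusive where two printed
bands share an edge (trunk flexed exactly 20° scores the 20–60° band;
1 h / 3 h / 7 h rank in the upper duration band), and strictly where the
worksheet phrases a strict threshold (wrist > 15°, trunk > 60°,
load > 10 kg, repetition > 4/min, matrix hours > 3). Wrist deviation is
banded by magnitude (flexion vs. extension does not change the band).
A load under 2 kg scores force 0 regardless of the static/repeated flag,
since the worksheet defines only the "< 2 kg intermittent" cell. The
muscle-use and force scores are assessed once from the observation and
applied to both the arm/wrist and neck/trunk/legs sides, mirroring the
worksheet's layout.

Observer sessions of the same worker-task are consolidated to the modal
breakdown by grand score, ties toward the higher score. This rule is a
design choice (the field practice is consensus by discussion, which has no
algorithmic content); ties resolve conservatively because the tool is a
screen, not a diagnosis.

## Exposure classification gaps

The published bins (1–2, 3–6, 8–12, 16+) omit attainable values 7 (= 3×2+1)
and 13 (= 4×3+1). The classifier closes the gaps contiguously — low ≤ 2,
medium 3–7, high 8–15, very high 16+ — preserving every published bin edge
(3, 8, 16). Values landing in a printed gap are flagged on the
`TaskExposure` and surfaced as report warnings rather than silently
classified.

One row of the published worked example (liquifying metal: RAL 3, band 2,
printed EV 3) contradicts the formula, which gives 6 (same class). The
package computes 6 and carries both values, flagged, in
`fixtures.expected_paper_results()`; reproducing the printed 3 would bake an
arithmetic error into a regression baseline.

`average_ral` rounds the mean action level half-up to an integer; the
worked example reports integer RALs without stating its rounding rule, and
half-up keeps midpoints conservative. Per-task SD is the sample SD (n−1);
a single observation reports SD 0 with a `single_observation` flag.

## Priority matrix conventions

"Multiple tasks conducted for > 3 h per working day" is read as the
worker's **total** daily hours across tasks exceeding 3 (this matches the
observed outcome that workers doing all tasks over a working day fall in
the immediate-action cell). The alternative reading — any single task
exceeding 3 h — is available as `hours_rule="any-task"`. Exactly 3 h falls
in the lower band (the strict ">" wins over the equally printed "<").
Group A membership is "any task high/very-high", the conservative screening
choice, rather than a majority rule.

## Pipeline

`run_assessment` chains: read/validate observations → consolidate observer
sessions per worker-task → RULA breakdown → per-task action-level average
(RAL) and descriptive statistics → duration band of the task's mean
recorded hours → task-level vibration (1 if any observation of the task
reports it) → EV and classification → per-worker priority. The pipeline is
deterministic; the config's `seed` exists to thread reproducibility into
simulated inputs.

The observation schema is a fixed 27-column table (CSV or JSON), UTF-8,
"." decimals, booleans as 0/1, angles in degrees with flexion positive and
(upper-arm) extension negative. Unknown or missing columns and unparseable
rows are named errors with row indices; nothing is coerced or dropped
silently.

## Packaged fixture

The nine-task hand-made cookware fixture carries the published per-task
values (RAL, duration band, vibration, printed EV/EC) in
`paper_tasks.json`. The raw 18-worker posture records behind those
summaries are not public, so `paper_observations.csv` is **synthetic**:
one constructed posture per task, derived from the published qualitative
hazard descriptions (trunk flexion ranges, loads, repetition rates,
kneeling/squatting, vibration), chosen so that the RULA engine reproduces
each task's printed action level, then replicated across 18 workers. Task
hours are band-representative values (0.5, 2, 5 h midpoints; 10 h for the
open 7+ band, matching the longest reported task). Consequences: the
fixture reproduces the published per-task EV/EC and the worker-level matrix
outcome exactly, but its per-task spread across workers is zero, so
published mean/SD summaries are checked for shape and internal consistency
only — passing tests say nothing about between-worker variability in real
data.

## Synthetic-data generator

`simulate_observations` emulates walkthrough records: per-task templates
with uniform angle ranges, Bernoulli posture flags, and uniform load,
repetition and hours ranges. The nine default templates mirror the cookware
study conditions (loads from under 2 kg to over 20 kg, ~12 repetitions/min,
task durations from half an hour to about ten hours, vibration only in
defect removal). Randomness is numpy PCG64; each worker draws from a
substream seeded by (seed, worker index), so tables are byte-reproducible
under a fixed seed and stable under per-worker parallel generation. The
generator produces independent draws — it does not emulate observer
disagreement, within-day task switching, or correlations between a
worker's postures across tasks.

## Numerical and degenerate-input choices

Ordinal arguments are validated strictly (booleans rejected where integers
are required); out-of-range values raise `DomainError`, malformed tables
`SchemaError`, non-finite angles fail validation at construction. Floats in
CSVs render via `%g` so write→read→write is byte-identical. Degenerate
cases: a neutral posture scores grand 1 / action level 1; an empty
observation table is an error, an empty worker list in a report is a
warning.

## Problem sizes

All domains are small by construction: the table sweeps are exhaustive
(144 + 72 + 56 cells, plus a 15×15 clamping sweep), the EV identity covers
all 32 (RAL, D, V) combinations, classifier totality covers EV 1–40, and
the composition property is checked on ~1,000 simulated observations. The
full suite runs in a few seconds on one CPU.

## Known limitations

- RULA variants (REBA, OWAS, QEC, strain index, NIOSH lifting equation) are
  out of scope, as are instrumented inputs (electrogoniometry, EMG) and
  photographic posture estimation.
- Vibration is a binary task-level flag; intensity, frequency and duration
  of vibration exposure are not modelled.
- The duration band uses each task's mean recorded hours across workers;
  per-worker duration banding would need per-worker EVs, which the method
  defines at task level.
- The exposure value is an ordinal screening index; it has no units and no
  dose-response interpretation.
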