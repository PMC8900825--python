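# Methods and design notes

## The workflow being modelled

A crystallographic fragment-screening campaign proceeds in five stages:
crystallization plates are registered (Plates), optionally cryo-protected
(Cryo), selected drops are soaked with fragment stock by an acoustic
dispenser (Soaking), optionally via the DMSO-free redissolve route
(Redissolve), and crystals are harvested onto pins in cryo-pucks
(Fishing). `fragflow` models the data and state of that workflow; it does
not drive instruments, and diffraction processing, ligand fitting and
refinement are upstream/downstream systems whose outputs it only consumes.

## Plate addressing

Crystallization plates are 96-well (8 rows × 12 columns) with three drop
subwells per well, displayed as row letter + 1-based column + lower-case
drop letter (`B7c`). Whether real facilities letter or number subwells
varies; `a/b/c` was chosen here and parsing is case-insensitive while
formatting is canonical. Source plates are 384 (A1–P24) or 1536
(A1–AF48); 1536 rows run A–Z then AA–AF, Excel-style, since no de facto
printed convention exists. All indices are 0-based internally, display
columns 1-based. Geometry lives in `config.py` (rows, columns, drops,
subwell centre offsets) so other plate types can be added without touching
workflow code.

## Diversity selection

Fragments are compared by binary structural fingerprints; we use Morgan
(circular) fingerprints, radius 2, 1024 bits — the kind and size are
configuration, because the contract is selection quality within a
descriptor family, not a specific proprietary descriptor. Distance is
Tanimoto: d = 1 − |A∩B|/|A∪B|. Selection is greedy MaxMin: the first
pick is the lexicographically smallest fragment id when `seed == 0`,
otherwise a seeded uniform choice (`first_id` can force it); each further
step adds the candidate maximizing its minimum distance to the selected
set, with ties broken by fragment-id order for determinism. Greedy MaxMin
guarantees that the *n*-selection is a prefix of the (*n*+1)-selection and
that, when started on a member of the globally most distant pair, its
first two picks attain that pair's distance; both properties are tested,
the second against a brute-force oracle and rdkit's independent MaxMin
picker.

## Campaign store

The store is an embedded JSON-lines file (one document per line, tagged
with its collection) rather than a database server: the behavioural
contract is the *validator*, not the engine. Each collection declares
required keys with types — Plates{barcode, kind, campaign},
Wells{plate_barcode, well, campaign}, Libraries{name, plate_format} — a
minimal set implied by what downstream operations need; these are
assumptions, declared in `config.py`. Validation is total: every insert
is either accepted or rejected with the offending key named; extra keys
always pass (schema-less beyond requirements). Booleans are not accepted
where numbers are required. Stage transitions are forward-only; a stage
may start or complete only when all earlier stages are done (or skipped,
for the optional Cryo and Redissolve); only optional stages may be
skipped. Station file exchange is a transport-agnostic file contract
(export a CSV, ingest a report CSV); no socket layer is included.

## Soak planning

- **Droplet quantum**: 2.5 nL, the ejection granularity of acoustic
  dispensers of this class; configurable. Every transfer volume must be an
  exact multiple (tolerance 1e-9 droplets).
- **Offsets**: a click at pixel (px, py) maps to
  ((px−cx)·s, (py−cy)·s) mm with +x right and +y down; results beyond the
  ±1.5 mm drop half-extent are clamped and flagged rather than rejected,
  since a stray click should warn, not crash a session.
- **Subwell encoding**: the transfer CSV addresses the 96-well position;
  the subwell is encoded by adding its configured centre offset (a
  triangular a/b/c layout) to the in-drop offset. The alternative —
  separate destination well names per subwell — is isolated behind the CSV
  writer and could be swapped without touching planning logic.
- **Transfer CSV**: cherry-pick convention columns (Source Plate Barcode,
  Source Well, Destination Plate Barcode, Destination Well, Transfer
  Volume, Destination Well X/Y Offset); volumes in nL with one decimal,
  offsets in mm with three decimals, rounded at construction so the CSV
  round-trips bit-exactly.
- **Timers**: per soak record (a per-plate duration is the maximum over
  its records), floored to whole minutes to match the display refresh
  granularity; stopped by the dispense report's arrival.
- **Report matching**: key = (destination barcode, well+drop); first match
  wins, duplicates and unplanned rows come back as discrepancies instead
  of raising, because a partial report must not destroy session state.
- **DMSO**: the final concentration of a t nL transfer into a d nL drop is
  100·t/(d+t) % v/v — strictly increasing in t and bounded in (0, 100).
- **Redissolve**: fragments are dispensed row-major one per subwell
  (A1a, A1b, A1c, A2a, …, 288 per plate) onto an empty plate and tracked
  through dispensed/dried/redissolved steps.

## Harvesting

Pucks hold 16 pins (SPINE/Unipuck convention; configurable). The
harvesting station reports per-drop outcomes in visiting order; the
barcode station reports a sequence-numbered puck/pin list. There is no
shared key, so the k-th *fished* row joins the k-th scan; skipped and
failed drops consume no scan. A count mismatch aborts with both counts
reported — guessing an alignment would silently mislabel samples. Optional
pin barcodes, when both sides record one, are cross-checked and
disagreements are surfaced as warnings, not resolved automatically. Sample
names are `campaign-plate-welldrop`; the sheet is emitted as CSV and XLSX
with identical cells, column names in a config template.

## Statistics

The funnel is soaked ≥ mounted ≥ diffracting ≥ RSCC-pass ≥ verified, all
percentages over the soaked count. Crystal-level percentages (mounted,
diffracting) print as whole percent and dataset-level ones (RSCC pass,
verified) to one decimal — the precision convention of published campaign
tables — rounded half away from zero using exact decimal arithmetic (no
float intermediates), an inference from printed values that is documented
as an assumption. The RSCC triage threshold (default 0.7) is inclusive.
Verification of a complex is human judgement and enters as an input flag;
RSCC values come from external fitting software. Funnel monotonicity is
asserted on inputs, never assumed. Resolution histograms use half-open
bins [lo, lo+w) with edges at multiples of the width (a value sitting
exactly on an edge bins rightward); interior empty bins are kept, counts
always sum to the input size.

## Synthetic campaigns

`FixtureSpec` defaults describe a realistic production-scale campaign:
2 plates × 288 drops (~576 planned soaks), 3% dispense failures, 3%
fishing skips, resolutions drawn from N(1.7 Å, 0.2 Å) truncated below at
0.9 Å (screening datasets cluster narrowly around a project-typical
resolution and nothing diffracts better than ~0.9 Å), a 7.5% RSCC pass
rate among diffracting datasets and 85% of passers verified — the shape of
a campaign with a mid-single-digit-percent hit rate. Passing RSCCs are
drawn uniform on [0.70, 0.95], failing ones on [0.20, 0.69]; datasets
worse than the cutoff get no RSCC (ligand density is not evaluated at low
resolution), which makes the funnel monotone by construction. All
randomness flows from one seed; the same spec yields byte-identical files.
The built-in catalogue holds 52 rule-of-3-sized fragment SMILES and is
cycled with fresh ids when more fragments are requested, so very large
simulated libraries repeat chemistry — fine for workflow tests, not for
chemistry benchmarks.

What the generator does **not** emulate: drop images (coordinates only),
source-volume depletion, crystal-quality correlations between neighbouring
drops, resolution-dependent RSCC reliability, and any systematic (non-i.i.d.)
failure mode. Passing tests therefore demonstrate workflow and statistical
correctness, not performance on real diffraction data.

## Problem sizes and verification

The test suite runs the address round-trip exhaustively (288 + 384 + 1536
addresses), 1000 random transfer plans, brute-force MaxMin checks on all
catalogue chunks of ≤8 molecules, 500 random funnels, 100 perturbed
documents per collection, and one full simulated campaign per end-to-end
test (~576 soaks), completing in a few seconds on one CPU. The end-to-end
funnel is checked against binomial expectations (truncated-normal CDF for
the resolution stage) within 3 standard deviations at the simulated n.
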