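# Methods and design notes

## What the package models

The package is a laboratory-information core for protein crystallization:
a persistent record of which crystal grew where (plate / well / drop /
condition), what it was called, which container it sits in, and where it
has been. There is no numerical model to fit; the "science" here is a set
of naming, bookkeeping and safety rules whose violation costs real beam
time, so the package treats those rules as invariants and tests them as
such.

## Sample-name grammar

Names follow `ACRONYM "_" BARCODE WELL "d" DROP "c" CRYSTAL ["_" EXT]`.
The grammar is formalized from worked examples, so two choices were made
explicit:

* Acronyms and plate barcodes are restricted to `[A-Za-z0-9]`. This makes
  the parse unambiguous: the first underscore ends the acronym, a second
  underscore starts the user extension, and the core is parsed
  right-anchored (`c<int>`, then `d<int>`, then a three-character well
  label `A07`); whatever remains is the barcode. A property test drives
  10⁴ random field tuples through generate→parse to confirm the round
  trip, including barcodes that themselves contain well-like substrings.
* Well columns are zero-padded to width 2 (`A07`, `E01`), fixed by the
  printed examples; 384-well label schemes are out of scope.

Limits: 45 characters is a hard error (the downstream sample database
rejects longer names), 27 a warning (synchrotron implementations differ);
the full rendered string including the extension is counted, the
conservative reading. The core name without extension is the global
uniqueness key, so renaming a ligand extension never collides. Crystal
numbers within a drop are issued in selection order and never reused;
deleting a selected crystal is tombstoning, not renumbering — issued names
are immutable.

## Translation

Nucleotide sequences are translated on entry (reading frame 1, standard
genetic code, via Biopython) with U treated as T. Ambiguity codes whose
codon still decodes uniquely are translated (GCN → A); anything else,
including Biopython's two-letter ambiguity residues B/Z/J, is collapsed to
X; stop codons, internal or terminal, are kept as `*`. No ORF finding, no
multi-frame translation. The test oracle is an independently hand-written
64-codon table with explicit ambiguity expansion.

## Screens

Three dialects are read into one `Screen` container: two-column text
(well + free-text condition, tab or first-comma delimited), CSV (header
with `Well`/`Condition`, plus an optional `Components` column holding a
JSON-encoded ingredient list so write∘parse is lossless), and an XML
subset (`screen/condition/ingredient` with name, concentration, unit, pH;
unknown elements ignored, since vendor XML varies by version). MIMER is
deliberately unsupported — its schema is defined externally — and reports
an unsupported-format error rather than guessing. Well labels are
normalized (`A1` → `A01`); normalization is idempotent and rejects labels
outside the 8×12 geometry. No chemical-ontology normalization of condition
components is attempted.

## Imaging import

Vendor imager databases are replaced by a file-drop contract: one
directory per inspection with a flat `key: value` sidecar (barcode,
ISO timestamp, mode, optional owner/temperature/geometry/scale) and one
image per drop named `<well><subposition>.png`. Inspections are ingested
only once they are older than `import_delay_s` (default 300 s) so a
half-written export is never imported; age is measured against the sidecar
timestamp, which keeps ingestion deterministic and testable. Re-scanning
is idempotent (keyed on barcode + timestamp + mode). Malformed sidecars
are quarantined with a reason, never crash a scan; an unknown owner hint
assigns the plate to a configurable fallback user rather than dropping
data. Plate expiry is an explicit call (`mark_plate_expired`) rather than
a clock policy, with an optional max-age config left to deployments.

## Scoring and selection

The score vocabulary is an ordered, configurable list (default 10 classes,
clear < precipitates < phase separation < … < single crystal) with display
colors; only the ordinal matters to the code. The full score history per
drop is append-only; the plate's "best score" is a cache of the maximum
ordinal, checked in tests against a brute-force recount. Crystal
measurements are a single longest-dimension length in µm and are accepted
only when the drop's latest image carries imager scale information.
ISPyB pre-information (space group, six positive cell parameters, known /
desired resolution in Å) may be set at selection or any time later; the
shipment payload snapshots whatever is present at submission time.

## Bench and containers

Puck capacity defaults to 16 (uni-puck convention) and is configurable per
puck. "First puck" in the first-empty-slot placement rule means the
earliest *scanned* puck of the session that still has space — scan order
is the only order the bench knows. Dummy (non-barcoded) pins are created
by fishing straight onto a puck; their slot is their only identity, so
they may be repositioned within their puck but never moved to another one,
and washing retires them. Quick-fish requires a barcoded pin precisely
because it skips puck placement. Containers inside a *sent* shipment are
locked against mutation (the physical dewar is away). A crystal can be
dismounted only by the wash flow; there is no ad-hoc dismount.

All bench mutations append to a session event log, and
`replay_placements` reconstructs puck occupancy from the log alone; a test
asserts replay ≡ actual state (event-sourcing property). Operations
validate before mutating, so a refused fish or move leaves no partial
state.

## Shipment

Validation flags, per subject: empty dewars, empty pucks, pins without a
crystal, crystals without a protein acronym, acronyms missing from the
shipment's approved list, and names over 45 characters. Submission is
blocked unless the report is clean; the acceptance suite cross-checks the
validator against an independent brute-force recount on 10³ randomly
flawed container trees and asserts submit succeeds iff the report is
clean.

The payload is a self-defined JSON hierarchy
(shipment → dewars → containers → samples) in deterministic
(dewar, puck, position) order, since the upstream API's exact field set is
site-specific; endpoint URL and link templates
(`{proposal}/{session}/{sample}`) are configuration. The bundled mock
endpoint exists in two forms: an in-process object (default, used by
tests) and the same logic behind stdlib `http.server` for HTTP exercises;
the HTTP client uses stdlib `urllib`. On endpoint failure the shipment
stays a retryable draft. The manifest is canonical as structured rows —
one per mounted crystal, with the local crystal-page link and the
synchrotron per-sample link, and QR payload strings identical to those two
URLs — plus a plain-text rendering with a note margin; PDF typography and
QR rasterization are out of scope.

Return processing: a pin's recorded disposition (`keep_crystal` /
`wash_pin`) drives unpacking; if none was recorded the pin is washed and
the result carries a warning. Washing empties the pin and returns it to
the pool while the crystal record survives with its full pin and shipment
history; kept crystals stay mounted and re-shippable, accumulating one
history entry (proposal + session ids) per submitted shipment. When every
pin is processed, pucks and dewars revert to the lab pool.

## Search

Exact barcode / core-name / PDB-code hits rank before substring hits over
rendered names (which is how a ligand-name extension finds its series);
ties break by recency. PDB codes are 4 characters starting with a digit,
stored lowercase, matched case-insensitively, with multiple codes per
crystal and an undo. Results are filtered by project read permission when
a caller is supplied; container barcodes are lab-wide. The incremental
index is tested for equality against a from-scratch rebuild after random
operation sequences. No full-text search over note bodies, no fuzzy
matching.

## Permissions

Authorization is enforced in the library: every mutating operation takes a
caller. Project owners and members write; guests read; admins bypass; only
users flagged as shippers assemble and submit shipments. Callers are
trusted identities — there is no authentication backend.

## Synthetic data

The fixture generator emulates an imager export: 2 plates × 96 wells ×
3 drops × 3 inspections by default, with sidecars, small grey-noise PNGs,
and a ground-truth list marking each drop crystal-bearing independently
with probability 0.1 (a realistic hit rate for a sparse-matrix screen; on
the default geometry that is ~58 of 576 drops). The generator is
byte-deterministic per seed. It does **not** emulate real drop imagery,
focus stacks, UV cross-validation, imager clock skew or partial exports —
so passing tests demonstrate correct bookkeeping over the contract, not
robustness to imager quirks beyond the quarantine path.

## Problem sizes and numerics

The randomized suites use sizes chosen to give strong coverage while
keeping the default test run quick: 10⁴ name round trips, 10³ container
trees for validation soundness, 100 independent lifecycle sequences of
10³ operations each (10⁵ operations total) with invariants checked after
every step, and 10³ random sequences for the translation oracle. There is
no floating-point estimation anywhere; all comparisons are exact, and
determinism is asserted by hashing the canonical JSON payload.

## Known limitations

* One store, one process: the JSON persistence is a snapshot, not a
  concurrent database; simultaneous CLI invocations can lose updates.
* Per-drop volumes/ratios for three-drop plates are stored as free-form
  text per subposition; no arithmetic is done on them.
* One payload schema; adapters for other synchrotron API flavors are an
  open seam.
* Search spans only structured fields; notes are reachable from their
  parent records, not searchable globally.
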