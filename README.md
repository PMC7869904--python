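# xtaltrack

A headless Python library (plus a thin CLI) that tracks macromolecular
crystallization experiments end to end: 96-well plate registration and
inspection import from an imaging system, drop scoring and time-lapse
viewing, crystal selection with systematic sample naming, cryo-fishing
into barcoded pins/pucks/dewars at a virtual workbench, validated shipment
of samples to a synchrotron with automatic metadata upload, data-collection
bookkeeping, dewar-return recycling, and PDB-code back-linking with global
search.

It is aimed at structural-biology laboratories that image crystallization
plates and ship cryocooled crystals to synchrotron beamlines, where
unattended data collection makes complete, pre-uploaded sample metadata
essential.

## The data model in one paragraph

Every selected crystal receives a globally unique sample name

```
<ACRONYM>_<BARCODE><WELL>d<DROP>c<CRYSTAL>[_<EXTENSION>]
```

for example `LMTIM_9098A07d1c1`: protein acronym `LMTIM`, plate barcode
`9098`, well `A07`, drop 1, first crystal fished from that drop (a second
crystal from the same drop becomes `…d1c2`). The acronym is the short,
case-sensitive, strictly alphanumeric safety identifier registered at the
synchrotron (at most 5 characters recommended); the full name must stay
within 45 characters (27 recommended). Crystals are mounted on *pins*
(barcoded, or positionally tracked "dummy" pins), pins sit in numbered
slots of *pucks* (16 by default), pucks travel in *dewars*, and a dewar
moves through `in_lab → in_shipment → sent → returned → in_lab`. Before
submission a shipment is validated: no empty dewar, puck or pin; every
crystal's acronym present and on the shipment's approved list; no
over-length sample name.

## Worked example

```python
from xtaltrack import LabStore, domain, imaging, scoring, naming

store = LabStore()
store.add_user("u1")
project = domain.create_project(store, "TIM kinetics", "TIM variants", "u1")
protein = domain.add_protein(store, project, "LMTIM")
plate = imaging.register_plate_from_imager(
    store, {"barcode": "9098", "owner": "u1"})
imaging.assign_plate(store, plate, project.id, protein.id, None, "u1")

crystal = scoring.select_crystal(store, plate, "A07", 1, "u1")
print(crystal.sample_name.rendered)
print(naming.parse_sample_name(crystal.sample_name.rendered))
```

prints

```
LMTIM_9098A07d1c1
SampleName(acronym='LMTIM', plate_barcode='9098', well_label='A07',
           drop_number=1, crystal_number=1, extension=None)
```

i.e. the first crystal selected in drop 1 of well A07 on plate 9098 is
named from the plate's protein acronym, and the name parses back into its
parts (this round trip is what makes barcode- and name-based search work).

The whole workflow can be exercised against a synthetic imager export:

```
$ xtaltrack demo work/ --seed 5
{
 "n_inspections": 6,
 "n_crystals": 54,
 "validation_ok": true,
 "manifest_rows": 54,
 "payload_samples": 54,
 "pins_kept": 18,
 "pins_washed": 36,
 "dewar_states": ["in_lab"],
 ...
}
```

Two plates, three inspections each, are ingested (6 inspections); the 54
drops flagged crystal-bearing in the generator's ground truth are scored
and selected; all 54 crystals are fished, shipped and submitted to the
mock synchrotron endpoint (54 manifest rows = 54 payload samples); on
return 18 pins keep their crystals for the next trip, 36 are washed, and
every dewar ends back `in_lab`.

The CLI mirrors the library per module: `xtaltrack project|name|screen|
plate|ingest|fixture|drop|crystal|bench|ship|search`, with state kept in a
JSON file (`--db`).

## Scope notes

No web GUI, no image analysis or automated scoring, no live imager
integration (a documented file-drop inbox contract replaces vendor
databases), no real synchrotron authentication (the bundled mock endpoint
accepts the payload), and no MIMER screen-format support. See
`docs/methods.md` for design details and limitations.
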