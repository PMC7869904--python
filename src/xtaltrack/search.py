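"""Global search and the crystal page.

One search box covers plate, pin, puck and dewar barcodes, crystal sample
names, user extensions and PDB codes.  Exact matches (barcode, core name,
PDB code) rank before substring matches on rendered names — so searching a
ligand name used as a sample-name extension finds every crystal of that
ligand series.  PDB codes are stored lowercase and matched
case-insensitively.

The crystal page (:func:`crystal_detail`) aggregates everything known about
one sample: where it grew (plate, drop, crystallization conditions), where
it sits (pin, puck, dewar), every shipment it went on with proposal and
session ids, its synchrotron links, notes, files and PDB codes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import NotFoundError, PermissionDenied, ValidationError

_PDB_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


@dataclass
class SearchHit:
    kind: str  # "plate" | "pin" | "puck" | "dewar" | "crystal"
    key: str
    match: str  # "barcode" | "name" | "pdb" | "extension"
    rank: int  # 0 = exact, 1 = substring


class SearchIndex:
    """Incrementally maintained lookup structures.

    ``rebuild`` reconstructs everything from the store; tests use it as the
    oracle against the incrementally updated state.
    """

    def __init__(self) -> None:
        self.barcodes: dict[str, str] = {}  # barcode -> kind
        self.crystal_names: dict[str, str] = {}  # core name -> core name (key)
        self.rendered_names: dict[str, str] = {}  # core name -> rendered
        self.pdb_codes: dict[str, set[str]] = {}  # lowercase code -> core names

    def add_barcode(self, kind: str, barcode: str) -> None:
        self.barcodes[barcode] = kind

    def add_crystal(self, crystal) -> None:
        self.crystal_names[crystal.core_name] = crystal.core_name
        self.rendered_names[crystal.core_name] = crystal.sample_name.rendered

    def update_crystal(self, crystal) -> None:
        self.rendered_names[crystal.core_name] = crystal.sample_name.rendered

    def add_pdb(self, code: str, core_name: str) -> None:
        self.pdb_codes.setdefault(code.lower(), set()).add(core_name)

    def remove_pdb(self, code: str, core_name: str) -> None:
        entries = self.pdb_codes.get(code.lower())
        if entries is not None:
            entries.discard(core_name)
            if not entries:
                del self.pdb_codes[code.lower()]

    def rebuild(self, store) -> "SearchIndex":
        fresh = SearchIndex()
        for barcode in store.plates:
            fresh.add_barcode("plate", barcode)
        for pin in store.pins.values():
            if pin.barcode:
                fresh.add_barcode("pin", pin.barcode)
        for barcode in store.pucks:
            fresh.add_barcode("puck", barcode)
        for barcode in store.dewars:
            fresh.add_barcode("dewar", barcode)
        for crystal in store.crystals.values():
            fresh.add_crystal(crystal)
            for code in crystal.pdb_codes:
                fresh.add_pdb(code, crystal.core_name)
        return fresh


def _readable(store, caller: Optional[str], crystal_key: str) -> bool:
    """Results are filtered by project read permission when a caller is
    given; container barcodes are visible lab-wide."""
    if caller is None:
        return True
    from .domain import can_read
    crystal = store.crystals[crystal_key]
    plate = store.plates.get(crystal.plate_barcode)
    if plate is None or plate.project_id is None:
        return True
    return can_read(store, caller, plate.project_id) or plate.owner == caller


def search(store, query: str, caller: Optional[str] = None) -> list[SearchHit]:
    """Rank exact barcode / sample-name / PDB hits first, then
    extension/substring hits over rendered names; ties break by recency
    (most recently created first).  An empty query returns nothing."""
    query = query.strip()
    if not query:
        return []
    index = store.index
    hits: list[SearchHit] = []
    seen: set[tuple[str, str]] = set()

    def add(kind: str, key: str, match: str, rank: int) -> None:
        if (kind, key) not in seen:
            seen.add((kind, key))
            hits.append(SearchHit(kind, key, match, rank))

    if query in index.barcodes:
        kind = index.barcodes[query]
        add(kind, query, "barcode", 0)
    if query in index.crystal_names and _readable(store, caller, query):
        add("crystal", query, "name", 0)
    for core in index.pdb_codes.get(query.lower(), ()):
        if _readable(store, caller, core):
            add("crystal", core, "pdb", 0)
    # substring over rendered names (covers user extensions), newest first
    substring = [
        core for core, rendered in index.rendered_names.items()
        if query in rendered and _readable(store, caller, core)
    ]
    for core in sorted(substring, key=lambda c: store.crystals[c].selected_at,
                       reverse=True):
        add("crystal", core, "extension", 1)
    hits.sort(key=lambda h: h.rank)
    return hits


def link_pdb(store, crystal, pdb_code: str, caller: str):
    """Record a PDB deposition on the crystal page.

    Codes are 4 characters, starting with a digit; stored lowercase.
    Multiple codes per crystal are allowed.
    """
    from .scoring import _require_plate_write
    _require_plate_write(store, store.plates[crystal.plate_barcode], caller)
    if not _PDB_RE.match(pdb_code):
        raise ValidationError(
            f"{pdb_code!r} is not a PDB code (4 alphanumerics starting "
            "with a digit)"
        )
    code = pdb_code.lower()
    if code not in crystal.pdb_codes:
        crystal.pdb_codes.append(code)
        store.index.add_pdb(code, crystal.core_name)
    return crystal


def unlink_pdb(store, crystal, pdb_code: str, caller: str):
    """Undo a wrongly entered PDB code."""
    from .scoring import _require_plate_write
    _require_plate_write(store, store.plates[crystal.plate_barcode], caller)
    code = pdb_code.lower()
    if code not in crystal.pdb_codes:
        raise NotFoundError(f"crystal has no PDB code {pdb_code!r}")
    crystal.pdb_codes.remove(code)
    store.index.remove_pdb(code, crystal.core_name)
    return crystal


def crystal_detail(store, core_name: str, caller: Optional[str] = None) -> dict:
    """The crystal page as a composite record."""
    crystal = store.crystals.get(core_name)
    if crystal is None:
        raise NotFoundError(f"unknown crystal {core_name!r}")
    if caller is not None and not _readable(store, caller, core_name):
        raise PermissionDenied(f"user {caller!r} may not view {core_name!r}")
    plate = store.plates.get(crystal.plate_barcode)
    condition = None
    if plate is not None and plate.setup.screen_name:
        screen = store.screens.get(plate.setup.screen_name)
        if screen is not None:
            cond = screen.conditions.get(crystal.well)
            condition = cond.description if cond else None
    pin = next(
        (p for p in store.pins.values() if p.crystal_name == core_name), None
    )
    location = None
    if pin is not None:
        from .bench import _puck_of, _slot_of
        puck = _puck_of(store, pin)
        location = {
            "pin": pin.id,
            "pin_barcode": pin.barcode,
            "pin_state": pin.state,
            "puck": puck.barcode if puck else None,
            "position": _slot_of(puck, pin.id) if puck else None,
        }
        if puck is not None:
            for dewar in store.dewars.values():
                if puck.barcode in dewar.puck_barcodes:
                    location["dewar"] = dewar.barcode
    return {
        "sample_name": crystal.sample_name.rendered,
        "core_name": crystal.core_name,
        "acronym": crystal.sample_name.acronym,
        "drop": {
            "plate": crystal.plate_barcode,
            "well": crystal.well,
            "subposition": crystal.subposition,
            "condition": condition,
            "protein_buffer": plate.setup.protein_buffer if plate else None,
        },
        "selected_by": crystal.selected_by,
        "selected_at": crystal.selected_at.isoformat(),
        "ispyb_info": dict(crystal.ispyb_info),
        "location": location,
        "shipment_history": list(crystal.shipment_history),
        "ispyb_links": list(crystal.ispyb_links),
        "notes": [
            {"author": n.author, "at": n.timestamp.isoformat(), "text": n.text}
            for n in crystal.notes
        ],
        "files": [
            {"author": f.author, "path": f.path, "media_type": f.media_type}
            for f in crystal.files
        ],
        "pdb_codes": list(crystal.pdb_codes),
        "icebear_link": store.config.icebear_link_template.format(
            sample=crystal.sample_name.rendered
        ),
    }
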