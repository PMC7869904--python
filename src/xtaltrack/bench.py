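"""The crystal-fishing virtual workbench.

Fishing (harvesting) moves a crystal from its drop onto a *pin*, which sits
in a numbered slot of a *puck*, which travels inside a *dewar*.  At the
bench, plates and containers are declared present by scanning their
barcodes into a session; a crystal is then fished onto a pin and the pin is
placed, by default, at the lowest-numbered empty slot of the earliest
scanned puck that still has space.

Non-barcoded ("dummy") pins are supported: fishing straight onto a puck
creates one, and from then on its position in the puck is its only
identity, so dummy pins never move between pucks.  Quick-fish binds a
crystal to a specific barcoded pin with no puck involved at all — the pin
is placed later, at the bench or while finalizing a shipment.

Every mutation appends to the session event log; replaying the log
reconstructs the bench state exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

from .errors import (
    CapacityError,
    LockedError,
    NotFoundError,
    OccupancyError,
    StateError,
    ValidationError,
)
from .imaging import DropImage, Inspection, Plate, drop_key
from .scoring import Crystal, select_crystal

PIN_STATES = ("available", "mounted", "in_shipment", "returned_keep", "washed")
DEWAR_STATES = ("in_lab", "in_shipment", "sent", "returned")


@dataclass
class Pin:
    id: str
    barcode: Optional[str] = None  # None for dummy pins
    crystal_name: Optional[str] = None  # core sample name
    state: str = "available"

    @property
    def dummy(self) -> bool:
        return self.barcode is None


@dataclass
class Puck:
    barcode: str
    capacity: int = 16
    slots: dict[int, str] = field(default_factory=dict)  # position -> pin id

    def first_empty_slot(self) -> Optional[int]:
        for pos in range(1, self.capacity + 1):
            if pos not in self.slots:
                return pos
        return None


@dataclass
class Dewar:
    barcode: str
    puck_barcodes: list[str] = field(default_factory=list)
    state: str = "in_lab"
    shipment_id: Optional[str] = None


@dataclass
class BenchSession:
    user: str
    plates: list[str] = field(default_factory=list)
    pins: list[str] = field(default_factory=list)
    pucks: list[str] = field(default_factory=list)  # scan order matters
    dewars: list[str] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)

    def log(self, op: str, now: Optional[datetime] = None, **details) -> None:
        self.events.append(
            {"op": op, "at": (now or datetime.now()).isoformat(), **details}
        )


# ---------------------------------------------------------------------------
# helpers


def _shipment_locked(store, pin: Pin) -> bool:
    """True when the pin sits in a container of a sent shipment."""
    puck = _puck_of(store, pin)
    if puck is None:
        return False
    for dewar in store.dewars.values():
        if puck.barcode in dewar.puck_barcodes and dewar.state == "sent":
            return True
    return False


def _puck_of(store, pin: Pin) -> Optional[Puck]:
    for puck in store.pucks.values():
        if pin.id in puck.slots.values():
            return puck
    return None


def _slot_of(puck: Puck, pin_id: str) -> Optional[int]:
    for pos, pid in puck.slots.items():
        if pid == pin_id:
            return pos
    return None


def create_pin(store, barcode: Optional[str]) -> Pin:
    if barcode is not None:
        if barcode in store.pins_by_barcode:
            raise ValidationError(f"pin {barcode!r} already exists")
        pin = Pin(id=barcode, barcode=barcode)
        store.index.add_barcode("pin", barcode)
    else:
        pin = Pin(id=store.new_id("dummy"), barcode=None)
    store.pins[pin.id] = pin
    return pin


def create_puck(store, barcode: str, capacity: Optional[int] = None) -> Puck:
    if barcode in store.pucks:
        raise ValidationError(f"puck {barcode!r} already exists")
    puck = Puck(barcode=barcode, capacity=capacity or store.config.puck_capacity)
    store.pucks[barcode] = puck
    store.index.add_barcode("puck", barcode)
    return puck


def create_dewar(store, barcode: str) -> Dewar:
    if barcode in store.dewars:
        raise ValidationError(f"dewar {barcode!r} already exists")
    dewar = Dewar(barcode=barcode)
    store.dewars[barcode] = dewar
    store.index.add_barcode("dewar", barcode)
    return dewar


# ---------------------------------------------------------------------------
# operations


def start_session(store, user: str) -> BenchSession:
    session = BenchSession(user=user)
    store.sessions.append(session)
    return session


def scan_item(store, session: BenchSession, barcode: str,
              kind_hint: Optional[str] = None,
              now: Optional[datetime] = None) -> dict:
    """Add a plate or container to the workbench by barcode.

    Returns a summary of what was scanned: for a plate, its selected
    crystals (so the bench can highlight them); for a pin, whether it
    already carries a crystal.  Re-scanning is a no-op.  Unknown barcodes
    are resolved via ``kind_hint`` ('pin', 'puck', 'dewar') by creating the
    container on the fly; without a hint they are an error.
    """
    kind, obj = _resolve_barcode(store, barcode)
    if kind is None:
        if kind_hint == "pin":
            obj = create_pin(store, barcode)
            kind = "pin"
        elif kind_hint == "puck":
            obj = create_puck(store, barcode)
            kind = "puck"
        elif kind_hint == "dewar":
            obj = create_dewar(store, barcode)
            kind = "dewar"
        else:
            raise NotFoundError(
                f"barcode {barcode!r} is unknown and no kind hint was given"
            )
    session_list = {
        "plate": session.plates, "pin": session.pins,
        "puck": session.pucks, "dewar": session.dewars,
    }[kind]
    item_id = obj.id if kind == "pin" else obj.barcode
    already = item_id in session_list
    if not already:
        session_list.append(item_id)
        session.log("scan", now=now, kind=kind, barcode=barcode)
    info: dict = {"kind": kind, "barcode": barcode, "already_in_session": already}
    if kind == "plate":
        info["selected_crystals"] = [
            c.core_name for c in store.crystals.values()
            if c.plate_barcode == barcode and not c.tombstoned
        ]
    if kind == "pin":
        info["occupied"] = obj.crystal_name is not None
    return info


def _resolve_barcode(store, barcode: str):
    if barcode in store.plates:
        return "plate", store.plates[barcode]
    if barcode in store.pins_by_barcode:
        return "pin", store.pins_by_barcode[barcode]
    if barcode in store.pucks:
        return "puck", store.pucks[barcode]
    if barcode in store.dewars:
        return "dewar", store.dewars[barcode]
    return None, None


def _check_fishable(store, crystal: Crystal) -> None:
    if crystal.tombstoned:
        raise StateError(f"crystal {crystal.core_name!r} is deleted")
    mounted_on = [p for p in store.pins.values()
                  if p.crystal_name == crystal.core_name
                  and p.state in ("mounted", "in_shipment", "returned_keep")]
    if mounted_on:
        raise OccupancyError(
            f"crystal {crystal.core_name!r} is already mounted on pin "
            f"{mounted_on[0].id!r}"
        )


def _mount(store, crystal: Crystal, pin: Pin) -> None:
    _check_fishable(store, crystal)
    if pin.crystal_name is not None:
        raise OccupancyError(f"pin {pin.id!r} already carries a crystal")
    if pin.state not in ("available",):
        raise StateError(f"pin {pin.id!r} is {pin.state}, not available")
    pin.crystal_name = crystal.core_name
    pin.state = "mounted"
    crystal.pin_history.append(pin.id)


def _first_empty(store, session: BenchSession) -> tuple[Puck, int]:
    """First-empty rule: lowest-numbered free slot of the earliest scanned
    puck that still has space."""
    for puck_barcode in session.pucks:
        puck = store.pucks[puck_barcode]
        pos = puck.first_empty_slot()
        if pos is not None:
            return puck, pos
    raise CapacityError("no scanned puck has a free slot")


def fish_crystal(store, session: BenchSession, crystal: Crystal,
                 pin: Optional[Pin] = None,
                 now: Optional[datetime] = None) -> dict:
    """Fish a crystal onto a pin and place the pin in a puck.

    With an explicit (scanned, empty) pin, that pin is used; with none, a
    dummy pin is created — either way the pin goes to the first empty slot
    of the first scanned puck with space.
    """
    # all checks precede any mutation so a refused fish changes nothing
    _check_fishable(store, crystal)
    puck, pos = _first_empty(store, session)
    if pin is not None:
        if pin.id not in session.pins:
            raise ValidationError(f"pin {pin.id!r} has not been scanned")
        if pin.crystal_name is not None:
            raise OccupancyError(f"pin {pin.id!r} already carries a crystal")
        if pin.state != "available":
            raise StateError(f"pin {pin.id!r} is {pin.state}, not available")
    else:
        pin = create_pin(store, None)  # dummy pin, positional identity
        session.pins.append(pin.id)
    _mount(store, crystal, pin)
    puck.slots[pos] = pin.id
    record = {
        "crystal": crystal.core_name, "pin": pin.id, "dummy": pin.dummy,
        "puck": puck.barcode, "position": pos,
    }
    session.log("fish", now=now, **record)
    return record


def move_pin(store, pin: Pin, target_puck: Puck, position: int,
             session: Optional[BenchSession] = None,
             now: Optional[datetime] = None) -> None:
    """Relocate a pin to a specific puck slot (or place an unplaced pin).

    Forbidden for pins of sent shipments and, across pucks, for dummy pins
    (their slot is their only identity).
    """
    if not (1 <= position <= target_puck.capacity):
        raise ValidationError(
            f"position {position} outside puck capacity {target_puck.capacity}"
        )
    if position in target_puck.slots:
        raise OccupancyError(
            f"slot {position} of puck {target_puck.barcode!r} is occupied"
        )
    if _shipment_locked(store, pin):
        raise LockedError(f"pin {pin.id!r} belongs to a sent shipment")
    current = _puck_of(store, pin)
    if pin.dummy and current is not None and current.barcode != target_puck.barcode:
        raise ValidationError(
            "dummy pins are tracked by their puck position and cannot move "
            "to another puck"
        )
    if current is not None:
        del current.slots[_slot_of(current, pin.id)]
    target_puck.slots[position] = pin.id
    if session is not None:
        session.log("move", now=now, pin=pin.id, puck=target_puck.barcode,
                    position=position)


def quick_fish(store, crystal: Crystal, pin_barcode: str,
               now: Optional[datetime] = None) -> dict:
    """Bind a crystal to a specific *barcoded* pin with no puck placement;
    the pin can be dropped into a puck later at the bench or while the
    shipment is finalized."""
    if not pin_barcode:
        raise ValidationError("quick-fish requires a barcoded pin")
    pin = store.pins_by_barcode.get(pin_barcode)
    if pin is None:
        pin = create_pin(store, pin_barcode)
    if pin.dummy:
        raise ValidationError("quick-fish requires a barcoded pin")
    _mount(store, crystal, pin)
    return {"crystal": crystal.core_name, "pin": pin.id, "puck": None,
            "position": None}


def fish_unimaged(store, session: BenchSession, plate_barcode: str,
                  well: str, drop_number: int, caller: str,
                  project_id: Optional[str] = None,
                  protein_id: Optional[str] = None,
                  pin: Optional[Pin] = None,
                  now: Optional[datetime] = None) -> dict:
    """Fish from a plate that was never imaged.

    The plate is registered on the fly with default geometry if needed, a
    dummy drop image is attached so the drop exists in the record, and the
    crystal is selected (c1, c2, ...) and mounted in one step.  For a new
    plate the protein must be supplied so a sample name can be formed.
    """
    now = now or datetime.now()
    plate = store.plates.get(plate_barcode)
    if plate is None:
        plate = Plate(
            barcode=plate_barcode,
            rows=store.config.default_rows,
            cols=store.config.default_cols,
            drops_per_well=store.config.default_drops_per_well,
            owner=caller,
        )
        store.plates[plate_barcode] = plate
        store.index.add_barcode("plate", plate_barcode)
    if protein_id is not None:
        plate.project_id = project_id or store.proteins[protein_id].project_id
        plate.protein_id = protein_id
    if not plate.valid_drop(well, drop_number):
        raise ValidationError(
            f"drop {well}/{drop_number} outside plate geometry "
            f"({plate.rows}x{plate.cols}, {plate.drops_per_well} drops/well)"
        )
    key = drop_key(well, drop_number)
    if plate.latest_image(well, drop_number) is None:
        dummy_inspection = Inspection(
            plate_barcode=plate_barcode, timestamp=now, mode="visible",
            images={key: DropImage(path="", dummy=True)},
        )
        plate.inspections.append(dummy_inspection)
    if plate_barcode not in session.plates:
        session.plates.append(plate_barcode)
    crystal = select_crystal(store, plate, well, drop_number, caller, now=now)
    record = fish_crystal(store, session, crystal, pin=pin, now=now)
    session.log("fish_unimaged", now=now, crystal=crystal.core_name)
    return {"crystal_obj": crystal, **record}


# ---------------------------------------------------------------------------
# event-log replay (event-sourcing check)


def replay_placements(store, session: BenchSession) -> dict[str, dict[int, str]]:
    """Reconstruct puck occupancy for the session's pucks from its event
    log alone: {puck barcode: {position: pin id}}."""
    state: dict[str, dict[int, str]] = {}
    for event in session.events:
        if event["op"] == "scan" and event["kind"] == "puck":
            state.setdefault(event["barcode"], {})
        elif event["op"] == "fish":
            state.setdefault(event["puck"], {})[event["position"]] = event["pin"]
        elif event["op"] == "move":
            for slots in state.values():
                for pos, pid in list(slots.items()):
                    if pid == event["pin"]:
                        del slots[pos]
            state.setdefault(event["puck"], {})[event["position"]] = event["pin"]
    return state
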