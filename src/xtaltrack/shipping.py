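"""Shipment assembly, validation, synchrotron submission and dewar return.

A shipment is assembled by a *shipper* (a user also registered at the
synchrotron) from dewars prepared at the bench.  Before submission the
container tree is validated: no empty dewars, pucks or pins may travel,
every crystal must have a protein acronym and that acronym must be on the
shipment's approved safety list, and no sample name may exceed the
45-character limit.  Submission POSTs a deterministic, hierarchical payload
(shipment -> dewars -> containers -> samples) to the configured endpoint
and records a receipt; each crystal's page gains the per-sample link into
the synchrotron database and a shipment-history entry with the proposal and
session ids.

After data collection each pin position carries a disposition — keep the
crystal for another trip, or wash the pin — and once the dewar is back,
processing those decisions recycles pins, pucks and dewars for reuse.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

from . import naming
from .bench import Dewar, Pin, Puck, _puck_of, _slot_of
from .errors import (
    ConflictError,
    NotFoundError,
    PermissionDenied,
    StateError,
    TransportError,
    ValidationError,
)

VIOLATION_CODES = (
    "EMPTY_DEWAR",
    "EMPTY_PUCK",
    "EMPTY_PIN",
    "MISSING_ACRONYM",
    "UNAPPROVED_ACRONYM",
    "NAME_TOO_LONG",
)


@dataclass
class Violation:
    code: str
    subject: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class CollectionRecord:
    shipment_id: str
    puck_barcode: str
    position: int
    collected: bool = False
    notes: list = field(default_factory=list)
    disposition: Optional[str] = None  # "keep_crystal" | "wash_pin"


@dataclass
class Shipment:
    id: str
    shipper: str
    synchrotron: str
    proposal_id: Optional[str] = None
    session_id: Optional[str] = None
    dewar_barcodes: list[str] = field(default_factory=list)
    state: str = "draft"  # draft -> submitted -> sent -> returned
    approved_acronyms: set[str] = field(default_factory=set)
    submission_receipt: Optional[dict] = None
    # snapshot of pins at submission time, for return bookkeeping
    pin_ids: list[str] = field(default_factory=list)
    processed_pin_ids: list[str] = field(default_factory=list)
    collection_records: dict[str, CollectionRecord] = field(default_factory=dict)
    notes: list = field(default_factory=list)
    files: list = field(default_factory=list)


def _iter_tree(store, shipment: Shipment):
    """Yield (dewar, puck, position, pin) over the shipment's container
    tree, in deterministic (dewar, puck, position) order."""
    for dewar_barcode in shipment.dewar_barcodes:
        dewar = store.dewars[dewar_barcode]
        for puck_barcode in dewar.puck_barcodes:
            puck = store.pucks[puck_barcode]
            for position in sorted(puck.slots):
                yield dewar, puck, position, store.pins[puck.slots[position]]


# ---------------------------------------------------------------------------
# assembly


def assemble_shipment(store, shipper: str, synchrotron: str,
                      dewar_barcodes: list[str],
                      approved_acronyms: set[str],
                      proposal_id: Optional[str] = None,
                      session_id: Optional[str] = None) -> Shipment:
    """Create a draft shipment from prepared dewars.

    Only users with the shipper flag may assemble; the dewars must be in
    the lab and not already committed to another shipment.  Dewars, pucks
    and pins can still be added or removed while the shipment is a draft.
    """
    user = store.users.get(shipper)
    if user is None or not user.is_shipper:
        raise PermissionDenied(f"user {shipper!r} is not a shipper")
    shipment = Shipment(id=store.new_id("shp"), shipper=shipper,
                        synchrotron=synchrotron, proposal_id=proposal_id,
                        session_id=session_id,
                        approved_acronyms=set(approved_acronyms))
    for barcode in dewar_barcodes:
        _attach_dewar(store, shipment, barcode)
    store.shipments[shipment.id] = shipment
    return shipment


def _attach_dewar(store, shipment: Shipment, barcode: str) -> None:
    dewar = store.dewars.get(barcode)
    if dewar is None:
        raise NotFoundError(f"unknown dewar {barcode!r}")
    if dewar.state != "in_lab" or dewar.shipment_id is not None:
        raise ConflictError(
            f"dewar {barcode!r} is {dewar.state} (shipment {dewar.shipment_id!r})"
        )
    dewar.state = "in_shipment"
    dewar.shipment_id = shipment.id
    shipment.dewar_barcodes.append(barcode)


def add_dewar(store, shipment: Shipment, barcode: str) -> None:
    if shipment.state != "draft":
        raise StateError("dewars can only be added while the shipment is a draft")
    _attach_dewar(store, shipment, barcode)


def remove_dewar(store, shipment: Shipment, barcode: str) -> None:
    if shipment.state != "draft":
        raise StateError("dewars can only be removed while the shipment is a draft")
    if barcode not in shipment.dewar_barcodes:
        raise NotFoundError(f"dewar {barcode!r} is not in this shipment")
    shipment.dewar_barcodes.remove(barcode)
    dewar = store.dewars[barcode]
    dewar.state = "in_lab"
    dewar.shipment_id = None


# ---------------------------------------------------------------------------
# validation


def validate_shipment(store, shipment: Shipment) -> ValidationReport:
    """Pre-upload validation of the shipment's own data.

    Flags empty containers at every level, crystals without a protein
    acronym, acronyms missing from the shipment's approved list, and sample
    names over the hard length limit.  The report carries every violation;
    it never raises.
    """
    report = ValidationReport()

    def flag(code: str, subject: str, message: str) -> None:
        report.violations.append(Violation(code, subject, message))

    for dewar_barcode in shipment.dewar_barcodes:
        dewar = store.dewars[dewar_barcode]
        if not dewar.puck_barcodes:
            flag("EMPTY_DEWAR", f"dewar:{dewar_barcode}",
                 f"dewar {dewar_barcode} contains no pucks")
        for puck_barcode in dewar.puck_barcodes:
            puck = store.pucks[puck_barcode]
            if not puck.slots:
                flag("EMPTY_PUCK", f"puck:{puck_barcode}",
                     f"puck {puck_barcode} contains no pins")
            for position in sorted(puck.slots):
                pin = store.pins[puck.slots[position]]
                subject = f"pin:{puck_barcode}/{position}"
                if pin.crystal_name is None:
                    flag("EMPTY_PIN", subject,
                         f"pin at {puck_barcode}/{position} carries no crystal")
                    continue
                crystal = store.crystals.get(pin.crystal_name)
                if crystal is None:
                    flag("EMPTY_PIN", subject,
                         f"pin at {puck_barcode}/{position} references an "
                         f"unknown crystal")
                    continue
                acronym = crystal.sample_name.acronym
                if not acronym:
                    flag("MISSING_ACRONYM", subject,
                         f"crystal {crystal.core_name} has no protein acronym")
                elif acronym not in shipment.approved_acronyms:
                    flag("UNAPPROVED_ACRONYM", subject,
                         f"acronym {acronym!r} is not on the approved list")
                rendered = crystal.sample_name.rendered
                if len(rendered) > naming.HARD_LIMIT:
                    flag("NAME_TOO_LONG", subject,
                         f"sample name {rendered!r} exceeds "
                         f"{naming.HARD_LIMIT} characters")
    return report


# ---------------------------------------------------------------------------
# payload, submission, manifest


def build_ispyb_payload(store, shipment: Shipment) -> dict:
    """Build the hierarchical sample payload for the synchrotron.

    Deterministic ordering (dewar, puck, position); each sample carries the
    crystal's name, acronym, position and whatever pre-information (space
    group, cell, resolutions) has been provided by submission time.
    """
    payload = {
        "shipment_id": shipment.id,
        "shipper": shipment.shipper,
        "synchrotron": shipment.synchrotron,
        "proposal": shipment.proposal_id,
        "session": shipment.session_id,
        "dewars": [],
    }
    for dewar_barcode in shipment.dewar_barcodes:
        dewar = store.dewars[dewar_barcode]
        dewar_entry = {"barcode": dewar_barcode, "containers": []}
        for puck_barcode in dewar.puck_barcodes:
            puck = store.pucks[puck_barcode]
            container = {
                "barcode": puck_barcode,
                "capacity": puck.capacity,
                "samples": [],
            }
            for position in sorted(puck.slots):
                pin = store.pins[puck.slots[position]]
                crystal = store.crystals[pin.crystal_name]
                sample = {
                    "name": crystal.sample_name.rendered,
                    "acronym": crystal.sample_name.acronym,
                    "position": position,
                    "pin_barcode": pin.barcode,
                }
                info = crystal.ispyb_info
                for key in ("space_group", "cell", "known_resolution_a",
                            "desired_resolution_a"):
                    if info.get(key) is not None:
                        sample[key] = info[key]
                container["samples"].append(sample)
            dewar_entry["containers"].append(container)
        payload["dewars"].append(dewar_entry)
    return payload


def submit_shipment(store, shipment: Shipment, credentials: dict,
                    transport=None) -> dict:
    """Validate, POST the payload to the synchrotron, and mark submitted.

    Refused with the validation report if any rule is violated.  On
    endpoint failure the shipment stays a retryable draft.  On success
    every shipped crystal gains a shipment-history entry and its
    per-sample synchrotron link.
    """
    if shipment.state != "draft":
        raise StateError(f"shipment {shipment.id!r} is {shipment.state}, not draft")
    if not shipment.proposal_id or not shipment.session_id:
        raise ValidationError("select a proposal and session before submitting")
    report = validate_shipment(store, shipment)
    if not report.ok:
        raise ValidationError(
            "shipment failed pre-upload validation: "
            + "; ".join(v.message for v in report.violations)
        )
    payload = build_ispyb_payload(store, shipment)
    transport = transport or store.transport
    receipt = transport.submit(payload, credentials)  # may raise TransportError
    canonical = json.dumps(payload, sort_keys=True).encode()
    shipment.submission_receipt = {
        "payload_sha256": hashlib.sha256(canonical).hexdigest(),
        "submitted_at": datetime.now().isoformat(),
        **(receipt or {}),
    }
    shipment.state = "submitted"
    shipment.pin_ids = []
    for _, puck, position, pin in _iter_tree(store, shipment):
        shipment.pin_ids.append(pin.id)
        pin.state = "in_shipment"
        crystal = store.crystals[pin.crystal_name]
        link = store.config.ispyb_link_template.format(
            proposal=shipment.proposal_id, session=shipment.session_id,
            sample=crystal.sample_name.rendered,
        )
        crystal.shipment_history.append({
            "shipment_id": shipment.id,
            "synchrotron": shipment.synchrotron,
            "proposal_id": shipment.proposal_id,
            "session_id": shipment.session_id,
            "puck": puck.barcode,
            "position": position,
            "ispyb_link": link,
        })
        if link not in crystal.ispyb_links:
            crystal.ispyb_links.append(link)
    return shipment.submission_receipt


def render_manifest(store, shipment: Shipment) -> list[dict]:
    """The shipment manifest: one row per mounted crystal, in container
    order, each with links (and identical QR payload strings) to the local
    crystal page and to the synchrotron's per-sample page.  The printed
    form leaves a margin for freehand notes; here the rows are the data."""
    if shipment.state == "draft":
        raise StateError("the manifest is generated at submission")
    rows = []
    for dewar, puck, position, pin in _iter_tree(store, shipment):
        crystal = store.crystals[pin.crystal_name]
        icebear_link = store.config.icebear_link_template.format(
            sample=crystal.sample_name.rendered
        )
        ispyb_link = store.config.ispyb_link_template.format(
            proposal=shipment.proposal_id, session=shipment.session_id,
            sample=crystal.sample_name.rendered,
        )
        rows.append({
            "sample_name": crystal.sample_name.rendered,
            "acronym": crystal.sample_name.acronym,
            "pin_barcode": pin.barcode,
            "position": position,
            "puck": puck.barcode,
            "dewar": dewar.barcode,
            "icebear_link": icebear_link,
            "ispyb_link": ispyb_link,
            "qr_payloads": [icebear_link, ispyb_link],
        })
    return rows


def manifest_text(store, shipment: Shipment) -> str:
    """Plain-text rendering of the manifest for printing."""
    rows = render_manifest(store, shipment)
    lines = [
        f"Shipment {shipment.id} to {shipment.synchrotron} "
        f"(proposal {shipment.proposal_id}, session {shipment.session_id})",
        "",
    ]
    for row in rows:
        lines.append(
            f"{row['dewar']} / {row['puck']} / pos {row['position']:>2}  "
            f"{row['sample_name']}  [{row['acronym']}]"
        )
        lines.append(f"    icebear: {row['icebear_link']}")
        lines.append(f"    ispyb:   {row['ispyb_link']}")
        lines.append("    notes: " + "_" * 40)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# data collection and return


def mark_sent(store, shipment: Shipment) -> Shipment:
    """The dewar has physically left: lock the containers."""
    if shipment.state != "submitted":
        raise StateError(
            f"shipment {shipment.id!r} is {shipment.state}; submit it first"
        )
    shipment.state = "sent"
    for barcode in shipment.dewar_barcodes:
        store.dewars[barcode].state = "sent"
    return shipment


def record_collection(store, shipment: Shipment, puck_barcode: str,
                      position: int, collected: bool,
                      note: Optional[str] = None,
                      disposition: Optional[str] = None) -> CollectionRecord:
    """During the session: mark a position as collected, add a note, and
    record whether the crystal is to be kept or the pin washed on return."""
    if shipment.state != "sent":
        raise StateError("data collection is recorded once the shipment is sent")
    puck = store.pucks.get(puck_barcode)
    if puck is None or puck_barcode not in _shipment_pucks(store, shipment):
        raise NotFoundError(f"puck {puck_barcode!r} is not in this shipment")
    if position not in puck.slots:
        raise NotFoundError(f"no pin at {puck_barcode}/{position}")
    if disposition is not None and disposition not in ("keep_crystal", "wash_pin"):
        raise ValidationError(f"unknown disposition {disposition!r}")
    key = f"{puck_barcode}/{position}"
    record = shipment.collection_records.get(key)
    if record is None:
        record = CollectionRecord(shipment_id=shipment.id,
                                  puck_barcode=puck_barcode, position=position)
        shipment.collection_records[key] = record
    record.collected = collected
    if note:
        record.notes.append(note)
    if disposition is not None:
        record.disposition = disposition
    return record


def _shipment_pucks(store, shipment: Shipment) -> list[str]:
    out = []
    for dewar_barcode in shipment.dewar_barcodes:
        out.extend(store.dewars[dewar_barcode].puck_barcodes)
    return out


def puck_complete(store, shipment: Shipment, puck_barcode: str) -> bool:
    """True when every pin of the puck is marked as used (collected)."""
    puck = store.pucks[puck_barcode]
    return bool(puck.slots) and all(
        shipment.collection_records.get(f"{puck_barcode}/{pos}") is not None
        and shipment.collection_records[f"{puck_barcode}/{pos}"].collected
        for pos in puck.slots
    )


def mark_returned(store, shipment: Shipment) -> Shipment:
    """The dewar is back in the lab; unpacking can start."""
    if shipment.state != "sent":
        raise StateError(
            f"shipment {shipment.id!r} is {shipment.state}; mark it sent first"
        )
    shipment.state = "returned"
    for barcode in shipment.dewar_barcodes:
        store.dewars[barcode].state = "returned"
    return shipment


def process_return(store, shipment: Shipment, pin: Pin,
                   action: Optional[str] = None) -> dict:
    """Unpack one pin of a returned shipment.

    ``wash`` empties the pin (the crystal record survives with its full
    history) and makes it available again; ``keep`` leaves the crystal on
    the pin for the next synchrotron trip.  Without an explicit action the
    disposition recorded during data collection is used; if none was
    recorded, the pin is washed and the result carries a warning.  Once
    every pin is processed the pucks and dewars revert to the lab pool.
    """
    if shipment.state != "returned":
        raise StateError("mark the shipment returned before unpacking")
    if pin.id not in shipment.pin_ids:
        raise NotFoundError(f"pin {pin.id!r} is not part of this shipment")
    if pin.id in shipment.processed_pin_ids:
        raise StateError(f"pin {pin.id!r} has already been processed")
    puck = _puck_of(store, pin)
    warning = None
    if action is None:
        recorded = None
        if puck is not None:
            key = f"{puck.barcode}/{_slot_of(puck, pin.id)}"
            record = shipment.collection_records.get(key)
            recorded = record.disposition if record else None
        if recorded == "keep_crystal":
            action = "keep"
        elif recorded == "wash_pin":
            action = "wash"
        else:
            action = "wash"
            warning = (
                f"no disposition recorded for pin {pin.id!r}; defaulting to wash"
            )
    if action not in ("wash", "keep"):
        raise ValidationError(f"unknown return action {action!r}")
    if puck is not None:
        del puck.slots[_slot_of(puck, pin.id)]
    crystal = store.crystals.get(pin.crystal_name) if pin.crystal_name else None
    if action == "wash":
        pin.crystal_name = None
        if pin.dummy:
            # dummy pins have purely positional identity; washing retires them
            del store.pins[pin.id]
        else:
            pin.state = "available"
    else:
        pin.state = "returned_keep"
    shipment.processed_pin_ids.append(pin.id)
    if set(shipment.processed_pin_ids) >= set(shipment.pin_ids):
        for dewar_barcode in shipment.dewar_barcodes:
            dewar = store.dewars[dewar_barcode]
            dewar.puck_barcodes = []
            dewar.state = "in_lab"
            dewar.shipment_id = None
    return {"pin": pin.id, "action": action, "warning": warning,
            "crystal": crystal.core_name if crystal else None}
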