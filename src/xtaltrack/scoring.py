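"""Drop scoring, time-lapse viewing and crystal selection.

Scoring assigns each drop a class from an ordered, configurable vocabulary
(clear < precipitate < ... < single crystal); the full score history is
kept and the plate caches its best (maximum-ordinal) score.  Where the
imager provided a scale, a longest-dimension measurement in µm can be
stored with the score.

Selecting a crystal marks it for onward processing: the k-th crystal
selected (or fished) from a drop becomes crystal number k, its sample name
is generated from the plate's protein acronym, and a crystal record is
created which later accumulates ISPyB pre-information, notes, files,
container history, shipment history and PDB codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

from . import naming
from .errors import NotFoundError, PermissionDenied, ValidationError
from .imaging import DropImage, Plate, drop_key


@dataclass
class Score:
    plate_barcode: str
    well: str
    subposition: int
    class_id: int
    user: str
    timestamp: datetime
    measurement_um: Optional[float] = None

    @property
    def color(self) -> str:
        from .config import DEFAULT_SCORE_COLORS
        if 0 <= self.class_id < len(DEFAULT_SCORE_COLORS):
            return DEFAULT_SCORE_COLORS[self.class_id]
        return "#000000"


@dataclass
class Note:
    parent: str  # entity reference, e.g. "crystal:LMTIM_9098A07d1c1"
    author: str
    timestamp: datetime
    text: str


@dataclass
class FileAttachment:
    parent: str
    author: str
    timestamp: datetime
    path: str
    media_type: str = "application/octet-stream"


@dataclass
class Crystal:
    """A selected crystal, keyed by its core sample name."""

    sample_name: naming.SampleName
    plate_barcode: str
    well: str
    subposition: int
    selected_by: str
    selected_at: datetime
    # pre-information for the synchrotron sample database; snapshotted into
    # the shipment payload at submission time
    ispyb_info: dict = field(default_factory=dict)
    notes: list[Note] = field(default_factory=list)
    files: list[FileAttachment] = field(default_factory=list)
    pdb_codes: list[str] = field(default_factory=list)
    pin_history: list[str] = field(default_factory=list)  # pin ids over time
    shipment_history: list[dict] = field(default_factory=list)
    ispyb_links: list[str] = field(default_factory=list)
    tombstoned: bool = False

    @property
    def core_name(self) -> str:
        return self.sample_name.core


ISPYB_FIELDS = {
    "space_group",
    "cell",  # (a, b, c, alpha, beta, gamma)
    "known_resolution_a",
    "desired_resolution_a",
}


def _require_plate_write(store, plate: Plate, caller: str) -> None:
    from .domain import can_write
    user = store.users.get(caller)
    if user is not None and (user.is_admin or caller == plate.owner):
        return
    if plate.project_id is not None and can_write(store, caller, plate.project_id):
        return
    raise PermissionDenied(
        f"user {caller!r} has no write access to plate {plate.barcode!r}"
    )


def score_drop(store, plate: Plate, well: str, subposition: int, class_id: int,
               caller: str, measurement_um: Optional[float] = None,
               now: Optional[datetime] = None) -> Score:
    """Score a drop; appends to the drop's score history.

    A measurement may only accompany the score when the drop's latest image
    carries scale information from the imager.
    """
    _require_plate_write(store, plate, caller)
    if not plate.valid_drop(well, subposition):
        raise ValidationError(
            f"drop {well}/{subposition} outside plate {plate.barcode!r}"
        )
    vocab = store.config.score_classes
    if not (0 <= class_id < len(vocab)):
        raise ValidationError(
            f"score class {class_id} outside vocabulary of {len(vocab)} classes"
        )
    if measurement_um is not None:
        image = plate.latest_image(well, subposition)
        if image is None or image.dummy or image.scale_um_per_px is None:
            raise ValidationError(
                "measurement requires an image with scale information"
            )
        if measurement_um <= 0:
            raise ValidationError("measurement must be positive")
    score = Score(plate_barcode=plate.barcode, well=well,
                  subposition=subposition, class_id=class_id, user=caller,
                  timestamp=now or datetime.now(),
                  measurement_um=measurement_um)
    plate.scores.setdefault(drop_key(well, subposition), []).append(score)
    if plate.best_score is None or class_id > plate.best_score:
        plate.best_score = class_id
    return score


def drop_timeline(plate: Plate, well: str, subposition: int,
                  mode: Optional[str] = None) -> list[DropImage]:
    """Images of one drop across inspections, ascending by time; optionally
    filtered to visible or UV inspections."""
    key = drop_key(well, subposition)
    images = [
        insp.images[key]
        for insp in plate.inspections
        if key in insp.images and (mode is None or insp.mode == mode)
    ]
    return images


def select_crystal(store, plate: Plate, well: str, subposition: int,
                   caller: str, extension: Optional[str] = None,
                   now: Optional[datetime] = None) -> Crystal:
    """Mark a crystal in a drop for onward processing.

    Requires the plate to be assigned to a protein so the acronym is known.
    The crystal number is one more than the number of crystals already
    selected in this drop; numbers are never reused, even for tombstoned
    crystals.
    """
    _require_plate_write(store, plate, caller)
    if not plate.valid_drop(well, subposition):
        raise ValidationError(
            f"drop {well}/{subposition} outside plate {plate.barcode!r}"
        )
    if plate.protein_id is None:
        raise ValidationError(
            f"plate {plate.barcode!r} is not assigned to a protein; "
            "assign the plate to a project and protein first"
        )
    acronym = store.proteins[plate.protein_id].acronym
    existing = [
        c for c in store.crystals.values()
        if c.plate_barcode == plate.barcode
        and c.well == well and c.subposition == subposition
    ]
    crystal_number = len(existing) + 1
    name = naming.generate_sample_name(
        acronym, plate.barcode, well, subposition, crystal_number,
        extension=extension, registry=store.name_registry,
    )
    crystal = Crystal(
        sample_name=name, plate_barcode=plate.barcode, well=well,
        subposition=subposition, selected_by=caller,
        selected_at=now or datetime.now(),
    )
    store.crystals[name.core] = crystal
    store.index.add_crystal(crystal)
    return crystal


def extend_crystal_name(store, crystal: Crystal, extension: str,
                        caller: str) -> Crystal:
    """Attach a user extension (e.g. a ligand name) to an issued name; the
    core name and uniqueness key are unchanged."""
    plate = store.plates[crystal.plate_barcode]
    _require_plate_write(store, plate, caller)
    crystal.sample_name = naming.extend_sample_name(crystal.sample_name, extension)
    store.index.update_crystal(crystal)
    return crystal


def set_ispyb_info(store, crystal: Crystal, caller: str, **fields) -> Crystal:
    """Update the crystal's synchrotron pre-information (space group, cell,
    known/desired resolution).  Partial updates allowed; values are carried
    into shipment payloads at submission time."""
    plate = store.plates[crystal.plate_barcode]
    _require_plate_write(store, plate, caller)
    unknown = set(fields) - ISPYB_FIELDS
    if unknown:
        raise ValidationError(f"unknown ISPyB fields: {sorted(unknown)}")
    if "cell" in fields and fields["cell"] is not None:
        cell = tuple(fields["cell"])
        if len(cell) != 6 or any(v <= 0 for v in cell):
            raise ValidationError(
                "cell must be six positive numbers (a, b, c, alpha, beta, gamma)"
            )
        fields["cell"] = list(cell)
    for key in ("known_resolution_a", "desired_resolution_a"):
        if fields.get(key) is not None and fields[key] <= 0:
            raise ValidationError(f"{key} must be positive")
    crystal.ispyb_info.update(fields)
    return crystal


def _resolve_parent(store, parent: str):
    """Resolve an entity reference like ``crystal:NAME`` or ``plate:BARCODE``."""
    kind, _, key = parent.partition(":")
    if kind == "crystal" and key in store.crystals:
        return store.crystals[key]
    if kind == "plate" and key in store.plates:
        return store.plates[key]
    if kind == "shipment" and key.split("/")[0] in store.shipments:
        return store.shipments[key.split("/")[0]]
    raise NotFoundError(f"unknown note/file parent {parent!r}")


def _check_parent_write(store, parent_obj, caller: str) -> None:
    if isinstance(parent_obj, Plate):
        _require_plate_write(store, parent_obj, caller)
    elif isinstance(parent_obj, Crystal):
        _require_plate_write(store, store.plates[parent_obj.plate_barcode], caller)
    # shipments: any authenticated user with samples may annotate; kept open


def add_note(store, parent: str, text: str, caller: str,
             now: Optional[datetime] = None) -> Note:
    """Append an immutable note to a plate, crystal or shipment position."""
    obj = _resolve_parent(store, parent)
    _check_parent_write(store, obj, caller)
    note = Note(parent=parent, author=caller, timestamp=now or datetime.now(),
                text=text)
    obj.notes.append(note)
    return note


def add_file(store, parent: str, path: str, caller: str,
             media_type: str = "application/octet-stream",
             now: Optional[datetime] = None) -> FileAttachment:
    """Attach a file (diffraction image, processing log, scanned notes...)
    to a plate or crystal."""
    obj = _resolve_parent(store, parent)
    _check_parent_write(store, obj, caller)
    attachment = FileAttachment(parent=parent, author=caller,
                                timestamp=now or datetime.now(), path=path,
                                media_type=media_type)
    obj.files.append(attachment)
    return attachment


def recent_notes(store, author: str, limit: int = 10) -> list[str]:
    """Most recent note texts by an author, for one-touch reuse while
    fishing."""
    texts: list[str] = []
    for container in list(store.crystals.values()) + list(store.plates.values()):
        for note in container.notes:
            if note.author == author:
                texts.append((note.timestamp, note.text))
    texts.sort(key=lambda t: t[0], reverse=True)
    out = []
    for _, text in texts:
        if text not in out:
            out.append(text)
        if len(out) >= limit:
            break
    return out
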