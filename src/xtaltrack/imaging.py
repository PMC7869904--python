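"""Plate registration and inspection import from an imaging system.

Imaging systems export inspections to a drop directory ("inbox"); this
module ingests them.  The contract is one sub-directory per inspection
containing

* ``inspection.txt`` — a flat ``key: value`` sidecar with at least the
  plate barcode, the inspection timestamp (ISO 8601) and the imaging mode
  (``visible`` or ``uv``); optionally the owner username, temperature and
  plate geometry, and
* one image file per imaged drop, named ``<well><subposition>.<ext>``
  (e.g. ``A071.png`` for well A07, drop 1).

New inspections are only picked up once they are older than the configured
import delay (default 300 s, measured against the sidecar timestamp), so
an imager still writing files is never half-imported.  Unknown barcodes
register a new plate and open an "assign plate" task for its owner;
malformed sidecars are quarantined with a reason rather than aborting the
scan.  Re-scanning the same inbox is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

from .errors import ConflictError, NotFoundError, PermissionDenied, ValidationError
from .screens import PlateSetup

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
SIDECAR_NAME = "inspection.txt"
MANDATORY_SIDECAR_FIELDS = ("barcode", "timestamp", "mode")


def drop_key(well: str, subposition: int) -> str:
    return f"{well}/{subposition}"


@dataclass
class DropImage:
    path: str
    scale_um_per_px: Optional[float] = None
    dummy: bool = False
    mode: str = "visible"


@dataclass
class Inspection:
    plate_barcode: str
    timestamp: datetime
    mode: str  # "visible" | "uv"
    images: dict[str, DropImage] = field(default_factory=dict)  # drop_key -> image


@dataclass
class Task:
    id: str
    user: str
    kind: str  # "assign_plate" | "remove_expired_plate" | "complete_metadata"
    subject: str  # entity reference (plate barcode, ...)
    created: datetime
    open: bool = True


@dataclass
class Plate:
    barcode: str
    rows: int = 8
    cols: int = 12
    drops_per_well: int = 3
    temperature_c: Optional[float] = None
    owner: str = ""
    project_id: Optional[str] = None
    protein_id: Optional[str] = None
    construct_id: Optional[str] = None
    setup: PlateSetup = field(default_factory=PlateSetup)
    inspections: list[Inspection] = field(default_factory=list)
    expired: bool = False
    # drop_key -> full score history (append-only); best_score is a cache of
    # the maximum score ordinal over all drops
    scores: dict[str, list] = field(default_factory=dict)
    best_score: Optional[int] = None
    notes: list = field(default_factory=list)
    files: list = field(default_factory=list)

    def valid_drop(self, well: str, subposition: int) -> bool:
        from .naming import parse_well_label
        try:
            parse_well_label(well, self.rows, self.cols)
        except Exception:
            return False
        return 1 <= subposition <= self.drops_per_well

    def latest_image(self, well: str, subposition: int) -> Optional[DropImage]:
        key = drop_key(well, subposition)
        for insp in reversed(self.inspections):
            if key in insp.images:
                return insp.images[key]
        return None


# ---------------------------------------------------------------------------
# sidecar handling


def parse_sidecar(text: str) -> dict:
    """Parse a flat ``key: value`` sidecar file into a dict."""
    data = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition(":")
        if sep:
            data[key.strip().lower()] = value.strip()
    return data


def write_sidecar(data: dict) -> str:
    return "".join(f"{k}: {v}\n" for k, v in data.items())


# ---------------------------------------------------------------------------
# operations


def register_plate_from_imager(store, sidecar: dict) -> Plate:
    """Create a plate from imager-provided metadata and open an
    "assign plate" task for its owner.

    If the owner hint is missing or unknown, the plate is kept (assigned to
    the configured fallback user) and the task goes to that user instead —
    data is never dropped because of a bad hint.
    """
    barcode = sidecar["barcode"]
    if barcode in store.plates:
        raise ConflictError(f"plate {barcode!r} already registered")
    owner = sidecar.get("owner", "")
    if owner not in store.users:
        owner = store.config.fallback_user
        store.ensure_user(owner)
    plate = Plate(
        barcode=barcode,
        rows=int(sidecar.get("rows", store.config.default_rows)),
        cols=int(sidecar.get("cols", store.config.default_cols)),
        drops_per_well=int(
            sidecar.get("drops_per_well", store.config.default_drops_per_well)
        ),
        temperature_c=(
            float(sidecar["temperature"]) if "temperature" in sidecar else None
        ),
        owner=owner,
    )
    if plate.drops_per_well not in (1, 3):
        raise ValidationError("plates have one drop or three drops per well")
    store.plates[barcode] = plate
    store.index.add_barcode("plate", barcode)
    store.open_task(owner, "assign_plate", barcode)
    return plate


def scan_inbox(store, directory, now: Optional[datetime] = None) -> list[Inspection]:
    """Scan an imager inbox directory and import mature inspections.

    Returns the list of newly imported inspections.  Inspections younger
    than ``config.import_delay_s`` (sidecar timestamp vs ``now``) are left
    for a later scan; sidecars missing mandatory fields are quarantined.
    """
    now = now or datetime.now()
    directory = Path(directory)
    imported: list[Inspection] = []
    for sub in sorted(p for p in directory.iterdir() if p.is_dir()):
        sidecar_path = sub / SIDECAR_NAME
        if not sidecar_path.exists():
            store.quarantine.append(
                {"path": str(sub), "reason": f"missing {SIDECAR_NAME}"}
            )
            continue
        sidecar = parse_sidecar(sidecar_path.read_text())
        missing = [f for f in MANDATORY_SIDECAR_FIELDS if f not in sidecar]
        if missing:
            store.quarantine.append(
                {"path": str(sub), "reason": f"sidecar missing fields: {missing}"}
            )
            continue
        try:
            timestamp = datetime.fromisoformat(sidecar["timestamp"])
        except ValueError:
            store.quarantine.append(
                {"path": str(sub),
                 "reason": f"bad timestamp {sidecar['timestamp']!r}"}
            )
            continue
        if now - timestamp < timedelta(seconds=store.config.import_delay_s):
            continue  # not yet mature; picked up by a later scan
        barcode = sidecar["barcode"]
        if barcode not in store.plates:
            register_plate_from_imager(store, sidecar)
        plate = store.plates[barcode]
        mode = sidecar["mode"]
        if any(
            i.timestamp == timestamp and i.mode == mode for i in plate.inspections
        ):
            continue  # already imported: idempotent re-scan
        inspection = Inspection(plate_barcode=barcode, timestamp=timestamp, mode=mode)
        scale = (
            float(sidecar["scale_um_per_px"]) if "scale_um_per_px" in sidecar else None
        )
        for img in sorted(sub.iterdir()):
            if img.suffix.lower() not in IMAGE_EXTENSIONS:
                continue
            stem = img.stem  # <well><subposition>, e.g. A071
            well, sub_no = stem[:3], stem[3:]
            if not sub_no.isdigit() or not plate.valid_drop(well, int(sub_no)):
                store.quarantine.append(
                    {"path": str(img),
                     "reason": f"image name {img.name!r} outside plate geometry"}
                )
                continue
            inspection.images[drop_key(well, int(sub_no))] = DropImage(
                path=str(img), scale_um_per_px=scale, mode=mode
            )
        plate.inspections.append(inspection)
        plate.inspections.sort(key=lambda i: (i.timestamp, i.mode))
        if not plate.setup.complete:
            store.open_task(plate.owner, "complete_metadata", barcode)
        imported.append(inspection)
    return imported


def assign_plate(store, plate: Plate, project_id: str, protein_id: str,
                 construct_id: Optional[str], caller: str) -> Plate:
    """Link a plate to a project/protein/construct; closes the owner's
    "assign plate" task.  Sample names for crystals selected on this plate
    will use the protein's acronym."""
    if caller != plate.owner:
        raise PermissionDenied(
            f"only the plate owner may assign plate {plate.barcode!r}"
        )
    project = store.projects.get(project_id)
    if project is None:
        raise NotFoundError(f"unknown project {project_id!r}")
    protein = store.proteins.get(protein_id)
    if protein is None or protein.project_id != project_id:
        raise ValidationError(
            f"protein {protein_id!r} does not belong to project {project_id!r}"
        )
    if construct_id is not None:
        construct = store.constructs.get(construct_id)
        if construct is None or construct.protein_id != protein_id:
            raise ValidationError(
                f"construct {construct_id!r} does not belong to protein "
                f"{protein_id!r}"
            )
    plate.project_id = project_id
    plate.protein_id = protein_id
    plate.construct_id = construct_id
    store.close_tasks("assign_plate", plate.barcode)
    return plate


def mark_plate_expired(store, plate: Plate,
                       now: Optional[datetime] = None) -> Task:
    """Flag a plate for removal from the imager; opens (or returns the
    already open) "remove expired plate" task for its owner."""
    plate.expired = True
    return store.open_task(plate.owner, "remove_expired_plate", plate.barcode,
                           now=now)


def pending_tasks(store, user: str) -> list[Task]:
    return [t for t in store.tasks if t.open and t.user == user]
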