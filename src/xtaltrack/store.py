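"""The in-memory object store and its JSON persistence.

Everything the library tracks — users, projects, proteins, constructs,
plates, crystals, pins, pucks, dewars, screens, shipments, tasks — lives in
one :class:`LabStore`.  Cross-references are string ids or barcodes, so the
whole store serializes to a single JSON document; that is what the CLI
persists between invocations.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime
from pathlib import Path
from typing import Optional

from .bench import BenchSession, Dewar, Pin, Puck
from .config import Config
from .domain import Construct, Project, Protein, Sequence, User
from .imaging import DropImage, Inspection, Plate, Task
from .naming import NameRegistry, SampleName
from .screens import Component, Condition, PlateSetup, Screen
from .scoring import Crystal, FileAttachment, Note, Score
from .search import SearchIndex
from .shipping import CollectionRecord, Shipment


class LabStore:
    """Root container for all tracked entities."""

    def __init__(self, config: Optional[Config] = None) -> None:
        self.config = config or Config()
        self.users: dict[str, User] = {}
        self.projects: dict[str, Project] = {}
        self.proteins: dict[str, Protein] = {}
        self.constructs: dict[str, Construct] = {}
        self.plates: dict[str, Plate] = {}
        self.crystals: dict[str, Crystal] = {}  # keyed by core sample name
        self.pins: dict[str, Pin] = {}
        self.pucks: dict[str, Puck] = {}
        self.dewars: dict[str, Dewar] = {}
        self.screens: dict[str, Screen] = {}
        self.shipments: dict[str, Shipment] = {}
        self.tasks: list[Task] = []
        self.quarantine: list[dict] = []
        self.sessions: list[BenchSession] = []
        self.name_registry = NameRegistry()
        self.index = SearchIndex()
        self._counter = 0
        self._transport = None

    # -- identity -----------------------------------------------------------

    def new_id(self, prefix: str) -> str:
        self._counter += 1
        return f"{prefix}-{self._counter:04d}"

    @property
    def pins_by_barcode(self) -> dict[str, Pin]:
        return {p.barcode: p for p in self.pins.values() if p.barcode}

    # -- users / tasks ------------------------------------------------------

    def add_user(self, username: str, full_name: str = "",
                 is_admin: bool = False, is_shipper: bool = False) -> User:
        if username in self.users:
            raise ValueError(f"user {username!r} already exists")
        user = User(username=username, full_name=full_name,
                    is_admin=is_admin, is_shipper=is_shipper)
        self.users[username] = user
        return user

    def ensure_user(self, username: str) -> User:
        if username not in self.users:
            return self.add_user(username)
        return self.users[username]

    def open_task(self, user: str, kind: str, subject: str,
                  now: Optional[datetime] = None) -> Task:
        """Open a task, deduplicating on (kind, subject): at most one open
        task per pair."""
        for task in self.tasks:
            if task.open and task.kind == kind and task.subject == subject:
                return task
        task = Task(id=self.new_id("task"), user=user, kind=kind,
                    subject=subject, created=now or datetime.now())
        self.tasks.append(task)
        return task

    def close_tasks(self, kind: str, subject: str) -> int:
        closed = 0
        for task in self.tasks:
            if task.open and task.kind == kind and task.subject == subject:
                task.open = False
                closed += 1
        return closed

    # -- transport ----------------------------------------------------------

    @property
    def transport(self):
        if self._transport is None:
            from .mock_synchrotron import make_transport
            self._transport = make_transport(self.config.synchrotron_endpoint)
        return self._transport

    @transport.setter
    def transport(self, value) -> None:
        self._transport = value

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "counter": self._counter,
            "users": {k: _encode(v) for k, v in self.users.items()},
            "projects": {k: _encode(v) for k, v in self.projects.items()},
            "proteins": {k: _encode(v) for k, v in self.proteins.items()},
            "constructs": {k: _encode(v) for k, v in self.constructs.items()},
            "plates": {k: _encode(v) for k, v in self.plates.items()},
            "crystals": {k: _encode(v) for k, v in self.crystals.items()},
            "pins": {k: _encode(v) for k, v in self.pins.items()},
            "pucks": {k: _encode(v) for k, v in self.pucks.items()},
            "dewars": {k: _encode(v) for k, v in self.dewars.items()},
            "screens": {k: _encode(v) for k, v in self.screens.items()},
            "shipments": {k: _encode(v) for k, v in self.shipments.items()},
            "tasks": [_encode(t) for t in self.tasks],
            "quarantine": list(self.quarantine),
            "sessions": [_encode(s) for s in self.sessions],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LabStore":
        store = cls(config=Config.from_dict(data.get("config", {})))
        store._counter = data.get("counter", 0)
        store.users = {k: _decode_user(v) for k, v in data["users"].items()}
        store.projects = {
            k: Project(**v) for k, v in data["projects"].items()
        }
        store.proteins = {k: Protein(**v) for k, v in data["proteins"].items()}
        store.constructs = {
            k: Construct(**{**v, "sequences": [Sequence(**s) for s in v["sequences"]]})
            for k, v in data["constructs"].items()
        }
        store.plates = {k: _decode_plate(v) for k, v in data["plates"].items()}
        store.crystals = {k: _decode_crystal(v) for k, v in data["crystals"].items()}
        store.pins = {k: Pin(**v) for k, v in data["pins"].items()}
        store.pucks = {
            k: Puck(barcode=v["barcode"], capacity=v["capacity"],
                    slots={int(p): pid for p, pid in v["slots"].items()})
            for k, v in data["pucks"].items()
        }
        store.dewars = {k: Dewar(**v) for k, v in data["dewars"].items()}
        store.screens = {k: _decode_screen(v) for k, v in data["screens"].items()}
        store.shipments = {
            k: _decode_shipment(v) for k, v in data["shipments"].items()
        }
        store.tasks = [
            Task(**{**t, "created": datetime.fromisoformat(t["created"])})
            for t in data.get("tasks", [])
        ]
        store.quarantine = list(data.get("quarantine", []))
        store.sessions = [BenchSession(**s) for s in data.get("sessions", [])]
        for core in store.crystals:
            store.name_registry.register(core)
        store.index = store.index.rebuild(store)
        return store

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "LabStore":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# encoding helpers: dataclasses -> JSON-safe dicts and back


def _encode(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _encode(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, datetime):
        return obj.isoformat()
    if isinstance(obj, dict):
        return {str(k): _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, set):
        return sorted(obj)
    return obj


def _decode_user(v: dict) -> User:
    return User(**v)


def _decode_plate(v: dict) -> Plate:
    v = dict(v)
    v["setup"] = PlateSetup(**v["setup"])
    v["inspections"] = [
        Inspection(
            plate_barcode=i["plate_barcode"],
            timestamp=datetime.fromisoformat(i["timestamp"]),
            mode=i["mode"],
            images={k: DropImage(**img) for k, img in i["images"].items()},
        )
        for i in v["inspections"]
    ]
    v["scores"] = {
        k: [
            Score(**{**s, "timestamp": datetime.fromisoformat(s["timestamp"])})
            for s in scores
        ]
        for k, scores in v["scores"].items()
    }
    v["notes"] = [_decode_note(n) for n in v["notes"]]
    v["files"] = [_decode_file(f) for f in v["files"]]
    return Plate(**v)


def _decode_note(n: dict) -> Note:
    return Note(**{**n, "timestamp": datetime.fromisoformat(n["timestamp"])})


def _decode_file(f: dict) -> FileAttachment:
    return FileAttachment(
        **{**f, "timestamp": datetime.fromisoformat(f["timestamp"])}
    )


def _decode_crystal(v: dict) -> Crystal:
    v = dict(v)
    v["sample_name"] = SampleName(**v["sample_name"])
    v["selected_at"] = datetime.fromisoformat(v["selected_at"])
    v["notes"] = [_decode_note(n) for n in v["notes"]]
    v["files"] = [_decode_file(f) for f in v["files"]]
    return Crystal(**v)


def _decode_screen(v: dict) -> Screen:
    return Screen(
        name=v["name"],
        conditions={
            well: Condition(
                well_label=c["well_label"],
                description=c["description"],
                components=[Component(**comp) for comp in c["components"]],
            )
            for well, c in v["conditions"].items()
        },
    )


def _decode_shipment(v: dict) -> Shipment:
    v = dict(v)
    v["approved_acronyms"] = set(v["approved_acronyms"])
    v["collection_records"] = {
        k: CollectionRecord(**r) for k, r in v["collection_records"].items()
    }
    v["notes"] = [_decode_note(n) for n in v["notes"]]
    v["files"] = [_decode_file(f) for f in v["files"]]
    return Shipment(**v)
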