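"""Crystallization screen files and plate-level crystallization metadata.

A *screen* is a set of up to 96 crystallization conditions keyed by well
label.  Screens arrive in several formats: simple two-column text files
(well, condition), CSV with a defined header, and an XML dialect in which
each condition lists its chemical ingredients.  All parsers normalize well
labels (``A1`` -> ``A01``) and produce the same in-memory ``Screen``.

Plate metadata (which screen, protein buffer and concentration, drop
volumes, temperature) is provided by the plate owner; a plate is *complete*
once both the screen and the protein buffer are known, and incomplete
plates surface as pending tasks.
"""

from __future__ import annotations

import csv
import io
import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    ConflictError,
    ParseError,
    PermissionDenied,
    UnsupportedFormatError,
    ValidationError,
)

_WELL_LOOSE_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")


@dataclass(frozen=True)
class Component:
    """One chemical ingredient of a condition."""

    name: str
    concentration: Optional[float] = None
    unit: Optional[str] = None
    ph: Optional[float] = None

    def describe(self) -> str:
        parts = []
        if self.concentration is not None:
            conc = f"{self.concentration:g}"
            parts.append(f"{conc} {self.unit}" if self.unit else conc)
        parts.append(self.name)
        text = " ".join(parts)
        if self.ph is not None:
            text += f" pH {self.ph:g}"
        return text


@dataclass
class Condition:
    well_label: str
    description: str
    components: list[Component] = field(default_factory=list)


@dataclass
class Screen:
    name: str
    conditions: dict[str, Condition] = field(default_factory=dict)

    @property
    def well_count(self) -> int:
        return len(self.conditions)


@dataclass
class PlateSetup:
    """Owner-provided crystallization metadata for one plate."""

    screen_name: Optional[str] = None
    protein_buffer: Optional[str] = None
    protein_concentration: Optional[str] = None  # value + unit, free form
    drop_volumes: dict[str, str] = field(default_factory=dict)  # subposition -> volume
    temperature_c: Optional[float] = None
    description: Optional[str] = None

    @property
    def complete(self) -> bool:
        """True once screen and protein buffer are both provided."""
        return bool(self.screen_name) and bool(self.protein_buffer)


def normalize_well_label(label: str, rows: int = 8, cols: int = 12) -> str:
    """Normalize ``A1``/``a1``/``A01`` to ``A01``; reject labels outside the
    plate geometry.  Idempotent."""
    m = _WELL_LOOSE_RE.match(label.strip())
    if m is None:
        raise ParseError(f"invalid well label {label!r}")
    row = ord(m.group(1).upper()) - ord("A")
    col = int(m.group(2))
    if row >= rows or not (1 <= col <= cols):
        raise ParseError(f"well {label!r} outside {rows}x{cols} plate")
    return f"{chr(ord('A') + row)}{col:02d}"


# ---------------------------------------------------------------------------
# parsers


def parse_screen_two_column(text: str, name: str = "imported") -> Screen:
    """Parse a simple two-column screen file.

    Each non-empty line is a well label and a condition description
    separated by a tab or the first comma.  Lines starting with ``#`` are
    comments; a ``# screen: NAME`` comment sets the screen name.
    """
    screen = Screen(name=name)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*screen:\s*(.+)$", line)
            if m:
                screen.name = m.group(1).strip()
            continue
        if "\t" in line:
            well_part, cond_part = line.split("\t", 1)
        elif "," in line:
            well_part, cond_part = line.split(",", 1)
        else:
            raise ParseError(f"line {lineno}: no tab or comma delimiter")
        try:
            well = normalize_well_label(well_part)
        except ParseError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        cond = cond_part.strip()
        if not cond:
            raise ParseError(f"line {lineno}: empty condition for well {well}")
        if well in screen.conditions:
            raise ConflictError(f"line {lineno}: duplicate well {well}")
        screen.conditions[well] = Condition(well_label=well, description=cond)
    return screen


def write_screen_two_column(screen: Screen) -> str:
    lines = [f"# screen: {screen.name}"]
    for well in sorted(screen.conditions):
        lines.append(f"{well}\t{screen.conditions[well].description}")
    return "\n".join(lines) + "\n"


CSV_FIELDS = ["Well", "Condition", "Components"]


def parse_screen_csv(text: str, name: str = "imported") -> Screen:
    """Parse the CSV dialect: header with at least Well and Condition
    columns (case-insensitive); an optional Components column carries a
    JSON-encoded ingredient list for lossless round trips."""
    lines = text.splitlines()
    body = []
    screen_name = name
    for line in lines:
        m = re.match(r"#\s*screen:\s*(.+)$", line.strip())
        if m:
            screen_name = m.group(1).strip()
        elif line.strip():
            body.append(line)
    reader = csv.DictReader(io.StringIO("\n".join(body)))
    if reader.fieldnames is None:
        raise ParseError("empty CSV input")
    field_map = {f.lower(): f for f in reader.fieldnames}
    if "well" not in field_map or "condition" not in field_map:
        raise ParseError(
            f"CSV header must contain Well and Condition columns, "
            f"got {reader.fieldnames}"
        )
    screen = Screen(name=screen_name)
    for lineno, row in enumerate(reader, start=2):
        well = normalize_well_label(row[field_map["well"]])
        if well in screen.conditions:
            raise ConflictError(f"row {lineno}: duplicate well {well}")
        components = []
        comp_field = field_map.get("components")
        if comp_field and row.get(comp_field):
            try:
                components = [Component(**c) for c in json.loads(row[comp_field])]
            except (json.JSONDecodeError, TypeError) as exc:
                raise ParseError(f"row {lineno}: bad Components cell: {exc}")
        description = (row[field_map["condition"]] or "").strip()
        if not description:
            raise ParseError(f"row {lineno}: empty condition for well {well}")
        screen.conditions[well] = Condition(
            well_label=well, description=description, components=components
        )
    return screen


def write_screen_csv(screen: Screen) -> str:
    buf = io.StringIO()
    buf.write(f"# screen: {screen.name}\n")
    writer = csv.DictWriter(buf, fieldnames=CSV_FIELDS, lineterminator="\n")
    writer.writeheader()
    for well in sorted(screen.conditions):
        cond = screen.conditions[well]
        comp_cell = ""
        if cond.components:
            comp_cell = json.dumps(
                [
                    {k: v for k, v in vars(c).items() if v is not None}
                    for c in cond.components
                ]
            )
        writer.writerow(
            {"Well": well, "Condition": cond.description, "Components": comp_cell}
        )
    return buf.getvalue()


def parse_screen_xml(text: str, name: str = "imported") -> Screen:
    """Parse the XML screen dialect.

    Expected subset::

        <screen name="...">
          <condition well="A1">
            <ingredient name="HEPES" concentration="0.1" unit="M" ph="7.5"/>
            ...
          </condition>
        </screen>

    Unknown elements and attributes are ignored.  The condition description
    is synthesized from the ingredients unless a ``description`` attribute
    is given.
    """
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    if root.tag != "screen":
        raise ParseError(f"unknown root element {root.tag!r}; expected <screen>")
    screen = Screen(name=root.attrib.get("name", name))
    for cond_el in root.iter("condition"):
        well_attr = cond_el.attrib.get("well")
        if well_attr is None:
            raise ParseError("<condition> element without well attribute")
        well = normalize_well_label(well_attr)
        if well in screen.conditions:
            raise ConflictError(f"duplicate well {well} in XML screen")
        components = []
        for ing in cond_el.iter("ingredient"):
            components.append(
                Component(
                    name=ing.attrib.get("name", ""),
                    concentration=_opt_float(ing.attrib.get("concentration")),
                    unit=ing.attrib.get("unit"),
                    ph=_opt_float(ing.attrib.get("ph")),
                )
            )
        description = cond_el.attrib.get("description") or ", ".join(
            c.describe() for c in components
        )
        if not description:
            raise ParseError(f"condition {well}: no description or ingredients")
        screen.conditions[well] = Condition(
            well_label=well, description=description, components=components
        )
    return screen


def write_screen_xml(screen: Screen) -> str:
    root = ET.Element("screen", name=screen.name)
    for well in sorted(screen.conditions):
        cond = screen.conditions[well]
        cond_el = ET.SubElement(root, "condition", well=well,
                                description=cond.description)
        for comp in cond.components:
            attrs = {"name": comp.name}
            if comp.concentration is not None:
                attrs["concentration"] = f"{comp.concentration:g}"
            if comp.unit is not None:
                attrs["unit"] = comp.unit
            if comp.ph is not None:
                attrs["ph"] = f"{comp.ph:g}"
            ET.SubElement(cond_el, "ingredient", **attrs)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


def parse_screen_mimer(text: str, name: str = "imported") -> Screen:
    """MIMER screen descriptions are not supported; the format is defined
    externally and this reader deliberately refuses rather than guess."""
    raise UnsupportedFormatError("MIMER screen format is not supported")


def parse_screen(text: str, fmt: str = "auto", name: str = "imported") -> Screen:
    """Parse a screen, sniffing the format when ``fmt='auto'``."""
    if fmt == "auto":
        stripped = text.lstrip()
        if stripped.startswith("<"):
            fmt = "xml"
        else:
            first_data = next(
                (l for l in text.splitlines() if l.strip() and not l.startswith("#")),
                "",
            )
            fmt = "csv" if "well" in first_data.lower().split(",")[0].lower() else "txt"
    if fmt == "txt":
        return parse_screen_two_column(text, name)
    if fmt == "csv":
        return parse_screen_csv(text, name)
    if fmt == "xml":
        return parse_screen_xml(text, name)
    if fmt == "mimer":
        return parse_screen_mimer(text, name)
    raise ValidationError(f"unknown screen format {fmt!r}")


def _opt_float(value: Optional[str]) -> Optional[float]:
    return None if value in (None, "") else float(value)


# ---------------------------------------------------------------------------
# plate metadata


def set_plate_metadata(store, plate, caller: str, **fields) -> PlateSetup:
    """Partially update a plate's crystallization metadata.

    Allowed callers: the plate owner, the owner of the plate's project, or
    an admin.  The completeness flag is recomputed after every update; an
    open ``complete_metadata`` task for this plate is closed once the setup
    becomes complete.
    """
    caller_user = store.users.get(caller)
    allowed = caller_user is not None and (
        caller_user.is_admin
        or caller == plate.owner
        or (
            plate.project_id is not None
            and store.projects[plate.project_id].owner == caller
        )
    )
    if not allowed:
        raise PermissionDenied(
            f"user {caller!r} may not edit metadata of plate {plate.barcode!r}"
        )
    valid = {f for f in PlateSetup.__dataclass_fields__}
    unknown = set(fields) - valid
    if unknown:
        raise ValidationError(f"unknown plate metadata fields: {sorted(unknown)}")
    for key, value in fields.items():
        setattr(plate.setup, key, value)
    if plate.setup.complete:
        store.close_tasks("complete_metadata", plate.barcode)
    return plate.setup
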