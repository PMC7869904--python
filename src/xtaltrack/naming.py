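"""Crystal sample names and well labels.

Every selected crystal receives a globally unique sample name built from
the protein acronym, the plate barcode, the well label, the drop
(subposition) number and the crystal number within that drop:

    <ACRONYM>_<BARCODE><WELL>d<DROP>c<CRYSTAL>[_<EXTENSION>]

e.g. ``LMTIM_9098A07d1c1``: acronym LMTIM, plate 9098, well A07, drop 1,
first crystal fished from that drop.  The grammar is unambiguous because
acronyms and barcodes are strictly alphanumeric: the first underscore ends
the acronym, an optional second underscore starts a user extension, and the
core is parsed right-anchored (``c<int>``, ``d<int>``, then a three-character
well label).

Downstream sample databases cap names at 45 characters; 27 is the
recommended maximum because synchrotron implementations differ.  The core
name (without extension) is the uniqueness key.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, replace
from typing import Optional

from .errors import ConflictError, ParseError, ValidationError

HARD_LIMIT = 45
RECOMMENDED_LIMIT = 27

_ALNUM_RE = re.compile(r"^[A-Za-z0-9]+$")
_EXT_RE = re.compile(r"^[A-Za-z0-9-]+$")
_WELL_RE = re.compile(r"^[A-Z]\d{2}$")
# right-anchored core tail: well label, drop number, crystal number
_TAIL_RE = re.compile(r"([A-Z]\d{2})d(\d+)c(\d+)$")


@dataclass(frozen=True)
class SampleName:
    """Parsed form of a crystal sample name."""

    acronym: str
    plate_barcode: str
    well_label: str
    drop_number: int
    crystal_number: int
    extension: Optional[str] = None

    @property
    def core(self) -> str:
        """Rendered name without the user extension (the uniqueness key)."""
        return (f"{self.acronym}_{self.plate_barcode}{self.well_label}"
                f"d{self.drop_number}c{self.crystal_number}")

    @property
    def rendered(self) -> str:
        if self.extension:
            return f"{self.core}_{self.extension}"
        return self.core


def well_label(row_index: int, col_index: int,
               plate_rows: int = 8, plate_cols: int = 12) -> str:
    """Label a well from 0-based indices: row letter + 2-digit column.

    ``(0, 6)`` -> ``"A07"``; ``(4, 0)`` -> ``"E01"``.
    """
    if not (0 <= row_index < plate_rows):
        raise ValidationError(
            f"row index {row_index} outside plate with {plate_rows} rows"
        )
    if not (0 <= col_index < plate_cols):
        raise ValidationError(
            f"column index {col_index} outside plate with {plate_cols} columns"
        )
    if plate_rows > 26:
        raise ValidationError("plates with more than 26 rows are not supported")
    return f"{string.ascii_uppercase[row_index]}{col_index + 1:02d}"


def parse_well_label(label: str, plate_rows: int = 8,
                     plate_cols: int = 12) -> tuple[int, int]:
    """Inverse of :func:`well_label`; returns 0-based (row, col)."""
    if not _WELL_RE.match(label):
        raise ParseError(f"invalid well label {label!r}")
    row = ord(label[0]) - ord("A")
    col = int(label[1:]) - 1
    if row >= plate_rows or col >= plate_cols:
        raise ValidationError(
            f"well {label!r} outside {plate_rows}x{plate_cols} plate"
        )
    return row, col


class NameRegistry:
    """Global registry enforcing core-name uniqueness."""

    def __init__(self) -> None:
        self._names: set[str] = set()

    def __contains__(self, core: str) -> bool:
        return core in self._names

    def register(self, core: str) -> None:
        if core in self._names:
            raise ConflictError(f"sample name {core!r} already registered")
        self._names.add(core)

    def names(self) -> set[str]:
        return set(self._names)


def generate_sample_name(acronym: str, plate_barcode: str, well: str,
                         drop_number: int, crystal_number: int,
                         extension: Optional[str] = None,
                         registry: Optional[NameRegistry] = None) -> SampleName:
    """Build (and optionally register) a sample name.

    Raises on invalid parts, on names over the 45-character hard limit, and
    on collision with an already registered core name.
    """
    if not _ALNUM_RE.match(acronym):
        raise ValidationError(f"invalid acronym {acronym!r}")
    if not _ALNUM_RE.match(plate_barcode):
        raise ValidationError(f"plate barcode {plate_barcode!r} must be alphanumeric")
    if not _WELL_RE.match(well):
        raise ValidationError(f"invalid well label {well!r}")
    if drop_number < 1 or crystal_number < 1:
        raise ValidationError("drop and crystal numbers start at 1")
    if extension is not None and extension != "" and not _EXT_RE.match(extension):
        raise ValidationError(f"invalid extension {extension!r}")
    name = SampleName(acronym, plate_barcode, well, drop_number,
                      crystal_number, extension or None)
    if len(name.rendered) > HARD_LIMIT:
        raise ValidationError(
            f"sample name {name.rendered!r} is {len(name.rendered)} characters; "
            f"the hard limit is {HARD_LIMIT}"
        )
    if registry is not None:
        registry.register(name.core)
    return name


def parse_sample_name(rendered: str) -> SampleName:
    """Parse a rendered sample name back into its fields.

    The parse is right-anchored on the core: the crystal and drop numbers
    and the 3-character well label are matched from the end, the text before
    the first underscore is the acronym, and what lies between is the plate
    barcode.  A second underscore, if present, starts the user extension.
    """
    if "_" not in rendered:
        raise ParseError(f"{rendered!r}: no underscore after acronym")
    acronym, _, rest = rendered.partition("_")
    core_rest, _, extension = rest.partition("_")
    if "_" in extension:
        raise ParseError(f"{rendered!r}: more than one extension separator")
    m = _TAIL_RE.search(core_rest)
    if m is None:
        raise ParseError(
            f"{rendered!r}: missing well/drop/crystal tail (…A07d1c1)"
        )
    barcode = core_rest[: m.start()]
    if not _ALNUM_RE.match(acronym) or not _ALNUM_RE.match(barcode):
        raise ParseError(f"{rendered!r}: acronym/barcode not alphanumeric")
    if extension and not _EXT_RE.match(extension):
        raise ParseError(f"{rendered!r}: invalid extension {extension!r}")
    return SampleName(
        acronym=acronym,
        plate_barcode=barcode,
        well_label=m.group(1),
        drop_number=int(m.group(2)),
        crystal_number=int(m.group(3)),
        extension=extension or None,
    )


def validate_sample_name(rendered: str):
    """Severity check: error over 45 characters or unparseable; warning
    between 28 and 45 characters; ok otherwise."""
    from .domain import ValidationResult  # local import to avoid cycle at import time

    if len(rendered) > HARD_LIMIT:
        return ValidationResult(
            "error",
            f"name is {len(rendered)} characters; at most {HARD_LIMIT} allowed",
        )
    try:
        parse_sample_name(rendered)
    except ParseError as exc:
        return ValidationResult("error", str(exc))
    if len(rendered) > RECOMMENDED_LIMIT:
        return ValidationResult(
            "warning",
            f"name is {len(rendered)} characters; at most "
            f"{RECOMMENDED_LIMIT} recommended",
        )
    return ValidationResult("ok")


def extend_sample_name(name: SampleName, extension: str) -> SampleName:
    """Attach a user extension (alphanumeric plus '-').

    The extension aids navigation (e.g. a ligand name) and is excluded from
    the uniqueness key.  An empty extension is a no-op.
    """
    if extension == "":
        return name
    if not _EXT_RE.match(extension):
        raise ValidationError(
            f"extension {extension!r} may contain only letters, digits and '-'"
        )
    extended = replace(name, extension=extension)
    if len(extended.rendered) > HARD_LIMIT:
        raise ValidationError(
            f"extended name would be {len(extended.rendered)} characters; "
            f"the hard limit is {HARD_LIMIT}"
        )
    return extended
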