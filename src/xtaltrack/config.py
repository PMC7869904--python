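"""Site configuration.

All tunable policy lives here: the imager import delay, container
capacities, the drop-score vocabulary, link templates for the manifest and
the synchrotron endpoint.  Values can be loaded from a YAML file so each
laboratory can adapt them without touching code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: Ordered drop-score vocabulary, worst to best.  Scoring stores the index
#: into this list; the plate-level "best score" is the maximum index seen.
DEFAULT_SCORE_CLASSES = [
    "clear",
    "light precipitate",
    "heavy precipitate",
    "phase separation",
    "spherulites",
    "microcrystals",
    "needles",
    "plates",
    "small 3D crystals",
    "single crystal",
]

DEFAULT_SCORE_COLORS = [
    "#d0d0d0",
    "#c0a080",
    "#804020",
    "#a0a0ff",
    "#ffc0ff",
    "#80ffff",
    "#40c0c0",
    "#40a040",
    "#80ff80",
    "#00c000",
]


@dataclass
class Config:
    """Runtime policy for a deployment."""

    # imaging import
    import_delay_s: int = 300  # new inspections are picked up after 5 min
    fallback_user: str = "admin"  # owner of plates whose owner hint is unknown
    plate_max_age_days: int | None = None  # optional age-based expiry

    # plate geometry defaults (96-well SBS format)
    default_rows: int = 8
    default_cols: int = 12
    default_drops_per_well: int = 3

    # containers
    puck_capacity: int = 16  # uni-puck convention

    # naming limits (upstream sample-name constraints)
    name_hard_limit: int = 45
    name_recommended_limit: int = 27
    acronym_recommended_length: int = 5

    # scoring
    score_classes: list[str] = field(
        default_factory=lambda: list(DEFAULT_SCORE_CLASSES)
    )
    score_colors: list[str] = field(
        default_factory=lambda: list(DEFAULT_SCORE_COLORS)
    )

    # shipment links; {sample}, {proposal}, {session} are filled per crystal
    icebear_link_template: str = "https://icebear.example.org/crystal/{sample}"
    ispyb_link_template: str = (
        "https://ispyb.example.org/proposals/{proposal}/sessions/{session}"
        "/samples/{sample}"
    )

    # synchrotron submission endpoint; "mock:" selects the in-process mock
    synchrotron_endpoint: str = "mock:"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
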