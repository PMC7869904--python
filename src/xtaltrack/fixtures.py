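"""Synthetic imager-export generator.

Emulates the file-drop contract of a plate-imaging system: a directory
with one sub-directory per inspection, each holding an ``inspection.txt``
sidecar and one small PNG per drop.  A known random subset of drops is
designated crystal-bearing and written to a ground-truth JSON at the inbox
root, so tests and the end-to-end pipeline know which drops to score and
select without any image analysis.

The generator is fully deterministic: the same seed produces a
byte-identical directory tree.
"""

from __future__ import annotations

import json
import random
from datetime import datetime, timedelta
from pathlib import Path

from PIL import Image

from .imaging import SIDECAR_NAME, write_sidecar
from .naming import well_label

GROUND_TRUTH_NAME = "ground_truth.json"
_BASE_TIME = datetime(2024, 3, 1, 9, 0, 0)
_BARCODE_ALPHABET = "0123456789abcdefghjkmnpqrstuvwxyz"


def generate_fixture(directory, seed: int, n_plates: int = 2,
                     inspections_per_plate: int = 3,
                     crystal_fraction: float = 0.1,
                     rows: int = 8, cols: int = 12,
                     drops_per_well: int = 3,
                     owner: str = "u1",
                     image_size: int = 16) -> dict:
    """Populate ``directory`` as a synthetic imager inbox.

    Returns the ground truth: plate barcodes and the list of
    crystal-bearing drops, also written to ``ground_truth.json`` in the
    directory.  Inspections are spaced one day apart starting well in the
    past, so they are always mature with respect to the import delay.
    """
    rng = random.Random(seed)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    barcodes: list[str] = []
    while len(barcodes) < n_plates:
        barcode = "".join(rng.choice(_BARCODE_ALPHABET) for _ in range(4))
        if barcode not in barcodes:
            barcodes.append(barcode)

    wells = [well_label(r, c, rows, cols) for r in range(rows) for c in range(cols)]
    crystal_drops = []
    for barcode in barcodes:
        for well in wells:
            for sub in range(1, drops_per_well + 1):
                if rng.random() < crystal_fraction:
                    crystal_drops.append(
                        {"plate": barcode, "well": well, "subposition": sub}
                    )

    for plate_no, barcode in enumerate(barcodes):
        for insp_no in range(inspections_per_plate):
            timestamp = _BASE_TIME + timedelta(
                days=insp_no, hours=plate_no
            )
            sub_dir = directory / f"{barcode}_insp{insp_no + 1}"
            sub_dir.mkdir(exist_ok=True)
            sidecar = {
                "barcode": barcode,
                "timestamp": timestamp.isoformat(),
                "mode": "visible",
                "owner": owner,
                "temperature": "20",
                "rows": str(rows),
                "cols": str(cols),
                "drops_per_well": str(drops_per_well),
                "scale_um_per_px": "2.5",
            }
            (sub_dir / SIDECAR_NAME).write_text(write_sidecar(sidecar))
            for well in wells:
                for sub in range(1, drops_per_well + 1):
                    _write_drop_image(
                        sub_dir / f"{well}{sub}.png", rng, image_size
                    )

    ground_truth = {
        "seed": seed,
        "plates": barcodes,
        "owner": owner,
        "inspections_per_plate": inspections_per_plate,
        "drops_per_well": drops_per_well,
        "crystal_drops": crystal_drops,
    }
    (directory / GROUND_TRUTH_NAME).write_text(
        json.dumps(ground_truth, indent=1)
    )
    return ground_truth


def _write_drop_image(path: Path, rng: random.Random, size: int) -> None:
    """A small grey-noise placeholder drop image (no science in the pixels)."""
    img = Image.new("L", (size, size))
    img.putdata([rng.randrange(96, 192) for _ in range(size * size)])
    img.save(path, format="PNG")


def load_ground_truth(directory) -> dict:
    return json.loads((Path(directory) / GROUND_TRUTH_NAME).read_text())
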