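"""End-to-end demonstration pipeline.

Runs the whole tracked life of a crystallization campaign against a
synthetic imager export: generate the inbox, ingest the inspections,
assign the plates to a project, score and select the crystal-bearing drops
named in the ground truth, fish them into pucks and dewars at the bench,
assemble and submit a shipment to the mock synchrotron, render the
manifest, and process the dewar return.  Used by the CLI demo and the
reproduction script; every step goes through the public operations.
"""

from __future__ import annotations

import random
from datetime import datetime
from pathlib import Path

from . import bench, domain, fixtures, imaging, scoring, shipping
from .mock_synchrotron import MockSynchrotron
from .store import LabStore


def run_demo_pipeline(workdir, seed: int, n_plates: int = 2,
                      inspections_per_plate: int = 3,
                      crystal_fraction: float = 0.1) -> dict:
    """Run the full workflow; returns a summary of counts and checks.

    Deterministic for a fixed seed: the fixture, the selection order, the
    container packing and the payload are all reproducible.
    """
    workdir = Path(workdir)
    inbox = workdir / "inbox"
    ground_truth = fixtures.generate_fixture(
        inbox, seed=seed, n_plates=n_plates,
        inspections_per_plate=inspections_per_plate,
        crystal_fraction=crystal_fraction,
    )

    store = LabStore()
    owner = ground_truth["owner"]
    store.add_user(owner, full_name="Plate Owner")
    store.add_user("shipper1", is_shipper=True)

    # ingest (the fixture's timestamps are old, so everything is mature)
    now = datetime(2024, 4, 1)
    inspections = imaging.scan_inbox(store, inbox, now=now)
    rescan = imaging.scan_inbox(store, inbox, now=now)

    # project setup and plate assignment
    project = domain.create_project(store, "demo campaign",
                                    "synthetic end-to-end run", owner)
    protein = domain.add_protein(store, project, "DEMO", "demo protein")
    for barcode in ground_truth["plates"]:
        imaging.assign_plate(store, store.plates[barcode], project.id,
                             protein.id, None, owner)

    # score and select every crystal-bearing drop from the ground truth
    top_class = len(store.config.score_classes) - 1
    crystals = []
    for entry in ground_truth["crystal_drops"]:
        plate = store.plates[entry["plate"]]
        scoring.score_drop(store, plate, entry["well"], entry["subposition"],
                           top_class, owner, now=now)
        crystals.append(
            scoring.select_crystal(store, plate, entry["well"],
                                   entry["subposition"], owner, now=now)
        )

    # bench session: scan containers, fish every selected crystal
    rng = random.Random(seed)
    session = bench.start_session(store, owner)
    capacity = store.config.puck_capacity
    n_pucks = max(1, -(-len(crystals) // capacity))
    n_dewars = max(1, -(-n_pucks // 4))
    for d in range(n_dewars):
        bench.scan_item(store, session, f"DW{seed:03d}{d:02d}", kind_hint="dewar")
    for p in range(n_pucks):
        bench.scan_item(store, session, f"PK{seed:03d}{p:02d}", kind_hint="puck")
    for barcode in ground_truth["plates"]:
        bench.scan_item(store, session, barcode)
    for i, crystal in enumerate(crystals):
        if rng.random() < 0.5:
            pin = bench.create_pin(store, f"PIN{seed:03d}{i:04d}")
            session.pins.append(pin.id)
            bench.fish_crystal(store, session, crystal, pin=pin, now=now)
        else:
            bench.fish_crystal(store, session, crystal, now=now)  # dummy pin

    # pack pucks into dewars round-robin
    for p, puck_barcode in enumerate(session.pucks):
        dewar = store.dewars[session.dewars[p % n_dewars]]
        dewar.puck_barcodes.append(puck_barcode)

    # shipment: assemble, validate, submit to the mock endpoint
    transport = MockSynchrotron()
    shipment = shipping.assemble_shipment(
        store, "shipper1", "DLS", list(session.dewars),
        approved_acronyms={"DEMO"}, proposal_id="mx1234", session_id="mx1234-5",
    )
    report = shipping.validate_shipment(store, shipment)
    payload = shipping.build_ispyb_payload(store, shipment)
    receipt = shipping.submit_shipment(
        store, shipment, {"username": "shipper1", "password": "pw"},
        transport=transport,
    )
    manifest = shipping.render_manifest(store, shipment)

    # collection, return, recycling: keep a third, wash the rest
    shipping.mark_sent(store, shipment)
    for i, row in enumerate(manifest):
        shipping.record_collection(
            store, shipment, row["puck"], row["position"], collected=True,
            disposition="keep_crystal" if i % 3 == 0 else "wash_pin",
        )
    shipping.mark_returned(store, shipment)
    kept = washed = 0
    for pin_id in list(shipment.pin_ids):
        result = shipping.process_return(store, shipment, store.pins[pin_id])
        if result["action"] == "keep":
            kept += 1
        else:
            washed += 1

    mounted_pins = sum(1 for p in store.pins.values() if p.crystal_name)
    payload_samples = sum(
        len(c["samples"]) for d in payload["dewars"] for c in d["containers"]
    )
    return {
        "store": store,
        "ground_truth": ground_truth,
        "n_inspections": len(inspections),
        "n_rescan": len(rescan),
        "n_crystals": len(crystals),
        "validation_ok": report.ok,
        "payload": payload,
        "payload_sha256": shipment.submission_receipt["payload_sha256"],
        "receipt": receipt,
        "manifest": manifest,
        "manifest_rows": len(manifest),
        "payload_samples": payload_samples,
        "pins_kept": kept,
        "pins_washed": washed,
        "dewar_states": sorted(
            store.dewars[b].state for b in shipment.dewar_barcodes
        ),
        "mounted_after_return": mounted_pins,
    }
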