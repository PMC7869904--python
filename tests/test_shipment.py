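"""Shipment validation, submission, manifest and dewar-return recycling."""

import json
from datetime import datetime

import pytest

from xtaltrack import bench, scoring, shipping
from xtaltrack.errors import (
    PermissionDenied,
    StateError,
    TransportError,
    ValidationError,
)
from xtaltrack.mock_synchrotron import MockSynchrotron

NOW = datetime(2024, 4, 1, 12, 0, 0)
CREDS = {"username": "shipper1", "password": "pw"}


def build_loaded_dewar(store, plate, n_crystals=3, dewar="DW01", puck="PUCK1"):
    """A dewar with one puck holding n mounted crystals."""
    session = bench.start_session(store, "u1")
    bench.scan_item(store, session, dewar, kind_hint="dewar")
    bench.scan_item(store, session, puck, kind_hint="puck")
    bench.scan_item(store, session, plate.barcode)
    crystals = []
    for _ in range(n_crystals):
        crystal = scoring.select_crystal(store, plate, "A07", 1, "u1", now=NOW)
        bench.fish_crystal(store, session, crystal, now=NOW)
        crystals.append(crystal)
    store.dewars[dewar].puck_barcodes.append(puck)
    return crystals


@pytest.fixture
def loaded(store, plate):
    crystals = build_loaded_dewar(store, plate)
    shipment = shipping.assemble_shipment(
        store, "shipper1", "DLS", ["DW01"], approved_acronyms={"LMTIM"},
        proposal_id="mx1234", session_id="mx1234-5",
    )
    return crystals, shipment


class TestAssembly:
    def test_non_shipper_refused(self, store, plate):
        build_loaded_dewar(store, plate)
        with pytest.raises(PermissionDenied):
            shipping.assemble_shipment(store, "u1", "DLS", ["DW01"], set())

    def test_dewar_cannot_join_two_shipments(self, store, loaded):
        with pytest.raises(Exception):
            shipping.assemble_shipment(store, "shipper1", "DLS", ["DW01"],
                                       set())

    def test_draft_allows_add_and_remove(self, store, plate, loaded):
        _, shipment = loaded
        bench.create_dewar(store, "DW02")
        shipping.add_dewar(store, shipment, "DW02")
        assert store.dewars["DW02"].state == "in_shipment"
        shipping.remove_dewar(store, shipment, "DW02")
        assert store.dewars["DW02"].state == "in_lab"


class TestValidation:
    def test_clean_shipment_passes(self, store, loaded):
        _, shipment = loaded
        report = shipping.validate_shipment(store, shipment)
        assert report.ok and report.violations == []

    def test_empty_containers_flagged(self, store, plate):
        bench.create_dewar(store, "DW01")
        bench.create_puck(store, "PUCK1")
        store.dewars["DW01"].puck_barcodes.append("PUCK1")
        shipment = shipping.assemble_shipment(
            store, "shipper1", "DLS", ["DW01"], {"LMTIM"},
            proposal_id="p", session_id="s",
        )
        report = shipping.validate_shipment(store, shipment)
        assert [v.code for v in report.violations] == ["EMPTY_PUCK"]

    def test_empty_pin_flagged(self, store, loaded):
        _, shipment = loaded
        pin = bench.create_pin(store, "EMPTYPIN")
        store.pucks["PUCK1"].slots[10] = pin.id
        report = shipping.validate_shipment(store, shipment)
        assert [v.code for v in report.violations] == ["EMPTY_PIN"]

    def test_unapproved_acronym_flagged(self, store, loaded):
        _, shipment = loaded
        shipment.approved_acronyms = {"PSB"}
        report = shipping.validate_shipment(store, shipment)
        assert {v.code for v in report.violations} == {"UNAPPROVED_ACRONYM"}
        assert len(report.violations) == 3  # one per crystal

    def test_submit_blocked_until_clean(self, store, loaded):
        _, shipment = loaded
        shipment.approved_acronyms = set()
        with pytest.raises(ValidationError):
            shipping.submit_shipment(store, shipment, CREDS,
                                     transport=MockSynchrotron())
        assert shipment.state == "draft"


class TestSubmission:
    def test_payload_and_history(self, store, loaded):
        crystals, shipment = loaded
        scoring.set_ispyb_info(store, crystals[0], "u1",
                               space_group="P212121",
                               desired_resolution_a=1.5)
        transport = MockSynchrotron()
        receipt = shipping.submit_shipment(store, shipment, CREDS,
                                           transport=transport)
        assert shipment.state == "submitted"
        assert receipt["accepted_samples"] == 3
        payload = transport.submissions[0]
        samples = payload["dewars"][0]["containers"][0]["samples"]
        assert [s["position"] for s in samples] == [1, 2, 3]
        assert samples[0]["desired_resolution_a"] == 1.5
        for crystal in crystals:
            entry = crystal.shipment_history[-1]
            assert (entry["proposal_id"], entry["session_id"]) == (
                "mx1234", "mx1234-5"
            )
            assert crystal.ispyb_links  # per-sample link recorded

    def test_payload_deterministic(self, store, loaded):
        _, shipment = loaded
        a = shipping.build_ispyb_payload(store, shipment)
        b = shipping.build_ispyb_payload(store, shipment)
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_endpoint_failure_keeps_draft(self, store, loaded):
        _, shipment = loaded
        with pytest.raises(TransportError):
            shipping.submit_shipment(store, shipment, CREDS,
                                     transport=MockSynchrotron(fail=True))
        assert shipment.state == "draft"
        assert shipment.submission_receipt is None
        # retry against a working endpoint succeeds
        shipping.submit_shipment(store, shipment, CREDS,
                                 transport=MockSynchrotron())
        assert shipment.state == "submitted"


class TestHttpEndpoint:
    def test_submission_over_http_loopback(self, store, loaded):
        from xtaltrack.mock_synchrotron import HttpTransport, serve_mock
        _, shipment = loaded
        server, url = serve_mock()
        try:
            receipt = shipping.submit_shipment(store, shipment, CREDS,
                                               transport=HttpTransport(url))
        finally:
            server.shutdown()
        assert receipt["accepted_samples"] == 3
        assert shipment.state == "submitted"


class TestManifest:
    def test_rows_and_qr_payloads(self, store, loaded):
        _, shipment = loaded
        shipping.submit_shipment(store, shipment, CREDS,
                                 transport=MockSynchrotron())
        rows = shipping.render_manifest(store, shipment)
        assert len(rows) == 3
        for row in rows:
            assert row["qr_payloads"] == [row["icebear_link"],
                                          row["ispyb_link"]]
            assert row["sample_name"] in row["icebear_link"]

    def test_manifest_links_resolve_via_search(self, store, loaded):
        from xtaltrack.search import search
        _, shipment = loaded
        shipping.submit_shipment(store, shipment, CREDS,
                                 transport=MockSynchrotron())
        for row in shipping.render_manifest(store, shipment):
            hits = search(store, row["sample_name"])
            assert hits and hits[0].kind == "crystal"

    def test_no_manifest_for_draft(self, store, loaded):
        _, shipment = loaded
        with pytest.raises(StateError):
            shipping.render_manifest(store, shipment)


class TestCollectionAndReturn:
    @pytest.fixture
    def sent(self, store, loaded):
        crystals, shipment = loaded
        shipping.submit_shipment(store, shipment, CREDS,
                                 transport=MockSynchrotron())
        shipping.mark_sent(store, shipment)
        return crystals, shipment

    def test_record_on_draft_refused(self, store, loaded):
        _, shipment = loaded
        with pytest.raises(StateError):
            shipping.record_collection(store, shipment, "PUCK1", 1, True)

    def test_puck_complete_when_all_positions_used(self, store, sent):
        _, shipment = sent
        for pos in (1, 2):
            shipping.record_collection(store, shipment, "PUCK1", pos, True)
        assert not shipping.puck_complete(store, shipment, "PUCK1")
        shipping.record_collection(store, shipment, "PUCK1", 3, True,
                                   disposition="keep_crystal")
        assert shipping.puck_complete(store, shipment, "PUCK1")

    def test_wash_frees_pin_but_keeps_crystal_record(self, store, sent):
        crystals, shipment = sent
        shipping.mark_returned(store, shipment)
        pin = store.pins[shipment.pin_ids[0]]
        crystal_name = pin.crystal_name
        result = shipping.process_return(store, shipment, pin, action="wash")
        assert result["action"] == "wash"
        crystal = store.crystals[crystal_name]
        assert crystal.shipment_history  # history survives the wash
        assert pin.id not in store.pucks["PUCK1"].slots.values()

    def test_kept_crystal_is_reshippable_with_history(self, store, plate,
                                                      sent):
        crystals, shipment = sent
        shipping.mark_returned(store, shipment)
        for pin_id in list(shipment.pin_ids):
            shipping.process_return(store, shipment, store.pins[pin_id],
                                    action="keep")
        assert store.dewars["DW01"].state == "in_lab"
        # second trip with the kept crystal on the same pin
        pin = store.pins[shipment.pin_ids[0]]
        assert pin.state == "returned_keep"
        bench.create_puck(store, "PUCK9")
        bench.create_dewar(store, "DW09")
        bench.move_pin(store, pin, store.pucks["PUCK9"], 1)
        store.dewars["DW09"].puck_barcodes.append("PUCK9")
        second = shipping.assemble_shipment(
            store, "shipper1", "DLS", ["DW09"], {"LMTIM"},
            proposal_id="mx1234", session_id="mx1234-7",
        )
        shipping.submit_shipment(store, second, CREDS,
                                 transport=MockSynchrotron())
        crystal = store.crystals[pin.crystal_name]
        assert [h["session_id"] for h in crystal.shipment_history] == [
            "mx1234-5", "mx1234-7"
        ]

    def test_unrecorded_disposition_defaults_to_wash_with_warning(
            self, store, sent):
        _, shipment = sent
        shipping.mark_returned(store, shipment)
        pin = store.pins[shipment.pin_ids[0]]
        result = shipping.process_return(store, shipment, pin)
        assert result["action"] == "wash"
        assert "defaulting to wash" in result["warning"]

    def test_processing_before_return_refused(self, store, sent):
        _, shipment = sent
        pin = store.pins[shipment.pin_ids[0]]
        with pytest.raises(StateError):
            shipping.process_return(store, shipment, pin, action="wash")

    def test_sent_shipment_locks_pins(self, store, sent):
        _, shipment = sent
        pin = store.pins[shipment.pin_ids[0]]
        bench.create_puck(store, "OTHER")
        from xtaltrack.errors import LockedError
        with pytest.raises((LockedError, ValidationError)):
            bench.move_pin(store, pin, store.pucks["OTHER"], 1)
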