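"""Virtual workbench: scanning, fishing, pin placement and the event log."""

import random
from datetime import datetime

import pytest

from xtaltrack import bench, scoring
from xtaltrack.errors import (
    CapacityError,
    NotFoundError,
    OccupancyError,
    ValidationError,
)

NOW = datetime(2024, 4, 1, 12, 0, 0)


@pytest.fixture
def session(store):
    return bench.start_session(store, "u1")


@pytest.fixture
def workbench(store, session, plate):
    """Session with one dewar, two pucks and the plate scanned, and three
    crystals selected on the plate."""
    bench.scan_item(store, session, "DW01", kind_hint="dewar")
    bench.scan_item(store, session, "PUCK1", kind_hint="puck")
    bench.scan_item(store, session, "PUCK2", kind_hint="puck")
    crystals = [
        scoring.select_crystal(store, plate, "A07", 1, "u1", now=NOW)
        for _ in range(3)
    ]
    info = bench.scan_item(store, session, plate.barcode)
    return session, crystals, info


class TestScan:
    def test_plate_scan_lists_selected_crystals(self, workbench):
        _, crystals, info = workbench
        assert info["kind"] == "plate"
        assert set(info["selected_crystals"]) == {c.core_name for c in crystals}

    def test_rescan_is_noop(self, store, session):
        bench.scan_item(store, session, "PUCK1", kind_hint="puck")
        info = bench.scan_item(store, session, "PUCK1")
        assert info["already_in_session"]
        assert session.pucks == ["PUCK1"]

    def test_occupied_pin_flagged(self, store, session, plate):
        crystal = scoring.select_crystal(store, plate, "A07", 1, "u1", now=NOW)
        bench.quick_fish(store, crystal, "PIN9")
        info = bench.scan_item(store, session, "PIN9")
        assert info["occupied"]

    def test_unknown_barcode_needs_hint(self, store, session):
        with pytest.raises(NotFoundError):
            bench.scan_item(store, session, "nothing")


class TestFishing:
    def test_first_empty_slot_rule(self, store, workbench):
        session, crystals, _ = workbench
        records = [bench.fish_crystal(store, session, c, now=NOW)
                   for c in crystals]
        assert [(r["puck"], r["position"]) for r in records] == [
            ("PUCK1", 1), ("PUCK1", 2), ("PUCK1", 3)
        ]

    def test_dummy_pin_created_when_no_pin_given(self, store, workbench):
        session, crystals, _ = workbench
        record = bench.fish_crystal(store, session, crystals[0], now=NOW)
        assert record["dummy"]
        assert store.pins[record["pin"]].barcode is None

    def test_explicit_pin_used(self, store, workbench):
        session, crystals, _ = workbench
        pin = bench.create_pin(store, "PIN1")
        session.pins.append(pin.id)
        record = bench.fish_crystal(store, session, crystals[0], pin=pin,
                                    now=NOW)
        assert record["pin"] == "PIN1"
        assert not record["dummy"]

    def test_occupied_pin_refused(self, store, workbench):
        session, crystals, _ = workbench
        pin = bench.create_pin(store, "PIN1")
        session.pins.append(pin.id)
        bench.fish_crystal(store, session, crystals[0], pin=pin, now=NOW)
        with pytest.raises(OccupancyError):
            bench.fish_crystal(store, session, crystals[1], pin=pin, now=NOW)

    def test_crystal_cannot_be_mounted_twice(self, store, workbench):
        session, crystals, _ = workbench
        bench.fish_crystal(store, session, crystals[0], now=NOW)
        with pytest.raises(OccupancyError):
            bench.fish_crystal(store, session, crystals[0], now=NOW)

    def test_overflow_to_second_puck_then_capacity_error(self, store, plate):
        store.config.puck_capacity = 2
        session = bench.start_session(store, "u1")
        bench.scan_item(store, session, "P1", kind_hint="puck")
        bench.scan_item(store, session, "P2", kind_hint="puck")
        crystals = [
            scoring.select_crystal(store, plate, "A07", 1, "u1", now=NOW)
            for _ in range(5)
        ]
        placements = [bench.fish_crystal(store, session, c, now=NOW)
                      for c in crystals[:4]]
        assert [(r["puck"], r["position"]) for r in placements] == [
            ("P1", 1), ("P1", 2), ("P2", 1), ("P2", 2)
        ]
        with pytest.raises(CapacityError):
            bench.fish_crystal(store, session, crystals[4], now=NOW)


class TestMovePin:
    def test_move_frees_old_slot(self, store, workbench):
        session, crystals, _ = workbench
        record = bench.fish_crystal(store, session, crystals[0], pin=None,
                                    now=NOW)
        pin = store.pins[record["pin"]]
        # dummy pins may move within their puck
        bench.move_pin(store, pin, store.pucks["PUCK1"], 5, session=session)
        assert store.pucks["PUCK1"].slots == {5: pin.id}

    def test_move_into_occupied_slot_refused(self, store, workbench):
        session, crystals, _ = workbench
        a = bench.fish_crystal(store, session, crystals[0], now=NOW)
        bench.fish_crystal(store, session, crystals[1], now=NOW)
        with pytest.raises(OccupancyError):
            bench.move_pin(store, store.pins[a["pin"]],
                           store.pucks["PUCK1"], 2)

    def test_dummy_pin_cannot_change_puck(self, store, workbench):
        session, crystals, _ = workbench
        record = bench.fish_crystal(store, session, crystals[0], now=NOW)
        with pytest.raises(ValidationError):
            bench.move_pin(store, store.pins[record["pin"]],
                           store.pucks["PUCK2"], 1)

    def test_barcoded_pin_moves_between_pucks(self, store, workbench):
        session, crystals, _ = workbench
        pin = bench.create_pin(store, "PIN1")
        session.pins.append(pin.id)
        bench.fish_crystal(store, session, crystals[0], pin=pin, now=NOW)
        bench.move_pin(store, pin, store.pucks["PUCK2"], 4, session=session)
        assert store.pucks["PUCK1"].slots == {}
        assert store.pucks["PUCK2"].slots == {4: "PIN1"}


class TestQuickFish:
    def test_binds_without_puck(self, store, plate):
        crystal = scoring.select_crystal(store, plate, "A07", 1, "u1", now=NOW)
        record = bench.quick_fish(store, crystal, "PIN123")
        assert record["puck"] is None
        pin = store.pins_by_barcode["PIN123"]
        assert pin.crystal_name == crystal.core_name

    def test_quick_fished_pin_placeable_later(self, store, session, plate):
        crystal = scoring.select_crystal(store, plate, "A07", 1, "u1", now=NOW)
        bench.quick_fish(store, crystal, "PIN123")
        bench.scan_item(store, session, "PUCK1", kind_hint="puck")
        pin = store.pins_by_barcode["PIN123"]
        bench.move_pin(store, pin, store.pucks["PUCK1"], 1, session=session)
        assert store.pucks["PUCK1"].slots[1] == pin.id

    def test_requires_barcode(self, store, plate):
        crystal = scoring.select_crystal(store, plate, "A07", 1, "u1", now=NOW)
        with pytest.raises(ValidationError):
            bench.quick_fish(store, crystal, "")


class TestFishUnimaged:
    def test_creates_plate_dummy_image_and_name(self, store, session,
                                                project, protein):
        bench.scan_item(store, session, "PUCK1", kind_hint="puck")
        record = bench.fish_unimaged(store, session, "77ab", "B03", 1, "u1",
                                     protein_id=protein.id, now=NOW)
        crystal = record["crystal_obj"]
        assert crystal.sample_name.rendered == "LMTIM_77abB03d1c1"
        plate = store.plates["77ab"]
        assert plate.latest_image("B03", 1).dummy

    def test_second_fish_same_drop_is_c2(self, store, session, project,
                                         protein):
        bench.scan_item(store, session, "PUCK1", kind_hint="puck")
        bench.fish_unimaged(store, session, "77ab", "B03", 1, "u1",
                            protein_id=protein.id, now=NOW)
        record = bench.fish_unimaged(store, session, "77ab", "B03", 1, "u1",
                                     now=NOW)
        assert record["crystal_obj"].sample_name.crystal_number == 2

    def test_drop_outside_geometry_refused(self, store, session, protein):
        bench.scan_item(store, session, "PUCK1", kind_hint="puck")
        with pytest.raises(ValidationError):
            bench.fish_unimaged(store, session, "77ab", "B03", 4, "u1",
                                protein_id=protein.id, now=NOW)


def brute_force_occupancy(store):
    """Oracle: recount mounts and slots from scratch."""
    mounted_crystals = {
        p.crystal_name for p in store.pins.values() if p.crystal_name
    }
    pins_with_crystal = sum(
        1 for p in store.pins.values() if p.crystal_name is not None
    )
    placed = [pid for puck in store.pucks.values()
              for pid in puck.slots.values()]
    return mounted_crystals, pins_with_crystal, placed


class TestInvariants:
    def test_occupancy_conservation_under_random_ops(self, store, plate):
        rng = random.Random(123)
        session = bench.start_session(store, "u1")
        for i in range(3):
            bench.scan_item(store, session, f"PK{i}", kind_hint="puck")
        crystals = [
            scoring.select_crystal(store, plate, "A07", 1, "u1", now=NOW)
            for _ in range(20)
        ]
        for step in range(300):
            op = rng.choice(["fish", "quick", "move"])
            try:
                if op == "fish":
                    bench.fish_crystal(store, session, rng.choice(crystals),
                                       now=NOW)
                elif op == "quick":
                    bench.quick_fish(store, rng.choice(crystals),
                                     f"QP{rng.randrange(10)}")
                else:
                    pin = rng.choice(list(store.pins.values()))
                    bench.move_pin(store, pin,
                                   store.pucks[rng.choice(session.pucks)],
                                   rng.randint(1, 16), session=session)
            except Exception:
                pass  # rejected operations must leave the state untouched
            mounted, pins_with, placed = brute_force_occupancy(store)
            assert len(placed) == len(set(placed))  # no slot double-booked
            assert pins_with == len(mounted)  # a crystal sits on one pin

    def test_event_log_replay_reconstructs_state(self, store, workbench):
        session, crystals, _ = workbench
        for c in crystals[:2]:
            bench.fish_crystal(store, session, c, now=NOW)
        record = bench.fish_crystal(store, session, crystals[2], now=NOW)
        bench.move_pin(store, store.pins[record["pin"]],
                       store.pucks["PUCK1"], 10, session=session)
        replayed = bench.replay_placements(store, session)
        actual = {
            barcode: dict(store.pucks[barcode].slots)
            for barcode in session.pucks
        }
        assert replayed == actual
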