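"""Inbox ingestion, plate registration, tasks, and the fixture generator."""

from datetime import datetime, timedelta
from pathlib import Path

import pytest

from xtaltrack import fixtures, imaging
from xtaltrack.errors import ConflictError, PermissionDenied, ValidationError

NOW = datetime(2024, 4, 1, 12, 0, 0)


def make_inspection_dir(root: Path, barcode: str, timestamp: datetime,
                        wells=("A01",), mode="visible", owner="u1",
                        sidecar_overrides=None) -> Path:
    sub = root / f"{barcode}_{timestamp:%Y%m%d%H%M%S}"
    sub.mkdir(parents=True)
    sidecar = {
        "barcode": barcode, "timestamp": timestamp.isoformat(), "mode": mode,
        "owner": owner, "temperature": "20", "rows": "8", "cols": "12",
        "drops_per_well": "3",
    }
    if sidecar_overrides:
        sidecar.update(sidecar_overrides)
        sidecar = {k: v for k, v in sidecar.items() if v is not None}
    (sub / imaging.SIDECAR_NAME).write_text(imaging.write_sidecar(sidecar))
    for well in wells:
        for drop in (1, 2, 3):
            (sub / f"{well}{drop}.png").write_bytes(b"\x89PNG fake")
    return sub


class TestScanInbox:
    def test_import_and_idempotence(self, store, tmp_path):
        make_inspection_dir(tmp_path, "9098", NOW - timedelta(minutes=10))
        first = imaging.scan_inbox(store, tmp_path, now=NOW)
        assert len(first) == 1
        assert len(first[0].images) == 3
        assert imaging.scan_inbox(store, tmp_path, now=NOW) == []

    def test_import_delay_holds_back_fresh_inspections(self, store, tmp_path):
        make_inspection_dir(tmp_path, "9098", NOW - timedelta(seconds=60))
        assert imaging.scan_inbox(store, tmp_path, now=NOW) == []
        # the same inspection matures and is picked up by a later scan
        later = NOW + timedelta(seconds=300)
        assert len(imaging.scan_inbox(store, tmp_path, now=later)) == 1

    def test_missing_barcode_quarantined(self, store, tmp_path):
        make_inspection_dir(tmp_path, "9098", NOW - timedelta(minutes=10),
                            sidecar_overrides={"barcode": None})
        assert imaging.scan_inbox(store, tmp_path, now=NOW) == []
        assert len(store.quarantine) == 1
        assert "barcode" in store.quarantine[0]["reason"]

    def test_unknown_barcode_registers_plate_with_task(self, store, tmp_path):
        make_inspection_dir(tmp_path, "77ab", NOW - timedelta(minutes=10))
        imaging.scan_inbox(store, tmp_path, now=NOW)
        plate = store.plates["77ab"]
        assert plate.owner == "u1"
        kinds = {t.kind for t in imaging.pending_tasks(store, "u1")}
        assert "assign_plate" in kinds
        assert "complete_metadata" in kinds  # no screen/buffer yet

    def test_unknown_owner_falls_back(self, store, tmp_path):
        make_inspection_dir(tmp_path, "77ab", NOW - timedelta(minutes=10),
                            sidecar_overrides={"owner": "nobody"})
        imaging.scan_inbox(store, tmp_path, now=NOW)
        assert store.plates["77ab"].owner == store.config.fallback_user

    def test_images_reachable_from_exactly_one_slot(self, store, tmp_path):
        make_inspection_dir(tmp_path, "9098", NOW - timedelta(minutes=10),
                            wells=("A01", "B05"))
        imaging.scan_inbox(store, tmp_path, now=NOW)
        paths = [
            img.path
            for plate in store.plates.values()
            for insp in plate.inspections
            for img in insp.images.values()
        ]
        assert len(paths) == 6
        assert len(set(paths)) == 6


class TestRegistration:
    def test_duplicate_barcode_rejected(self, store):
        imaging.register_plate_from_imager(store, {"barcode": "9098",
                                                   "owner": "u1"})
        with pytest.raises(ConflictError):
            imaging.register_plate_from_imager(store, {"barcode": "9098",
                                                       "owner": "u1"})

    def test_assign_closes_task(self, store, project, protein):
        plate = imaging.register_plate_from_imager(
            store, {"barcode": "9098", "owner": "u1"}
        )
        assert any(t.kind == "assign_plate"
                   for t in imaging.pending_tasks(store, "u1"))
        imaging.assign_plate(store, plate, project.id, protein.id, None, "u1")
        assert not any(t.kind == "assign_plate"
                       for t in imaging.pending_tasks(store, "u1"))

    def test_cross_project_construct_rejected(self, store, project, protein):
        from xtaltrack import domain
        other = domain.create_project(store, "other", "x", "u2")
        other_prot = domain.add_protein(store, other, "XYZ")
        other_con = domain.add_construct(store, other_prot, "wt",
                                         [("A", "amino_acid", "MK")])
        plate = imaging.register_plate_from_imager(
            store, {"barcode": "9098", "owner": "u1"}
        )
        with pytest.raises(ValidationError):
            imaging.assign_plate(store, plate, project.id, protein.id,
                                 other_con.id, "u1")

    def test_non_owner_cannot_assign(self, store, project, protein):
        plate = imaging.register_plate_from_imager(
            store, {"barcode": "9098", "owner": "u1"}
        )
        with pytest.raises(PermissionDenied):
            imaging.assign_plate(store, plate, project.id, protein.id,
                                 None, "u2")


class TestExpiry:
    def test_expired_plate_opens_one_task(self, store, plate):
        imaging.mark_plate_expired(store, plate, now=NOW)
        imaging.mark_plate_expired(store, plate, now=NOW)  # dedup
        tasks = [t for t in imaging.pending_tasks(store, "u1")
                 if t.kind == "remove_expired_plate"]
        assert len(tasks) == 1
        assert plate.expired
        assert imaging.pending_tasks(store, "u2") == []


class TestFixtureGenerator:
    def test_deterministic_tree(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        truth_a = fixtures.generate_fixture(a, seed=42, n_plates=1,
                                            inspections_per_plate=2,
                                            rows=2, cols=3)
        truth_b = fixtures.generate_fixture(b, seed=42, n_plates=1,
                                            inspections_per_plate=2,
                                            rows=2, cols=3)
        assert truth_a == truth_b
        files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel

    def test_zero_fraction_means_no_crystals(self, tmp_path):
        truth = fixtures.generate_fixture(tmp_path / "z", seed=1, n_plates=1,
                                          inspections_per_plate=1,
                                          crystal_fraction=0.0,
                                          rows=2, cols=3)
        assert truth["crystal_drops"] == []

    def test_generated_inbox_ingests_cleanly(self, store, tmp_path):
        truth = fixtures.generate_fixture(tmp_path / "in", seed=5, n_plates=2,
                                          inspections_per_plate=2,
                                          rows=2, cols=3)
        imported = imaging.scan_inbox(store, tmp_path / "in",
                                      now=datetime(2024, 4, 1))
        assert len(imported) == 4  # 2 plates x 2 inspections
        for insp in imported:
            assert len(insp.images) == 2 * 3 * 3  # wells x drops
        assert store.quarantine == []
        assert set(truth["plates"]) == set(store.plates)
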