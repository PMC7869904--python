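from datetime import datetime

import pytest

from xtaltrack import domain, imaging
from xtaltrack.store import LabStore

NOW = datetime(2024, 4, 1, 12, 0, 0)


@pytest.fixture
def store():
    """A store with the standard cast: owner u1, member u2, guest u3,
    an admin and a shipper."""
    s = LabStore()
    s.add_user("u1")
    s.add_user("u2")
    s.add_user("u3")
    s.add_user("admin", is_admin=True)
    s.add_user("shipper1", is_shipper=True)
    return s


@pytest.fixture
def project(store):
    prj = domain.create_project(store, "TIM kinetics",
                                "triosephosphate isomerase variants", "u1")
    domain.set_project_role(store, prj, "u2", "member", caller="u1")
    domain.set_project_role(store, prj, "u3", "guest", caller="u1")
    return prj


@pytest.fixture
def protein(store, project):
    return domain.add_protein(store, project, "LMTIM", "triosephosphate isomerase")


@pytest.fixture
def plate(store, project, protein):
    """Plate 9098, registered from the imager and assigned, with one
    scaled inspection covering well A07."""
    p = imaging.register_plate_from_imager(
        store, {"barcode": "9098", "owner": "u1", "temperature": "20"}
    )
    imaging.assign_plate(store, p, project.id, protein.id, None, "u1")
    inspection = imaging.Inspection(
        plate_barcode="9098", timestamp=NOW, mode="visible",
        images={
            imaging.drop_key("A07", 1): imaging.DropImage(
                path="A071.png", scale_um_per_px=2.5
            )
        },
    )
    p.inspections.append(inspection)
    return p
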