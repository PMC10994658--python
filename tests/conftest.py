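import numpy as np
import pytest

from spiculometry import morphometry, phantoms

try:  # keep hypothesis runs reproducible
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "repro", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
    )
    settings.load_profile("repro")
except ImportError:  # pragma: no cover
    pass


CAPSULE_R = 4.0
CAPSULE_L = 100.0


@pytest.fixture(scope="session")
def capsule_phantom():
    """Axis-aligned capsule rod, r=4 µm, L=100 µm, 1 µm isotropic spacing."""
    prim = phantoms.RodPrimitive((0.0, 0.0, 0.0), (0.0, 0.0, CAPSULE_L), CAPSULE_R)
    return phantoms.make_rod_phantom(phantoms.PhantomSpec((prim,), seed=0))


@pytest.fixture(scope="session")
def capsule_measured(capsule_phantom):
    vol, truth = capsule_phantom
    record, details = morphometry.measure_spicule(vol.values, vol.spacing, origin=vol.origin)
    return record, details, truth


@pytest.fixture(scope="session")
def triradiate_phantom():
    return phantoms.make_triradiate_phantom(
        (0.0, 0.0, 0.0),
        [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)],
        [50.0, 50.0, 50.0],
        radius=3.0,
    )


@pytest.fixture(scope="session")
def tip_split_phantom():
    base = phantoms.RodPrimitive((0.0, 0.0, 0.0), (0.0, 0.0, CAPSULE_L), CAPSULE_R)
    return phantoms.make_branched_phantom(base, 1.0, (0.0, 1.0, 1.0), 20.0)


@pytest.fixture(scope="session")
def back_branch_phantom():
    base = phantoms.RodPrimitive((0.0, 0.0, 0.0), (0.0, 0.0, CAPSULE_L), CAPSULE_R)
    return phantoms.make_branched_phantom(base, 0.5, (0.0, 1.0, 1.0), 20.0)


def measured_junctions_um(details):
    g = details["graph"]
    return [g.node_position_um(n.id) for n in g.nodes.values() if n.kind == "junction"]


@pytest.fixture(scope="session")
def fluor_fixture():
    """Two 100-px regions at densities 0.5 / 0.1 plus a blob region."""
    shape = (60, 120)
    masks = {
        "skeletogenic": np.zeros(shape, dtype=bool),
        "ectoderm": np.zeros(shape, dtype=bool),
        "vesicles": np.zeros(shape, dtype=bool),
    }
    masks["skeletogenic"][5:15, 5:15] = True
    masks["ectoderm"][5:15, 25:35] = True
    masks["vesicles"][20:55, 10:110] = True
    img, masks, truth = phantoms.make_fluor_fixture(
        shape,
        masks,
        {"skeletogenic": 0.5, "ectoderm": 0.1},
        blob_spec={"vesicles": (5, 3)},
        seed=7,
    )
    return img, masks, truth
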