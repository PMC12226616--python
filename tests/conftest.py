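import numpy as np
import pytest

from kevs.phantom import PhantomSpec, generate_phantom
from kevs.volume import CTVolume, LabelMap


@pytest.fixture(scope="session")
def phantom_case():
    """One default phantom shared across the suite (seed fixed for determinism)."""
    spec = PhantomSpec(seed=1)
    ct, labels, vat, census = generate_phantom(spec)
    return spec, ct, labels, vat, census


@pytest.fixture(scope="session")
def small_phantom_case():
    """A reduced-grid phantom for tests that regenerate or corrupt labels."""
    spec = PhantomSpec(
        shape=(64, 64, 32),
        body_radii=(26.0, 22.0),
        sat_thickness=5,
        lumbar_z=(6, 25),
        organ_count=2,
        seed=3,
    )
    ct, labels, vat, census = generate_phantom(spec)
    return spec, ct, labels, vat, census


def make_toy_case(rng=None):
    """A hand-sized scan: 6x6 SAT patch, an L3 marker, and 20 cavity voxels.

    Small enough that every pipeline quantity can be checked by direct
    enumeration.  Returns (ct, labels, cavity_index_array).
    """
    rng = rng or np.random.default_rng(42)
    shape = (20, 20, 5)
    lab = np.zeros(shape, dtype=np.int32)
    z = 2
    lab[2:8, 2:8, z] = 3  # subcutaneous_fat
    lab[9, 9, 1:4] = 8  # vertebra_L3 -> median z = 2
    cav = [(12 + i % 4, 12 + i // 4, z) for i in range(20)]
    for x, y, zz in cav:
        lab[x, y, zz] = 1  # abdominal_cavity
    ct = np.full(shape, -1000.0)
    ct[lab == 3] = rng.normal(-100, 20, size=(lab == 3).sum())
    hu = np.linspace(-140, 60, 20)  # cavity HU from adipose-like to organ-like
    for (x, y, zz), v in zip(cav, hu):
        ct[x, y, zz] = v
    spacing = (1.5, 1.5, 1.5)
    return CTVolume(ct, spacing), LabelMap(lab, spacing), np.array(cav)
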