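import numpy as np
import pytest

from cordquant.simulate import CellSpec, SectionSpec, make_section, random_cells


@pytest.fixture(scope="session")
def mirrored_iba1_section():
    """Section with identical cell layouts on both sides, ipsi peaks doubled.

    10 small + 8 large IBA1 cells per side; the contralesional side at peak
    8000, the ipsilesional mirror images at 16000 (a planted 2x intensity
    effect), zero noise.
    """
    rng = np.random.default_rng(0)
    contra = random_cells(
        10, 8, shape=(256, 256), channel="iba1", peak_intensity=8000.0, rng=rng, side="left"
    )
    ipsi = [
        CellSpec((c.center_px[0], 255 - c.center_px[1]), c.radius_px, 16000.0, "iba1")
        for c in contra
    ]
    spec = SectionSpec(seed=0, cells=tuple(contra) + tuple(ipsi))
    channels, truth = make_section(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def disk_fixture():
    """A single bright disk (radius 3, amplitude 100) on a flat background of 50."""
    img = np.full((64, 64), 50.0)
    rr, cc = np.mgrid[:64, :64]
    disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 3**2
    img[disk] += 100.0
    return img, disk
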