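import numpy as np
import pytest

from qctstiff import CTImage, DensityImage, ScannerModel, SpecimenSpec, generate_specimen
from qctstiff.voi import VOIMask


@pytest.fixture(scope="session")
def small_spec() -> SpecimenSpec:
    """Desk-scale specimen: 12 mm head in a 48x48x56 grid at 1 mm."""
    return SpecimenSpec(head_radius=12.0, cortical_thickness=2.0,
                        grid_shape=(48, 48, 56), spacing=(1.0, 1.0, 1.0),
                        muscle_thickness=6.0, adipose_thickness=5.0)


@pytest.fixture(scope="session")
def noiseless_specimen(small_spec):
    """Identity-scanner specimen shared by calibration/VOI tests."""
    return generate_specimen(small_spec, ScannerModel())


@pytest.fixture()
def cube_voi():
    """10 mm cube VOI at 1 mm voxels (the FE oracle geometry)."""
    return VOIMask(np.ones((10, 10, 10), bool), (1.0, 1.0, 1.0),
                   (0.5, 0.5, 0.5), depth=10.0)


def uniform_density(voi: VOIMask, value: float, tag: str = "uniform") -> DensityImage:
    return DensityImage(np.full(voi.shape, float(value)), voi.spacing,
                        voi.origin, calibration=tag)
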