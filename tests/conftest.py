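import numpy as np
import pytest

from deforecast.geodata import Raster


@pytest.fixture
def template_3x3() -> Raster:
    return Raster(np.zeros((3, 3)), (0.0, 90.0, 30.0), semantics="class_code")


@pytest.fixture
def template_10x10() -> Raster:
    return Raster(np.zeros((10, 10)), (0.0, 300.0, 30.0), semantics="class_code")


def make_raster(values, pixel_size=30.0, nodata=-9999.0, semantics="class_code"):
    values = np.asarray(values, dtype=float)
    nr = values.shape[0]
    return Raster(values, (0.0, nr * pixel_size, pixel_size), nodata, semantics)
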