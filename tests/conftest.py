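import numpy as np
import pytest

from lsradiomics import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def disk_phantom():
    """Noiseless soft-edged disk phantom with its ground-truth mask."""
    spec = PhantomSpec()
    img, mask = generate_phantom(spec)
    return spec, img, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


#: Window straddling the disk boundary (top of the lesion, boundary row 44);
#: used wherever the boundary gradient is estimated automatically.
BOUNDARY_WINDOW = (38, 54, 50, 74)
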