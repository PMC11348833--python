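import numpy as np
import pytest

from ppsim.optics import OpticalProperties, TissueClass


def make_medium(mu_a, mu_s, g=0.0, n=1.0, wavelengths=(460.0,), label=1, name="grey_matter"):
    """Single-class medium with identical properties at every wavelength."""
    return TissueClass(
        label=label,
        name=name,
        properties={
            float(wl): OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=n, wavelength=float(wl))
            for wl in wavelengths
        },
    )


@pytest.fixture
def medium_factory():
    return make_medium


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
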