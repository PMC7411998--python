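import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sideronet.spectra import Peak, Spectrum

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_spectrum(
    id="s",
    precursor=555.387,
    peaks=((100.0, 1.0), (200.0, 2.0), (300.0, 3.0)),
    source="sample",
):
    return Spectrum(
        id=id,
        precursor_mz=precursor,
        peaks=tuple(Peak(m, i) for m, i in peaks),
        source=source,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def random_spectrum(rng, id="r", n_peaks=None, precursor=None):
    n = int(rng.integers(1, 25)) if n_peaks is None else n_peaks
    mzs = np.sort(rng.uniform(60, 900, n))
    intens = rng.lognormal(3, 1, n)
    prec = float(rng.uniform(300, 1000)) if precursor is None else precursor
    return Spectrum(
        id=id, precursor_mz=prec, peaks=tuple(Peak(float(m), float(i)) for m, i in zip(mzs, intens))
    )
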