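import numpy as np
import pytest

import photokin as pk


@pytest.fixture
def scheme():
    return pk.default_scheme_pfr()


@pytest.fixture
def irf():
    return pk.InstrumentResponse(fwhm=60.0, t0=0.0)


@pytest.fixture
def vis_grid():
    delays = pk.default_delays()
    wavenumbers = np.linspace(10000.0, 16500.0, 80)
    return delays, wavenumbers


@pytest.fixture
def make_vis_dataset(scheme, irf, vis_grid):
    """Factory for default-scheme VIS datasets at a given noise level/seed."""
    delays, wavenumbers = vis_grid

    def _make(sigma=0.0, seed=0, channel="iso", oscillations=(), bands=None):
        return pk.simulate_ta(
            scheme,
            pk.default_bands_vis() if bands is None else bands,
            delays,
            wavenumbers,
            irf,
            noise=pk.NoiseSpec(sigma, seed) if sigma > 0 else None,
            oscillations=oscillations,
            channel=channel,
        )

    return _make


@pytest.fixture
def ir_irf():
    return pk.InstrumentResponse(fwhm=250.0, t0=0.0)


@pytest.fixture
def make_ir_dataset(scheme, ir_irf):
    delays = pk.default_delays()
    wavenumbers = np.arange(1630.0, 1921.0, 2.5)

    def _make(sigma=0.0, seed=0, channel="iso"):
        return pk.simulate_ta(
            scheme, pk.default_bands_ir(), delays, wavenumbers, ir_irf,
            noise=pk.NoiseSpec(sigma, seed) if sigma > 0 else None,
            channel=channel,
        )

    return _make
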