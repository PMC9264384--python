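import numpy as np
import pytest

from isolocate import Mobilogram, NSIEntry, NSISeries
from isolocate.peptide import FragmentIon


@pytest.fixture
def gaussian_trace():
    """Factory for a noise-free Gaussian Mobilogram on a dense ms grid."""

    def make(center=42.0, sigma=1.0, t0=35.0, t1=55.0, dt=0.05, scale=1000.0,
             **kw):
        t = np.arange(t0, t1 + dt / 2, dt)
        y = scale * np.exp(-0.5 * ((t - center) / sigma) ** 2)
        return Mobilogram(t, y, **kw)

    return make


@pytest.fixture
def series_factory():
    """Build an NSISeries (running_avg pre-filled with the given values)
    directly from a list of per-fragment values, y series on a 30-mer."""

    def make(values, length=30, series="y", start_n=1, fill_ra=True):
        s = NSISeries()
        for i, v in enumerate(values):
            if v is None:
                s.missing.append(start_n + i)
                continue
            frag = FragmentIon(series=series, n=start_n + i, z=1,
                               peptide_length=length)
            s.entries.append(NSIEntry(frag, float(v), charge_used=1))
            if fill_ra:
                s.running_avg[frag.n] = float(v)
        return s

    return make
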