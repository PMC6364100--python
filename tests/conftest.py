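import math

import numpy as np
import pytest

import phenoscreen as ps


@pytest.fixture(scope="session")
def library():
    return ps.make_compound_library()


@pytest.fixture(scope="session")
def standards(library):
    return ps.standards_only(library)


@pytest.fixture(scope="session")
def sample_contents():
    """Published per-sample contents as {sample: {code: mg/kg}} with
    missing cells dropped."""
    df = ps.load_sample_contents()
    return {str(i): {c: float(v) for c, v in row.items() if not math.isnan(v)}
            for i, row in df.iterrows()}


def gaussian_chromatogram(amplitude=1000.0, sigma=0.05, center=5.0,
                          span=(0.0, 10.0), dt=0.05, offset=0.0, rng=None,
                          noise=0.0):
    """Synthetic single-Gaussian trace, optionally noisy, built directly
    (independent of the simulator)."""
    rt = np.arange(span[0], span[1] + 1e-9, dt)
    y = amplitude * np.exp(-0.5 * ((rt - center) / sigma) ** 2) + offset
    if noise > 0:
        rng = rng or np.random.default_rng(0)
        y = np.clip(y + rng.normal(0, noise, y.shape), 0, None)
    return ps.Chromatogram(rt, y, "synthetic")
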