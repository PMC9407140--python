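import numpy as np
import pandas as pd
import pytest

from teaspec import SpectralAxis, SpectrumMatrix


@pytest.fixture
def axis20() -> SpectralAxis:
    """Small 20-band axis over the camera range."""
    return SpectralAxis.default(20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_matrix(values, axis, domain="reflectance") -> SpectrumMatrix:
    n = np.asarray(values).shape[0]
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "stage": ["withering"] * n,
        "time_h": np.arange(n, dtype=float),
        "replicate": [1] * n,
    })
    return SpectrumMatrix(values=values, axis=axis, metadata=meta,
                          domain=domain)


@pytest.fixture
def matrix_factory():
    return make_matrix
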