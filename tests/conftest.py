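import numpy as np
import pytest

from furrowkit import KVParams, MMParams


@pytest.fixture
def wt_mm_params() -> MMParams:
    """Michaelis-Menten truth of the phosphorylated wild-type-like motor."""
    return MMParams(k_basal=0.010, k_cat=1.23, K_app=38.9)


@pytest.fixture
def kv_params() -> KVParams:
    """Kelvin-Voigt truth with amplitude 2 µm and tau 5 s (v0 = 0.4 µm/s)."""
    return KVParams(T=2.0, zeta=1.0, eta=5.0)


@pytest.fixture
def actin_range() -> list[float]:
    """Eight actin concentrations spanning 0-100 µM."""
    return [0.0, 2.5, 5.0, 10.0, 20.0, 40.0, 70.0, 100.0]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
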