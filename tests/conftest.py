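import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netpredict.data import MixedDataset, VariableSpec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def mixed3() -> MixedDataset:
    """Tiny deterministic dataset: gaussian, binary, gaussian."""
    rng = np.random.default_rng(42)
    g1 = rng.normal(size=30)
    b = rng.integers(1, 3, size=30).astype(float)
    b[:2] = [1, 2]  # both levels guaranteed
    g2 = rng.normal(size=30)
    values = np.column_stack([g1, b, g2])
    specs = [
        VariableSpec("x", "gaussian"),
        VariableSpec("flag", "categorical", 2),
        VariableSpec("y", "gaussian"),
    ]
    return MixedDataset(values, specs)


@pytest.fixture
def gauss4() -> MixedDataset:
    rng = np.random.default_rng(7)
    values = rng.normal(size=(50, 4))
    specs = [VariableSpec(f"g{j}", "gaussian") for j in range(4)]
    return MixedDataset(values, specs)
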