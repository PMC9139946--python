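import numpy as np
import pytest

from pdcsp.synthetic import SynthSpec, generate_dataset


def random_spd(rng: np.random.Generator, ch: int) -> np.ndarray:
    """Random symmetric positive-definite matrix with unit trace."""
    G = rng.standard_normal((ch, ch + 2))
    C = G @ G.T + 1e-3 * np.eye(ch)
    return C / np.trace(C)


@pytest.fixture(scope="session")
def separable_spec() -> SynthSpec:
    """Default study conditions: 8 channels, strong planted separation."""
    return SynthSpec()


@pytest.fixture(scope="session")
def separable_dataset(separable_spec):
    return generate_dataset(separable_spec)


@pytest.fixture(scope="session")
def null_spec() -> SynthSpec:
    return SynthSpec(separation=0.0)


@pytest.fixture(scope="session")
def null_dataset(null_spec):
    return generate_dataset(null_spec)


@pytest.fixture(scope="session")
def small_dataset():
    """Quick separable dataset for structural tests (fewer segments)."""
    spec = SynthSpec(duration_s=30.0, n_recordings=2)
    return generate_dataset(spec)
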