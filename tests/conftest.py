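import numpy as np
import pytest

from sigmascan import MotifModel, default_sigma_motif


@pytest.fixture(scope="session")
def sigma_motif() -> MotifModel:
    """The built-in sigma-factor-like width-20 motif used by the simulator."""
    return default_sigma_motif()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_ppm(rng: np.random.Generator, width: int) -> np.ndarray:
    return rng.dirichlet(np.ones(4), size=width)


def sample_from_ppm(rng: np.random.Generator, p: np.ndarray) -> str:
    return "".join("ACGT"[rng.choice(4, p=row)] for row in p)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[k] for k in rng.integers(0, 4, n))
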