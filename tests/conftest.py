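import numpy as np
import pytest

from pbsquench.config import DEFAULT_LINESHAPES
from pbsquench.kinetics import RateMatrix, detailed_balance_pair
from pbsquench.spectra import LineShape, ShapeKind
from pbsquench.synthetic import ToyPBSConfig, make_toy_pbs


@pytest.fixture(scope="session")
def lineshapes():
    return {
        name: LineShape(ShapeKind.ABSORPTION, 15000.0, comps)
        for name, comps in DEFAULT_LINESHAPES.items()
    }


@pytest.fixture(scope="session")
def toy_network():
    return make_toy_pbs(ToyPBSConfig())


@pytest.fixture(scope="session")
def unquenched_network():
    return make_toy_pbs(ToyPBSConfig(n_can=0))


def balanced_random_rates(
    n: int, energies: np.ndarray, temperature: float, rng: np.random.Generator,
    decay: np.ndarray | None = None,
) -> RateMatrix:
    """Random detailed-balanced rate matrix over given site energies."""
    transfer = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            hi, lo = (i, j) if energies[i] >= energies[j] else (j, i)
            k_down = float(rng.uniform(0.05, 1.0))
            transfer[hi, lo] = k_down
            transfer[lo, hi] = detailed_balance_pair(
                k_down, energies[hi] - energies[lo], temperature
            )
    if decay is None:
        decay = np.zeros(n)
    return RateMatrix(transfer, decay, [f"p{i}" for i in range(n)], temperature)
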