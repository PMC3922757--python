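import numpy as np
import pytest
from hypothesis import settings

from hocca import CoupledBasis, SourcePairParams, generate_coupled_data

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def random_orthonormal(d, rng):
    Q, R = np.linalg.qr(rng.standard_normal((d, d)))
    return Q * np.sign(np.diag(R))


@pytest.fixture(scope="session")
def small_problem():
    """A seeded d=5 coupled estimation problem with known ground truth."""
    pairs = [
        SourcePairParams(rho, nu)
        for rho, nu in [(0.8, 2.5), (0.6, 3.0), (-0.5, 2.3), (0.3, 3.5), (0.9, 2.8)]
    ]
    rng = np.random.default_rng(1)
    A_x = random_orthonormal(5, rng)
    A_y = random_orthonormal(5, rng)
    basis = CoupledBasis(W_x=A_x, W_y=A_y, pairs=pairs)
    data = generate_coupled_data(basis, 20_000, seed=3)
    return {"basis": basis, "pairs": pairs, "A_x": A_x, "A_y": A_y, "data": data}
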