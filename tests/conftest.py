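import numpy as np
import pytest

from cropcal import build_default_space, make_synthetic_case


@pytest.fixture(scope="session")
def space():
    return build_default_space()


@pytest.fixture(scope="session")
def case():
    """One seeded synthetic case shared by read-only tests."""
    return make_synthetic_case(1)


@pytest.fixture(scope="session")
def linear_gaussian():
    """Linear forward model with a known Gaussian posterior.

    Uniform box prior wide enough that truncation is negligible, so the
    exact posterior is N(mpost, Cpost) with Cpost = (H^T R^-1 H)^-1.
    """
    rng = np.random.default_rng(7)
    H = rng.normal(size=(3, 2))
    R = 0.04 * np.eye(3)
    truth = np.array([0.7, -0.4])
    d_obs = H @ truth + rng.normal(0, 0.2, 3)
    bounds = np.array([[-20.0, 20.0], [-20.0, 20.0]])
    Cpost = np.linalg.inv(H.T @ np.linalg.inv(R) @ H)
    mpost = Cpost @ H.T @ np.linalg.inv(R) @ d_obs

    def model(M):
        return np.atleast_2d(M) @ H.T

    return {"H": H, "R": R, "d_obs": d_obs, "bounds": bounds,
            "Cpost": Cpost, "mpost": mpost, "model": model}
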