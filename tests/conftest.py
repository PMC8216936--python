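import numpy as np
import pytest

import openscr
from openscr import mcmc


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def micro_sim():
    """Tiny study (M=4, T=2, G=4, K=1, one platform, one group) whose
    discrete latent space can be enumerated exhaustively."""
    scn = openscr.SimulationScenario(
        n_x=2, n_y=2, side=1.0, T=2, K=1, M=4, n_transects=2,
        J=1, add_squares=False, beta=(0.5,),
        beta_gamma=((0.0, 0.3, -0.2),), beta_phi=((0.5, 0.2),),
        sigma_move=(1.0,), p0=((0.7,),), sigma_det=(0.8,))
    return openscr.simulate_study(scn, 7)


@pytest.fixture(scope="session")
def micro_params(micro_sim):
    scn = micro_sim.scenario
    return mcmc.ModelParams(
        beta_gamma=np.array(scn.beta_gamma, float),
        beta_phi=np.array(scn.beta_phi, float),
        beta_density=np.array(scn.beta, float),
        beta_move=np.array(scn.beta, float),
        sigma_move=np.array(scn.sigma_move, float),
        sigma_det=np.array(scn.sigma_det, float),
        b_det=np.array(scn.b_det, float),
        pi_group=np.array([1.0]),
        p0=np.array(scn.p0, float))


@pytest.fixture(scope="session")
def small_sim():
    """Small single-group study for fast end-to-end sampler runs."""
    scn = openscr.SimulationScenario(
        n_x=8, n_y=8, T=3, K=2, M=40, n_transects=4,
        J=2, add_squares=False, beta=(0.5, -0.3))
    return openscr.simulate_study(scn, 2)
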