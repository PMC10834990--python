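import warnings

import numpy as np
import pytest
from hypothesis import settings

from debipm import (Environment, KernelSet, Mesh, SpeciesTraits,
                    build_kernels, generate_fixture)
from debipm.ipm import MassEvictionWarning

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_mass_warning():
    """The 3-sigma offspring truncation always trips the lost-mass warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MassEvictionWarning)
        yield


@pytest.fixture
def shark_traits():
    """A plausible large, slow ectotherm (the worked-example parameter set)."""
    return SpeciesTraits(record_id="SHARK1", species="Testudo exemplaris",
                         kappa=0.8, L_b=30.0, L_p=100.0, L_m=200.0,
                         mu_j=0.2, mu_a=0.1, r_B=0.2, R_m=5.0)


@pytest.fixture
def env_high():
    return Environment(E_Y=0.9)


@pytest.fixture
def shark_kernels(shark_traits, env_high):
    return build_kernels(shark_traits, env_high)


@pytest.fixture(scope="session")
def fixture_table():
    return generate_fixture(50, seed=1)


def two_stage_toy(p=0.3, s=0.6, f=2.0) -> KernelSet:
    """Juvenile matures with probability p (or dies), adult survives with
    probability s and produces f recruits per year.  Closed form:
    R0 = p*f/(1-s)."""
    mesh = Mesh(n_bins=2, lower=0.0, upper=2.0)
    return KernelSet(
        mesh=mesh,
        S_diag=np.array([p, s]),
        G=np.array([[0.0, 0.0], [1.0, 1.0]]),
        R_diag=np.array([0.0, f]),
        D=np.array([[0.0, 1.0], [0.0, 0.0]]),
        adult_mask=np.array([False, True]),
        birth_index=0,
        puberty_index=1,
    )
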