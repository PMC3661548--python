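import numpy as np
import pytest

import morphmix as mm

# Published component parameters for the dimorphic male trait
# (homeomorphic: right-facing above 0.48 mm; heteromorphic: left-facing
# below 2.25 mm).
HOMEO = dict(shape=1.91, scale=0.163, bound=0.48)
HETERO = dict(shape=2.88, scale=0.201, bound=2.25)


@pytest.fixture(scope="session")
def homeo_component() -> mm.FacingGammaComponent:
    return mm.right_facing(HOMEO["shape"], HOMEO["scale"], HOMEO["bound"])


@pytest.fixture(scope="session")
def hetero_component() -> mm.FacingGammaComponent:
    return mm.left_facing(HETERO["shape"], HETERO["scale"], HETERO["bound"])


@pytest.fixture(scope="session")
def reference_model(homeo_component, hetero_component) -> mm.MixtureModel:
    """The published mixture with a neutral 0.5 mixing weight."""
    return mm.MixtureModel(0.5, homeo_component, hetero_component)


@pytest.fixture(scope="session")
def bimodal_sample(reference_model) -> np.ndarray:
    """n=2000 male trait values from the reference mixture, fixed seed."""
    rng = np.random.default_rng(20)
    return reference_model.sample(2000, rng)


@pytest.fixture(scope="session")
def fitted_model(bimodal_sample) -> mm.MixtureModel:
    """One mixture fit shared across tests (fitting is the slow step)."""
    return mm.fit_mixture(bimodal_sample, mm.FitConfig())
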