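import numpy as np
import pytest

from cumob.synthetic import LakeScenario, generate_campaign


@pytest.fixture(scope="session")
def default_scenario():
    return LakeScenario(seed=42)


@pytest.fixture(scope="session")
def synthetic_campaign(default_scenario):
    """One noisy campaign plus its closed-form ground truth (seed 42)."""
    return generate_campaign(default_scenario)


@pytest.fixture()
def linear_profile():
    """Simple uncensored linear nM profile for integration/gradient tests."""
    from cumob.profiles import DepthProfile

    z = np.linspace(0.0, 10.0, 21)
    return DepthProfile(
        analyte="Cu", fraction="dissolved", depths=z, values=15.0 - z, unit="nM"
    )
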