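import numpy as np
import pytest

from chromaglare.cam import CamSettings, CamStimulus
from chromaglare.scene import SunModel, make_glazing, sun_stimulus_color

#: Sun-window photopic transmittances of the low-transmittance group.
LOW_TAU_V = {"blue": 0.0039, "green": 0.0040, "red": 0.0033, "neutral": 0.0038}


@pytest.fixture(scope="session")
def sun():
    return SunModel()


@pytest.fixture(scope="session")
def glazings():
    return {c: make_glazing(c, t) for c, t in LOW_TAU_V.items()}


@pytest.fixture(scope="session")
def sun_stimuli(sun, glazings):
    """The four colored-sun stimuli normalized to 1000 cd/m^2."""
    return {c: CamStimulus.from_color(sun_stimulus_color(sun, g, 1000.0))
            for c, g in glazings.items()}


@pytest.fixture(scope="session")
def cam_settings(sun_stimuli):
    return CamSettings(white_point=sun_stimuli["neutral"].color)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
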