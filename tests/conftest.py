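import numpy as np
import pytest

from odfpbpk.oral import calibrate_mucosa_scales, default_dog_mouth
from odfpbpk.parameters import beagle_risperidone_fixture
from odfpbpk.gut import default_dog_gut

#: Reported oral-mucosal absorption anchors used for calibration (fraction
#: of dose at 2- and 10-min residence).
ORAL_ANCHORS = (0.070, 0.195)


@pytest.fixture(scope="session")
def params():
    return beagle_risperidone_fixture()


@pytest.fixture(scope="session")
def mouth():
    return default_dog_mouth()


@pytest.fixture(scope="session")
def gut():
    return default_dog_gut()


@pytest.fixture(scope="session")
def calibrated_scales(params):
    """Mucosa scales calibrated once per session to the reported anchors."""
    return calibrate_mucosa_scales(params, *ORAL_ANCHORS)
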