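import numpy as np
import pytest

from cascadeflim import FluorophorePair, ForceCalibration
from cascadeflim.simulate import DEFAULT_TS_PAIR, DEFAULT_TS_R_TL_NM


@pytest.fixture(scope="session")
def three_colour_pairs():
    """Fluorophore pair parameters of the purified three-colour construct:
    intrinsic donor lifetimes and Förster radii."""
    return {
        ("mTurq2", "mVenus"): FluorophorePair("mTurq2", "mVenus", tau_D_ns=4.178, R0_nm=5.83),
        ("mTurq2", "mScarlet"): FluorophorePair("mTurq2", "mScarlet", tau_D_ns=4.178, R0_nm=5.08),
        ("mVenus", "mScarlet"): FluorophorePair("mVenus", "mScarlet", tau_D_ns=3.020, R0_nm=5.53),
    }


@pytest.fixture(scope="session")
def ts_pair():
    return DEFAULT_TS_PAIR


@pytest.fixture(scope="session")
def ts_calibration():
    return ForceCalibration(linker_n=40, r_TL_nm=DEFAULT_TS_R_TL_NM)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
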