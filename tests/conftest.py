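import numpy as np
import pytest

import dcekit as dk


@pytest.fixture(scope="session")
def schedule():
    return dk.default_schedule()


@pytest.fixture(scope="session")
def plasma_aif(schedule):
    """Noise-free arterial plasma input on the burst schedule."""
    blood = dk.generate_aif(schedule, bolus_arrival_s=20.0)
    return dk.blood_to_plasma(blood, dk.Hematocrit(0.45))


@pytest.fixture(scope="session")
def dense_plasma_aif():
    """The same population input on a dense 0.5-s grid, for oracles."""
    t = np.arange(-30.0, 630.0, 0.5)
    blood = dk.generate_aif(dk.default_schedule(), 20.0)
    dense = np.interp(t, blood.times, blood.values)
    curve = dk.ConcentrationCurve("aif_dense", t, dense, "arterial_blood")
    return dk.blood_to_plasma(curve, dk.Hematocrit(0.45))


@pytest.fixture(scope="session")
def cohort_table():
    """The packaged 11-patient / 21-lesion study table."""
    return dk.load_study_table()
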