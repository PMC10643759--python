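import numpy as np
import pytest

from respeffort import (CohortSpec, EffortProfile, PatientParams,
                        VentSettings, simulate_breaths, simulate_occlusion,
                        simulate_titration)


@pytest.fixture(scope="session")
def std_patient():
    return PatientParams(ers=25.0, ecw=15.0, rrs=10.0, peepi=0.0, pes_ee=8.0)


@pytest.fixture(scope="session")
def std_vent():
    return VentSettings(ps=8.0, peep=5.0)


@pytest.fixture(scope="session")
def std_effort():
    return EffortProfile(pmus_max=8.0, respiratory_rate=18.0)


@pytest.fixture(scope="session")
def free_breathing(std_patient, std_vent, std_effort):
    """60 s of clean pressure-support breathing with ground truth."""
    return simulate_breaths(std_patient, std_vent, std_effort,
                            duration=60.0, seed=1)


@pytest.fixture(scope="session")
def ee_occlusion(std_patient, std_vent, std_effort):
    """Recording containing one end-expiratory hold."""
    return simulate_occlusion(std_patient, std_vent, std_effort,
                              "end_expiratory", 1.2, duration=25.0, seed=1)


@pytest.fixture(scope="session")
def ei_occlusion(std_patient, std_vent, std_effort):
    """Recording containing one end-inspiratory hold."""
    return simulate_occlusion(std_patient, std_vent, std_effort,
                              "end_inspiratory", 2.5, duration=25.0, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient titration cohort at the default study conditions."""
    return simulate_titration(CohortSpec(n_patients=6), seed=7)


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort):
    from respeffort.pipeline import analyze_dataset
    return analyze_dataset(small_cohort)
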