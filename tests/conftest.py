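import numpy as np
import pytest
from hypothesis import settings

from ecusim.parameters import IndividualParameters, PopulationModel
from ecusim.population import VirtualSubject

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def pop() -> PopulationModel:
    return PopulationModel()


@pytest.fixture()
def typical_ind(pop) -> IndividualParameters:
    """A 70-kg subject at the population typical values (no variability)."""
    return IndividualParameters(
        subject_id=0, cl_i=pop.pk.cl_typ, v_i=pop.pk.v_typ,
        vmax_i=pop.pk.vmax_typ, km_i=pop.pk.km,
        base_i=pop.pd.base, ic50_i=pop.pd.ic50,
        gamma_i=pop.pd.gamma, imax_i=pop.pd.imax)


@pytest.fixture()
def linear_ind(typical_ind) -> IndividualParameters:
    """Same subject with the saturable pathway switched off."""
    typical_ind.vmax_i = 0.0
    return typical_ind


@pytest.fixture()
def adult_subject() -> VirtualSubject:
    return VirtualSubject(subject_id=0, age=40.0, sex="female",
                          weight=70.0, height=165.0)
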