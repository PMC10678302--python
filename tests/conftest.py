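import datetime as dt

import numpy as np
import pytest

from gtbudget.registry import DiseaseRecord, Registry, TrialRecord, generate_registry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_registry():
    """A 10-disease, 20-trial synthetic registry used across tests."""
    return generate_registry(n_diseases=10, n_trials=20, seed=42)


def make_single_disease_registry(
    *,
    category="rare",
    therapeutic_area="CNS",
    incidence_i=120.0,
    prevalence_j=0.0,
    delta_qaly=10.0,
    prior_approval=True,
    age_mix=None,
    trial_end=dt.date(2019, 6, 1),
):
    """One disease with one program/trial; defaults give a closed-form
    spending plateau when dispersion and lags are switched off."""
    disease = DiseaseRecord(
        disease_id="D0",
        name="single",
        category=category,
        therapeutic_area=therapeutic_area,
        incidence_i=incidence_i,
        prevalence_j=prevalence_j,
        survival_p=0.5,
        survival_k=5.0,
        age_mix=age_mix or {"minor": 0.2, "adult": 0.5, "elderly": 0.3},
        delta_qaly=delta_qaly,
        prior_approval=prior_approval,
    )
    trial = TrialRecord(
        trial_id="T0", disease_id="D0", program_id="D0-P0", phase="3",
        start_date=dt.date(2017, 1, 1), end_date=trial_end,
    )
    return Registry(diseases=[disease], trials=[trial])
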