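import pytest

import tt1screen as t


@pytest.fixture(scope="session")
def patients():
    """The thirteen confirmed TT1 patients shipped with the package."""
    return t.patient_fixtures()


@pytest.fixture(scope="session")
def patient_panels(patients):
    return [t.compute_panel(r) for r in patients]


@pytest.fixture(scope="session")
def catalogue():
    return t.builtin_protocols()


@pytest.fixture(scope="session")
def small_enriched():
    """Enriched evaluation cohort with a reduced TN background: the referral
    strata (which set every FP/TP count) are at full published size."""
    return t.make_enriched_cohort(seed=7, n_tn=5_000)
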