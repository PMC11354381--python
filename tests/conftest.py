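import pytest

from amlreclass import GeneSetRegistry, fixture_cohort, fixture_table3
from amlreclass.classify import variants_by_patient


@pytest.fixture(scope="session")
def genes():
    return GeneSetRegistry.default()


@pytest.fixture(scope="session")
def cohort():
    """(patients, variants) of the deterministic 69-patient fixture."""
    return fixture_cohort()


@pytest.fixture(scope="session")
def patients(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def variants(cohort):
    return cohort[1]


@pytest.fixture(scope="session")
def olo_by_patient(variants):
    return {pid: [v for v in vs if v.is_olo]
            for pid, vs in variants_by_patient(variants).items()}


@pytest.fixture(scope="session")
def table3():
    """(segments, variants, loci) of the packaged CN-LOH table."""
    return fixture_table3()
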