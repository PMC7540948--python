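import numpy as np
import pytest

from socmort.records import IndividualRecord, records_from_frame


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_record(id="A", sex="F", birth=2000.0, entry=None, last=2012.0,
                fate="death", origin="natal", bracket=0.0):
    """Shorthand IndividualRecord with decimal-year dates."""
    if entry is None:
        entry = birth + {"F": 5.0, "M": 7.0}[sex]
    return IndividualRecord(
        id=id, sex=sex, birth_min=birth - bracket / 2, birth_max=birth + bracket / 2,
        entry=entry, last=last, fate=fate, origin=origin)


@pytest.fixture
def small_cohort():
    """Simulated small two-sex cohort (individuals df, records, covariates, truth)."""
    from socmort.simulate import SimConfig, simulate_population

    cfg = SimConfig(n_females=60, n_males=60, seed=77)
    individuals, covariates, truth = simulate_population(cfg)
    records = records_from_frame(individuals)
    return individuals, records, covariates, truth
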