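import numpy as np
import pytest

import tinnidyn as td
from tinnidyn.diary import N_DAYS, QUESTION_CODES, PatientDiary


def make_diary(pid="p1", days=None, value_fn=None) -> PatientDiary:
    """Complete-by-default diary; value_fn(question, day) -> VAS value."""
    days = range(N_DAYS) if days is None else days
    if value_fn is None:
        rng = np.random.default_rng(abs(hash(pid)) % 2**31)
        noise = {q: rng.uniform(20, 80, N_DAYS) for q in QUESTION_CODES}
        value_fn = lambda q, d: float(noise[q][d])
    series = {q: [(d, value_fn(q, d)) for d in days] for q in QUESTION_CODES}
    return PatientDiary(patient_id=pid, series=series)


@pytest.fixture(scope="session")
def small_cohort():
    """Fixed-seed synthetic cohort shared across tests (n=60)."""
    return td.generate(td.SyntheticConfig(n_patients=60, seed=49))


@pytest.fixture(scope="session")
def design_cohort():
    """Medium synthetic cohort with extracted features, for model tests."""
    diaries, outcomes, truth = td.generate(td.SyntheticConfig(n_patients=120, seed=11))
    from tinnidyn.pipeline import prepare_design

    F, y, ids = prepare_design(diaries, outcomes, 0.50)
    return F, y, ids, truth
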