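"""Shared fixtures: small seeded synthetic cohorts and hand-built records."""

from datetime import date, timedelta

import pytest

from straticare.cohort import ClientRecord
from straticare.synthetic import CohortConfig, generate_cohort


def make_record(client_id="c0", *, modality="LICBT", delivery_format="ecbt",
                phq9=((0, 15), (60, 8)), gad7=((0, 13), (60, 7)),
                admission=date(2019, 1, 1), **kwargs) -> ClientRecord:
    """A valid record with sensible defaults; scores given as (day, score)."""
    defaults = dict(
        age_at_admission=34.0, sex="female", employment="employed",
        living_arrangement="by_self", instability_q=1, deprivation_q=1,
        dependency_q=1, ethnic_concentration_q=1,
    )
    defaults.update(kwargs)
    return ClientRecord(
        client_id=client_id,
        modality=modality,
        delivery_format=delivery_format,
        admission_date=admission,
        phq9_scores=[(admission + timedelta(days=d), s) for d, s in phq9],
        gad7_scores=[(admission + timedelta(days=d), s) for d, s in gad7],
        **defaults,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """400 clients, seeded; shared across read-only tests."""
    return generate_cohort(CohortConfig(n_clients=400, seed=11))


@pytest.fixture(scope="session")
def medium_cohort():
    """2000 clients for margin-fidelity and oracle checks."""
    return generate_cohort(CohortConfig(n_clients=2000, seed=7))
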