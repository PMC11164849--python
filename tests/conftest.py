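import datetime as dt

import pytest

from borg_anchor.cohort_io import CPXRecord, StageMeasurement


def make_record(
    participant_id="P1",
    blas=(1.0, 1.2, 1.8, 2.6, 3.8, 5.4),
    rpes=(8, 9, 11, 13, 15, 17),
    loads=None,
    resting_bla=1.0,
    sex="male",
    ergometry="bicycle",
    test_date=dt.date(2018, 3, 1),
    age=35.0,
    height_cm=178.0,
    weight_kg=75.0,
    vo2max=40.0,
):
    """Hand-sized CPX record; lactate/RPE sequences are positional."""
    loads = loads or [50.0 + 25.0 * i for i in range(len(blas))]
    stages = [
        StageMeasurement(stage_index=i + 1, load=loads[i], bla=blas[i], rpe=rpes[i])
        for i in range(len(blas))
    ]
    return CPXRecord(
        participant_id=participant_id,
        test_date=test_date,
        age=age,
        sex=sex,
        ergometry=ergometry,
        height_cm=height_cm,
        weight_kg=weight_kg,
        vo2max=vo2max,
        resting_bla=resting_bla,
        stages=stages,
    )


@pytest.fixture
def simple_record():
    return make_record()


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 300-record synthetic cohort shared across tests."""
    from borg_anchor.synthetic import default_config, generate_cohort

    return generate_cohort(default_config(n=300, seed=17))
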