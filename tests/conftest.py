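from datetime import datetime

import pytest

from iciss import Cohort, PatientRecord, generate_cohort, titco_like_spec


def record(pid, injuries=(), died_30d=False, died_24h=False, day=1, **kw):
    """Fully observed patient with short-hand defaults."""
    defaults = dict(
        arrival=datetime(2014, 1, day),
        age=30.0,
        sex="male",
        mechanism="rti",
        transferred=False,
    )
    defaults.update(kw)
    return PatientRecord(
        patient_id=pid,
        injuries=tuple(injuries),
        died_30d=died_30d,
        died_24h=died_24h,
        **defaults,
    )


@pytest.fixture
def tiny_cohort():
    """Six fully observed patients over six days, three 30-day deaths."""
    return Cohort(
        [
            record("p1", ["S065", "S720"], day=1),
            record("p2", ["S065"], died_30d=True, died_24h=True, day=2),
            record("p3", [], day=3),
            record("p4", ["S720", "S720"], day=4),
            record("p5", ["S065", "T141"], died_30d=True, day=5),
            record("p6", ["T141"], died_30d=True, died_24h=True, day=6),
        ]
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A 2,000-patient registry-like cohort, fixed seed, shared read-only."""
    return generate_cohort(titco_like_spec(11, n_patients=2000))
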