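import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ginsengq import BinSpec, StudyRecord

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def bin_spec():
    return BinSpec((1.0, 2.0, 4.0, 8.0))


def make_record(
    record_id="R1",
    subject="red",
    function="Enhanced Immunity",
    experiment_type="in vivo",
    n_bioassays=3,
    impact_factor=2.5,
    score=None,
):
    return StudyRecord(
        record_id=record_id,
        subject=subject,
        function=function,
        experiment_type=experiment_type,
        n_bioassays=n_bioassays,
        impact_factor=impact_factor,
        score=score,
    )


@pytest.fixture
def record_factory():
    return make_record


def random_records(rng, n, subjects=("black", "red"), functions=("Enhanced Immunity",)):
    """Random but valid study records for property tests."""
    recs = []
    for k in range(n):
        recs.append(
            make_record(
                record_id=f"R{k}",
                subject=subjects[rng.integers(len(subjects))],
                function=functions[rng.integers(len(functions))],
                experiment_type=("in vitro", "in vivo", "human")[rng.integers(3)],
                n_bioassays=int(rng.integers(0, 12)),
                impact_factor=float(rng.uniform(0, 12)) if rng.random() > 0.1 else None,
            )
        )
    return recs


@pytest.fixture
def random_record_factory():
    return random_records
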