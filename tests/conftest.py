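import numpy as np
import pytest

from prernadx.cohort import SampleRecord, SimConfig, generate_cohort


def make_case(sid, age, ttd, *, sex="male", bdg="BDg1", histology="NSCLC",
              individual=None, smoking="current", stage="early"):
    return SampleRecord(
        sample_id=sid,
        individual_id=individual or f"ind_{sid}",
        group="case",
        histology=histology,
        stage=stage,
        sex=sex,
        age_at_donation=age,
        age_at_diagnosis=age + ttd,
        time_to_diagnosis=ttd,
        smoking=smoking,
        bdg=bdg,
    )


def make_control(sid, age, *, sex="male", bdg="BDg1", individual=None,
                 smoking="former"):
    return SampleRecord(
        sample_id=sid,
        individual_id=individual or f"ind_{sid}",
        group="control",
        histology="none",
        stage="none",
        sex=sex,
        age_at_donation=age,
        age_at_diagnosis=None,
        time_to_diagnosis=None,
        smoking=smoking,
        bdg=bdg,
    )


SMALL_FEATURES = {
    "miRNA": 10, "isomiR": 20, "miscRNA": 4, "piRNA": 8,
    "snoRNA": 4, "tRF": 10, "mRNA": 8, "lncRNA": 2,
}


@pytest.fixture(scope="session")
def small_cohort():
    """A small null cohort for structural tests (no planted signal)."""
    cfg = SimConfig(
        n_case_individuals=30,
        n_control_individuals=40,
        features_per_class=dict(SMALL_FEATURES),
        seed=123,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
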