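import pytest
from hypothesis import HealthCheck, settings

from menoderive import (
    MenopauseResponse,
    MHTUse,
    ParticipantRecord,
    YesNoMissing,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_record(
    participant_id="p1",
    age_at_baseline=60.0,
    menopause=MenopauseResponse.YES,
    mht=MHTUse.NEVER,
    hysterectomy=YesNoMissing.NO,
    oophorectomy=YesNoMissing.NO,
    oc_current=YesNoMissing.NO,
    age_at_menopause=50.0,
    age_started_mht=None,
    age_at_hysterectomy=None,
    age_at_oophorectomy=None,
) -> ParticipantRecord:
    """A well-formed natural-menopause record, with overridable fields."""
    return ParticipantRecord(
        participant_id=participant_id,
        age_at_baseline=age_at_baseline,
        menopause=menopause,
        mht=mht,
        hysterectomy=hysterectomy,
        oophorectomy=oophorectomy,
        oc_current=oc_current,
        age_at_menopause=age_at_menopause,
        age_started_mht=age_started_mht,
        age_at_hysterectomy=age_at_hysterectomy,
        age_at_oophorectomy=age_at_oophorectomy,
    )


@pytest.fixture
def record_factory():
    return make_record
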