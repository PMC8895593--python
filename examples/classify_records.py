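"""Classify individual questionnaire records into the seven detailed statuses.

Each record combines the self-reported menopause response with intervention
responses and event ages; the classifier orders the events to decide whether
an intervention masks menopause.
"""

from menoderive import (
    MenopauseResponse as MR,
    MHTUse,
    ParticipantRecord,
    YesNoMissing as YN,
    classify_detailed,
)

women = [
    # menopause at 50, no interventions: natural menopause
    ParticipantRecord("natural", 60.0, MR.YES, MHTUse.NEVER, YN.NO, YN.NO, YN.NO,
                      age_at_menopause=50.0),
    # hysterectomy at 45, reports menopause at 50: periods ended by surgery
    ParticipantRecord("hyst", 62.0, MR.YES, MHTUse.NEVER, YN.YES, YN.NO, YN.NO,
                      age_at_menopause=50.0, age_at_hysterectomy=45.0),
    # started MHT at 47, menopause reported at 52: MHT obscured the transition
    ParticipantRecord("mht", 58.0, MR.YES, MHTUse.FORMER, YN.NO, YN.NO, YN.NO,
                      age_at_menopause=52.0, age_started_mht=47.0),
    # not sure, bilateral oophorectomy: surgery caused menopause
    ParticipantRecord("ooph", 55.0, MR.NOT_SURE, MHTUse.NEVER, YN.NO, YN.YES, YN.NO,
                      age_at_oophorectomy=44.0),
    # says no to menopause despite oophorectomy: assumed unilateral, pre-menopause
    ParticipantRecord("uni", 48.0, MR.NO, MHTUse.NEVER, YN.NO, YN.YES, YN.NO,
                      age_at_oophorectomy=40.0),
    # reports menopause but the hysterectomy age is missing: order undecidable
    ParticipantRecord("unk", 60.0, MR.YES, MHTUse.NEVER, YN.YES, YN.NO, YN.NO,
                      age_at_menopause=None, age_at_hysterectomy=None),
]

for record in women:
    result = classify_detailed(record)
    flags = ", ".join(sorted(result.flags)) or "-"
    print(f"{record.participant_id:<8} -> {result.detailed.value:<28} flags: {flags}")

# The detailed status distinguishes women whose self-report is reliable
# (natural/peri/pre-menopause) from those whose status an intervention masks
# and from records too incomplete or inconsistent to classify (unknown).
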