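"""Step 2 — assign the seven-category detailed derived menopausal status.

The classifier combines the directly self-reported menopause response with
the three intervention responses and the ordering of event ages (age at
menopause, at MHT start, at hysterectomy, at oophorectomy). The seven
categories are:

* ``NATURAL_MENOPAUSE`` — menopause without any masking intervention before
  the final menstrual period;
* ``PERI_MENOPAUSE`` — the transition phase (irregular periods);
* ``PRE_MENOPAUSE`` — periods continuing, no masking intervention;
* ``MHT_BEFORE_PERIODS_STOPPED``, ``NO_PERIODS_HYSTERECTOMY`` — the two
  statuses in which an intervention masks whether menopause has occurred;
* ``MENOPAUSE_FROM_OOPHORECTOMY`` — menopause induced by bilateral
  oophorectomy (masked only when menopause is not itself self-reported,
  since that combination may indicate a unilateral procedure);
* ``UNKNOWN`` — missing core responses, missing event ages for a reported
  intervention, or internally inconsistent responses. Every ``UNKNOWN``
  carries at least one machine-readable reason flag.

All rule choices that the questionnaire alone cannot settle (the priority
order among interventions for "not sure" responders, where irregular
periods plus surgery should land, whether an oophorectomy must coincide
with the reported menopause age) are exposed on
:class:`ClassificationPolicy` with defaults chosen to reproduce the
published cohort behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import TYPE_CHECKING, Optional, Sequence

from .interventions import InterventionCategory, assign_intervention_category
from .records import (
    EVENT_AGE_SLACK,
    MenopauseResponse,
    MHTUse,
    ParticipantRecord,
    YesNoMissing,
)

if TYPE_CHECKING:  # pragma: no cover
    from .consolidate import ConsolidatedStatus


class DetailedStatus(str, Enum):
    NATURAL_MENOPAUSE = "natural_menopause"
    PERI_MENOPAUSE = "peri_menopause"
    PRE_MENOPAUSE = "pre_menopause"
    UNKNOWN = "unknown"
    MHT_BEFORE_PERIODS_STOPPED = "mht_before_periods_stopped"
    NO_PERIODS_HYSTERECTOMY = "no_periods_hysterectomy"
    MENOPAUSE_FROM_OOPHORECTOMY = "menopause_from_oophorectomy"


# classification flag codes
INCONSISTENT = "INCONSISTENT"
MISSING_CORE = "MISSING_CORE"
MISSING_EVENT_AGE = "MISSING_EVENT_AGE"
ASSUMED_UNILATERAL_OOPH = "ASSUMED_UNILATERAL_OOPH"

OOPHORECTOMY = "oophorectomy"
HYSTERECTOMY = "hysterectomy"
CURRENT_MHT = "current_mht"
MHT = "mht"


@dataclass(frozen=True, slots=True)
class ClassificationPolicy:
    """Configurable rule choices for the detailed-status decision table.

    ``not_sure_priority`` orders the interventions consulted for "not sure"
    responders (bilateral oophorectomy first: it causes menopause; then
    current MHT, which obscures bleeding; then hysterectomy).
    ``masking_precedence_for_yes`` orders the masking checks for women who
    report menopause. ``oophorectomy_menopause_tolerance`` (years) is how
    much later than the reported menopause an oophorectomy may fall and
    still count as its cause (0 means "at or before").
    """

    not_sure_priority: tuple[str, ...] = (OOPHORECTOMY, CURRENT_MHT, HYSTERECTOMY)
    not_sure_unmasked_target: DetailedStatus = DetailedStatus.PERI_MENOPAUSE
    irregular_with_hysterectomy: DetailedStatus = DetailedStatus.UNKNOWN
    irregular_with_oophorectomy: DetailedStatus = DetailedStatus.UNKNOWN
    irregular_with_current_mht: DetailedStatus = DetailedStatus.MHT_BEFORE_PERIODS_STOPPED
    oophorectomy_menopause_tolerance: float = 0.0
    natural_menopause_requires_age: bool = False
    masking_precedence_for_yes: tuple[str, ...] = (OOPHORECTOMY, HYSTERECTOMY, MHT)
    event_age_slack: float = EVENT_AGE_SLACK

    def __post_init__(self) -> None:
        if sorted(self.not_sure_priority) != sorted((OOPHORECTOMY, CURRENT_MHT, HYSTERECTOMY)):
            raise ValueError("not_sure_priority must permute oophorectomy/current_mht/hysterectomy")
        if sorted(self.masking_precedence_for_yes) != sorted((OOPHORECTOMY, HYSTERECTOMY, MHT)):
            raise ValueError("masking_precedence_for_yes must permute oophorectomy/hysterectomy/mht")
        if self.oophorectomy_menopause_tolerance < 0:
            raise ValueError("oophorectomy_menopause_tolerance must be >= 0")


DEFAULT_POLICY = ClassificationPolicy()


@dataclass(slots=True)
class ClassificationResult:
    """Derived statuses and explanatory flags for one participant."""

    participant_id: str
    intervention_category: InterventionCategory
    detailed: DetailedStatus
    consolidated: Optional["ConsolidatedStatus"] = None
    flags: frozenset[str] = frozenset()


def _classify_yes(record: ParticipantRecord, policy: ClassificationPolicy, flags: set[str]):
    """Self-reported menopause: check masking interventions in precedence order.

    An intervention dated after the reported menopause is post-menopausal and
    non-masking; the scan then continues to the next intervention. A reported
    intervention whose age (or the menopause age needed to order it) is
    absent makes the event order undecidable -> UNKNOWN.
    """
    am = record.age_at_menopause
    for step in policy.masking_precedence_for_yes:
        if step == OOPHORECTOMY and record.oophorectomy is YesNoMissing.YES:
            if record.age_at_oophorectomy is None or am is None:
                flags.add(MISSING_EVENT_AGE)
                return DetailedStatus.UNKNOWN
            if record.age_at_oophorectomy <= am + policy.oophorectomy_menopause_tolerance:
                return DetailedStatus.MENOPAUSE_FROM_OOPHORECTOMY
        elif step == HYSTERECTOMY and record.hysterectomy is YesNoMissing.YES:
            if record.age_at_hysterectomy is None or am is None:
                flags.add(MISSING_EVENT_AGE)
                return DetailedStatus.UNKNOWN
            if record.age_at_hysterectomy < am:  # same-age surgery is post-menopausal
                return DetailedStatus.NO_PERIODS_HYSTERECTOMY
        elif step == MHT and record.mht in (MHTUse.FORMER, MHTUse.CURRENT):
            if record.age_started_mht is None or am is None:
                flags.add(MISSING_EVENT_AGE)
                return DetailedStatus.UNKNOWN
            if record.age_started_mht < am:
                return DetailedStatus.MHT_BEFORE_PERIODS_STOPPED
    if am is None:
        flags.add(MISSING_EVENT_AGE)
        if policy.natural_menopause_requires_age:
            return DetailedStatus.UNKNOWN
    return DetailedStatus.NATURAL_MENOPAUSE


def _classify_no(record: ParticipantRecord, policy: ClassificationPolicy, flags: set[str]):
    if record.hysterectomy is YesNoMissing.YES:
        return DetailedStatus.NO_PERIODS_HYSTERECTOMY
    if record.mht is MHTUse.CURRENT:
        return DetailedStatus.MHT_BEFORE_PERIODS_STOPPED
    if record.oophorectomy is YesNoMissing.YES:
        # "no" to menopause despite bilateral oophorectomy: reconciled by
        # assuming the procedure was in fact unilateral
        flags.add(ASSUMED_UNILATERAL_OOPH)
    return DetailedStatus.PRE_MENOPAUSE


def _classify_irregular(record: ParticipantRecord, policy: ClassificationPolicy, flags: set[str]):
    if record.mht is MHTUse.CURRENT:
        target = policy.irregular_with_current_mht
    elif record.oophorectomy is YesNoMissing.YES:
        target = policy.irregular_with_oophorectomy
    elif record.hysterectomy is YesNoMissing.YES:
        target = policy.irregular_with_hysterectomy
    else:
        return DetailedStatus.PERI_MENOPAUSE
    if target is DetailedStatus.UNKNOWN:
        flags.add(INCONSISTENT)  # irregular periods contradict the surgery
    return target


def _classify_not_sure(record: ParticipantRecord, policy: ClassificationPolicy, flags: set[str]):
    for step in policy.not_sure_priority:
        if step == OOPHORECTOMY and record.oophorectomy is YesNoMissing.YES:
            return DetailedStatus.MENOPAUSE_FROM_OOPHORECTOMY
        if step == CURRENT_MHT and record.mht is MHTUse.CURRENT:
            return DetailedStatus.MHT_BEFORE_PERIODS_STOPPED
        if step == HYSTERECTOMY and record.hysterectomy is YesNoMissing.YES:
            return DetailedStatus.NO_PERIODS_HYSTERECTOMY
    target = policy.not_sure_unmasked_target
    if target is DetailedStatus.UNKNOWN:
        flags.add(MISSING_CORE)
    return target


_DISPATCH = {
    MenopauseResponse.YES: _classify_yes,
    MenopauseResponse.NO: _classify_no,
    MenopauseResponse.IRREGULAR: _classify_irregular,
    MenopauseResponse.NOT_SURE: _classify_not_sure,
}


def classify_detailed(
    record: ParticipantRecord, policy: ClassificationPolicy = DEFAULT_POLICY
) -> ClassificationResult:
    """Assign the detailed derived status for one record (total, deterministic).

    Degenerate inputs are absorbed by ``UNKNOWN``: any missing core response
    (menopause, MHT, hysterectomy, oophorectomy) flags ``MISSING_CORE``; an
    event age exceeding baseline age by more than the slack flags
    ``INCONSISTENT``; a reported intervention with undecidable event order
    flags ``MISSING_EVENT_AGE``.
    """
    flags: set[str] = set()
    category = assign_intervention_category(record)

    if (
        record.menopause is MenopauseResponse.MISSING
        or category is InterventionCategory.INCOMPLETE
    ):
        flags.add(MISSING_CORE)
    if record.inconsistent_event_ages(policy.event_age_slack):
        flags.add(INCONSISTENT)
    if flags:
        detailed = DetailedStatus.UNKNOWN
    else:
        detailed = _DISPATCH[record.menopause](record, policy, flags)

    return ClassificationResult(
        participant_id=record.participant_id,
        intervention_category=category,
        detailed=detailed,
        flags=frozenset(flags),
    )


def classify_cohort_detailed(
    cohort: Sequence[ParticipantRecord], policy: ClassificationPolicy = DEFAULT_POLICY
) -> list[ClassificationResult]:
    """Order-preserving map of :func:`classify_detailed` over a cohort."""
    return [classify_detailed(record, policy) for record in cohort]
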