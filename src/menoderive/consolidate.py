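"""Step 3B — collapse the seven detailed categories to four.

Natural menopause maps to post-menopause, and so does oophorectomy-induced
menopause when menopause was itself self-reported (the combination confirms
the surgery was bilateral and causal). Peri- and pre-menopause carry over
unchanged and are never re-classified. The remaining statuses — the masked
ones (MHT started before periods stopped, no periods due to hysterectomy,
oophorectomy without self-reported menopause) and, optionally, detailed
unknown — are re-classified to post-menopause when the woman's baseline age
is at or above the age threshold, and to unknown otherwise.
"""

from __future__ import annotations

from dataclasses import replace
from enum import Enum
from typing import Sequence, Union

from .detailed import ClassificationResult, DetailedStatus
from .io import AlignmentError
from .records import MenopauseResponse, ParticipantRecord
from .thresholds import ThresholdResult


class ConsolidatedStatus(str, Enum):
    POST_MENOPAUSE = "post_menopause"
    PERI_MENOPAUSE = "peri_menopause"
    PRE_MENOPAUSE = "pre_menopause"
    UNKNOWN = "unknown"


class ThresholdNotAttainedError(ValueError):
    """Consolidation was requested with a threshold that was never attained."""


#: Detailed statuses whose menopausal state is potentially masked.
MASKED_STATUSES = frozenset(
    {
        DetailedStatus.MHT_BEFORE_PERIODS_STOPPED,
        DetailedStatus.NO_PERIODS_HYSTERECTOMY,
    }
)


def consolidate_status(
    detailed: DetailedStatus,
    menopause: MenopauseResponse,
    age_at_baseline: float | None,
    threshold_age: int,
    reclassify_unknown: bool = True,
) -> ConsolidatedStatus:
    """Four-category consolidated status for one woman.

    ``threshold_age`` of a means "aged >= a years at baseline" re-classifies
    to post-menopause. A missing baseline age cannot be compared against the
    threshold, so masked/unknown statuses stay unknown.
    """
    if detailed is DetailedStatus.NATURAL_MENOPAUSE:
        return ConsolidatedStatus.POST_MENOPAUSE
    if detailed is DetailedStatus.MENOPAUSE_FROM_OOPHORECTOMY:
        if menopause is MenopauseResponse.YES:
            return ConsolidatedStatus.POST_MENOPAUSE
        # without self-reported menopause the procedure may have been
        # unilateral, so the status counts as masked
    elif detailed is DetailedStatus.PERI_MENOPAUSE:
        return ConsolidatedStatus.PERI_MENOPAUSE
    elif detailed is DetailedStatus.PRE_MENOPAUSE:
        return ConsolidatedStatus.PRE_MENOPAUSE
    elif detailed is DetailedStatus.UNKNOWN and not reclassify_unknown:
        return ConsolidatedStatus.UNKNOWN
    if age_at_baseline is not None and age_at_baseline >= threshold_age:
        return ConsolidatedStatus.POST_MENOPAUSE
    return ConsolidatedStatus.UNKNOWN


def consolidate_cohort(
    results: Sequence[ClassificationResult],
    records: Sequence[ParticipantRecord],
    threshold: Union[int, ThresholdResult],
    reclassify_unknown: bool = True,
) -> list[ClassificationResult]:
    """Fill the consolidated field of every aligned result (new list).

    Refuses a :class:`~menoderive.thresholds.ThresholdResult` whose cut-point
    was never attained.
    """
    if isinstance(threshold, ThresholdResult):
        if not threshold.attained:
            raise ThresholdNotAttainedError(
                f"{threshold.method.value} threshold not attained: {threshold.message}"
            )
        threshold_age = threshold.threshold_age
    else:
        threshold_age = int(threshold)
    if len(results) != len(records):
        raise AlignmentError(f"{len(results)} results vs {len(records)} records")
    out: list[ClassificationResult] = []
    for result, record in zip(results, records):
        if result.participant_id != record.participant_id:
            raise AlignmentError(
                f"result {result.participant_id!r} paired with record "
                f"{record.participant_id!r}"
            )
        consolidated = consolidate_status(
            result.detailed,
            record.menopause,
            record.age_at_baseline,
            threshold_age,
            reclassify_unknown,
        )
        flags = result.flags
        if (
            consolidated is ConsolidatedStatus.UNKNOWN
            and record.age_at_baseline is None
        ):
            flags = flags | {"MISSING_BASELINE_AGE"}
        out.append(replace(result, consolidated=consolidated, flags=flags))
    return out
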