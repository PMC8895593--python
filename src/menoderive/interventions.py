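"""Step 1 — map each woman to one of 13 intervention combinations.

Three questionnaire items can affect or mask menopause: MHT use (never /
former / current), hysterectomy (yes / no) and bilateral oophorectomy
(yes / no). Their 3 x 2 x 2 = 12 complete combinations, plus one
``INCOMPLETE`` category for any record missing one or more of the three
responses, give the 13 categories. The categories partition all possible
response triples, so assignment is a total function.
"""

from __future__ import annotations

from collections import Counter
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .records import MHTUse, ParticipantRecord, YesNoMissing


class InterventionCategory(str, Enum):
    NONE = "none"
    HYST_ONLY = "hyst_only"
    OOPH_ONLY = "ooph_only"
    HYST_OOPH = "hyst_ooph"
    MHT_FORMER_ONLY = "mht_former_only"
    MHT_CURRENT_ONLY = "mht_current_only"
    HYST_MHT_FORMER = "hyst_mht_former"
    HYST_MHT_CURRENT = "hyst_mht_current"
    OOPH_MHT_FORMER = "ooph_mht_former"
    OOPH_MHT_CURRENT = "ooph_mht_current"
    HYST_OOPH_MHT_FORMER = "hyst_ooph_mht_former"
    HYST_OOPH_MHT_CURRENT = "hyst_ooph_mht_current"
    INCOMPLETE = "incomplete"


#: The 12 complete (mht, hysterectomy, oophorectomy) triples.
_TRIPLE_TO_CATEGORY: dict[tuple[MHTUse, YesNoMissing, YesNoMissing], InterventionCategory] = {
    (MHTUse.NEVER, YesNoMissing.NO, YesNoMissing.NO): InterventionCategory.NONE,
    (MHTUse.NEVER, YesNoMissing.YES, YesNoMissing.NO): InterventionCategory.HYST_ONLY,
    (MHTUse.NEVER, YesNoMissing.NO, YesNoMissing.YES): InterventionCategory.OOPH_ONLY,
    (MHTUse.NEVER, YesNoMissing.YES, YesNoMissing.YES): InterventionCategory.HYST_OOPH,
    (MHTUse.FORMER, YesNoMissing.NO, YesNoMissing.NO): InterventionCategory.MHT_FORMER_ONLY,
    (MHTUse.CURRENT, YesNoMissing.NO, YesNoMissing.NO): InterventionCategory.MHT_CURRENT_ONLY,
    (MHTUse.FORMER, YesNoMissing.YES, YesNoMissing.NO): InterventionCategory.HYST_MHT_FORMER,
    (MHTUse.CURRENT, YesNoMissing.YES, YesNoMissing.NO): InterventionCategory.HYST_MHT_CURRENT,
    (MHTUse.FORMER, YesNoMissing.NO, YesNoMissing.YES): InterventionCategory.OOPH_MHT_FORMER,
    (MHTUse.CURRENT, YesNoMissing.NO, YesNoMissing.YES): InterventionCategory.OOPH_MHT_CURRENT,
    (MHTUse.FORMER, YesNoMissing.YES, YesNoMissing.YES): InterventionCategory.HYST_OOPH_MHT_FORMER,
    (MHTUse.CURRENT, YesNoMissing.YES, YesNoMissing.YES): InterventionCategory.HYST_OOPH_MHT_CURRENT,
}


def assign_intervention_category(record: ParticipantRecord) -> InterventionCategory:
    """Assign the intervention-combination category for one record.

    Depends only on the mht, hysterectomy and oophorectomy responses; any
    missing response among the three yields ``INCOMPLETE``.
    """
    if (
        record.mht is MHTUse.MISSING
        or record.hysterectomy is YesNoMissing.MISSING
        or record.oophorectomy is YesNoMissing.MISSING
    ):
        return InterventionCategory.INCOMPLETE
    return _TRIPLE_TO_CATEGORY[(record.mht, record.hysterectomy, record.oophorectomy)]


def tabulate_categories(
    cohort: Sequence[ParticipantRecord],
    merge: Optional[Mapping[InterventionCategory, str]] = None,
) -> dict:
    """Frequency table category -> (count, proportion of cohort).

    Every category appears, including zero-count ones; counts sum to the
    cohort size and proportions to 1. On an empty cohort proportions are
    undefined and reported as ``None``. ``merge`` optionally collapses
    categories into display groups (keys become the merged labels).
    """
    counts = Counter(assign_intervention_category(r) for r in cohort)
    n = len(cohort)
    if merge is None:
        return {
            cat: (counts.get(cat, 0), counts.get(cat, 0) / n if n else None)
            for cat in InterventionCategory
        }
    merged: Counter = Counter()
    for cat in InterventionCategory:
        merged[merge.get(cat, cat.value)] += counts.get(cat, 0)
    return {label: (c, c / n if n else None) for label, c in merged.items()}
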