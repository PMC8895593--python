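"""Core domain types for participant records.

A participant record holds one woman's coded questionnaire responses and
event ages. Categorical responses are closed enumerations in which
``MISSING`` is an explicit state — after parsing, no categorical field is
ever ``None``. Event ages are either a positive float or ``None`` (absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class MenopauseResponse(str, Enum):
    """Answer to "Have you been through menopause?"."""

    NO = "no"
    NOT_SURE = "not_sure"
    IRREGULAR = "irregular"
    YES = "yes"
    MISSING = "missing"


class MHTUse(str, Enum):
    """Menopausal hormone therapy use."""

    NEVER = "never"
    FORMER = "former"
    CURRENT = "current"
    MISSING = "missing"


class YesNoMissing(str, Enum):
    """Yes/no questionnaire item with explicit missingness."""

    YES = "yes"
    NO = "no"
    MISSING = "missing"


#: Minimum baseline age defining the cohort (women aged >= 45 at recruitment).
COHORT_MIN_AGE = 45.0

#: Slack, in years, allowed when checking "event age <= baseline age".
#: A reported event age exceeding baseline age by more than this is treated
#: as internally inconsistent.
EVENT_AGE_SLACK = 1.0


@dataclass(frozen=True, slots=True)
class ParticipantRecord:
    """One woman's coded responses and event ages; the unit of classification.

    Ages are in years and may be fractional (they are typically computed from
    dates in the source survey); no rounding is applied on ingest and event
    ordering comparisons use the values as given.
    """

    participant_id: str
    age_at_baseline: Optional[float]
    menopause: MenopauseResponse = MenopauseResponse.MISSING
    mht: MHTUse = MHTUse.MISSING
    hysterectomy: YesNoMissing = YesNoMissing.MISSING
    oophorectomy: YesNoMissing = YesNoMissing.MISSING
    oc_current: YesNoMissing = YesNoMissing.MISSING
    age_at_menopause: Optional[float] = None
    age_started_mht: Optional[float] = None
    age_at_hysterectomy: Optional[float] = None
    age_at_oophorectomy: Optional[float] = None

    def event_ages(self) -> dict[str, Optional[float]]:
        """Event ages keyed by field name (present or absent)."""
        return {
            "age_at_menopause": self.age_at_menopause,
            "age_started_mht": self.age_started_mht,
            "age_at_hysterectomy": self.age_at_hysterectomy,
            "age_at_oophorectomy": self.age_at_oophorectomy,
        }

    def inconsistent_event_ages(self, slack: float = EVENT_AGE_SLACK) -> list[str]:
        """Names of event ages exceeding baseline age by more than ``slack``."""
        if self.age_at_baseline is None:
            return []
        return [
            name
            for name, age in self.event_ages().items()
            if age is not None and age > self.age_at_baseline + slack
        ]


@dataclass(frozen=True, slots=True)
class ValidationFlag:
    participant_id: str
    code: str
    message: str


@dataclass(slots=True)
class ValidationReport:
    """Summary of structural issues found while reading a cohort file."""

    n_read: int = 0
    flags: list[ValidationFlag] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return len({f.participant_id for f in self.flags})

    def add(self, participant_id: str, code: str, message: str) -> None:
        self.flags.append(ValidationFlag(participant_id, code, message))
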