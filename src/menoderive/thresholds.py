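"""Step 3A — estimate the age threshold for likely post-menopause.

Above some baseline age, women whose menopausal status is masked or unknown
are very likely to be post-menopausal anyway; that age is estimated from the
cohort itself, restricted to women whose status cannot have been affected by
interventions (never used MHT, no hysterectomy, no bilateral oophorectomy,
not currently using hormonal contraception). Three estimators are provided:

* ``REFERENCE`` — among intervention-free women aged at least 55 at baseline
  with a derived natural menopause and a reported age at menopause, the
  smallest integer age below which at least 90% of reported menopause ages
  fall (cumulative distribution of age at menopause).
* ``CONSERVATIVE`` — the smallest age from which *every* single-year
  baseline-age group (of at least ``min_group_n`` women) has at least 90%
  self-reporting menopause.
* ``LEAST_CONSERVATIVE`` — the smallest baseline age from which at least 90%
  of all intervention-free women at or above it carry the derived natural
  menopause status.

The 90% cut-point is configurable; lower cut-points classify more women as
post-menopausal at the cost of specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .detailed import ClassificationResult, DetailedStatus
from .io import AlignmentError
from .records import MenopauseResponse, MHTUse, ParticipantRecord, YesNoMissing


class ThresholdMethod(str, Enum):
    REFERENCE = "reference"
    CONSERVATIVE = "conservative"
    LEAST_CONSERVATIVE = "least_conservative"


@dataclass(frozen=True, slots=True)
class ThresholdSpec:
    """Parameters of a threshold estimation.

    ``min_baseline_age_reference`` excludes younger women from the reference
    estimator (they may misread a temporary irregularity as menopause);
    ``min_group_n`` suppresses noisy extreme-age single-year groups in the
    conservative estimator; the scan runs over integer ages in
    ``age_scan_range`` inclusive.
    """

    method: ThresholdMethod = ThresholdMethod.REFERENCE
    cut_point: float = 0.90
    min_baseline_age_reference: float = 55.0
    min_group_n: int = 50
    age_scan_range: tuple[int, int] = (45, 100)

    def __post_init__(self) -> None:
        if not 0.0 < self.cut_point < 1.0:
            raise ValueError("cut_point must lie in (0, 1)")
        if self.age_scan_range[0] > self.age_scan_range[1]:
            raise ValueError("age_scan_range must be non-empty")


@dataclass(slots=True)
class ThresholdResult:
    """An integer age threshold with the table that produced it.

    ``cumulative_table`` rows are (age, numerator, denominator, proportion);
    for the conservative method they are per single-year age group, otherwise
    cumulative over the scan. ``threshold_age`` is ``None`` when the cut-point
    is never attained (``attained`` False, ``message`` explains why).
    """

    method: ThresholdMethod
    threshold_age: Optional[int]
    n_eligible: int
    cumulative_table: list[tuple[int, int, int, Optional[float]]] = field(default_factory=list)
    message: str = ""

    @property
    def attained(self) -> bool:
        return self.threshold_age is not None


Pair = tuple[ParticipantRecord, ClassificationResult]


def eligible_subcohort(
    cohort: Sequence[ParticipantRecord],
    results: Sequence[ClassificationResult],
    spec: ThresholdSpec,
) -> list[Pair]:
    """Intervention-free (record, result) pairs eligible for threshold estimation.

    All methods require never-MHT, no hysterectomy, no oophorectomy and no
    current hormonal contraception. The reference method additionally requires
    a derived natural menopause with a reported menopause age and baseline age
    >= ``spec.min_baseline_age_reference``.
    """
    if len(cohort) != len(results):
        raise AlignmentError(f"{len(cohort)} records vs {len(results)} results")
    pairs: list[Pair] = []
    for record, result in zip(cohort, results):
        if record.participant_id != result.participant_id:
            raise AlignmentError(
                f"record {record.participant_id!r} paired with result "
                f"{result.participant_id!r}"
            )
        if not (
            record.mht is MHTUse.NEVER
            and record.hysterectomy is YesNoMissing.NO
            and record.oophorectomy is YesNoMissing.NO
            and record.oc_current is YesNoMissing.NO
        ):
            continue
        if spec.method is ThresholdMethod.REFERENCE:
            if result.detailed is not DetailedStatus.NATURAL_MENOPAUSE:
                continue
            if record.age_at_menopause is None or record.age_at_baseline is None:
                continue
            if record.age_at_baseline < spec.min_baseline_age_reference:
                continue
        pairs.append((record, result))
    return pairs


def _not_attained(method: ThresholdMethod, n: int, message: str) -> ThresholdResult:
    return ThresholdResult(method=method, threshold_age=None, n_eligible=n, message=message)


def reference_threshold(eligible: Sequence[Pair], spec: ThresholdSpec) -> ThresholdResult:
    """Smallest age a with cumulative share of menopause ages strictly below a >= cut."""
    ages = np.sort(
        np.array([r.age_at_menopause for r, _ in eligible], dtype=float)
    )
    n = ages.size
    if n == 0:
        return _not_attained(ThresholdMethod.REFERENCE, 0, "no eligible women with a reported age at menopause")
    lo, hi = spec.age_scan_range
    scan = np.arange(lo, hi + 1)
    below = np.searchsorted(ages, scan, side="left")  # strict: age_at_menopause < a
    props = below / n
    table = [(int(a), int(k), n, float(p)) for a, k, p in zip(scan, below, props)]
    hits = np.nonzero(props >= spec.cut_point)[0]
    if hits.size == 0:
        return ThresholdResult(
            ThresholdMethod.REFERENCE, None, n, table,
            f"cumulative proportion never reaches {spec.cut_point} within the scan range",
        )
    return ThresholdResult(ThresholdMethod.REFERENCE, int(scan[hits[0]]), n, table)


def conservative_threshold(eligible: Sequence[Pair], spec: ThresholdSpec) -> ThresholdResult:
    """Smallest age from which every qualifying single-year group is >= cut.

    Groups are floor(baseline age); only groups with at least
    ``spec.min_group_n`` women qualify. The numerator counts direct
    self-reports of menopause ("yes"); all other responses, including
    missing, stay in the denominator.
    """
    lo, hi = spec.age_scan_range
    groups: dict[int, list[ParticipantRecord]] = {}
    n_elig = 0
    for record, _ in eligible:
        if record.age_at_baseline is None:
            continue
        g = int(np.floor(record.age_at_baseline))
        if lo <= g <= hi:
            groups.setdefault(g, []).append(record)
            n_elig += 1
    table = []
    qualifying: dict[int, float] = {}
    for g in sorted(groups):
        members = groups[g]
        n_yes = sum(1 for r in members if r.menopause is MenopauseResponse.YES)
        prop = n_yes / len(members)
        table.append((g, n_yes, len(members), prop))
        if len(members) >= spec.min_group_n:
            qualifying[g] = prop
    if not qualifying:
        return _not_attained(
            ThresholdMethod.CONSERVATIVE, n_elig,
            f"no single-year age group reaches min_group_n={spec.min_group_n}",
        )
    for a in range(lo, hi + 1):
        tail = [p for g, p in qualifying.items() if g >= a]
        if tail and all(p >= spec.cut_point for p in tail):
            return ThresholdResult(ThresholdMethod.CONSERVATIVE, a, n_elig, table)
    return ThresholdResult(
        ThresholdMethod.CONSERVATIVE, None, n_elig, table,
        f"no age from which every qualifying group is >= {spec.cut_point}",
    )


def least_conservative_threshold(eligible: Sequence[Pair], spec: ThresholdSpec) -> ThresholdResult:
    """Smallest age a with natural-menopause share among women aged >= a >= cut."""
    rows = [
        (r.age_at_baseline, res.detailed is DetailedStatus.NATURAL_MENOPAUSE)
        for r, res in eligible
        if r.age_at_baseline is not None
    ]
    n = len(rows)
    if n == 0:
        return _not_attained(ThresholdMethod.LEAST_CONSERVATIVE, 0, "no eligible women with a baseline age")
    ages = np.array([a for a, _ in rows], dtype=float)
    natural = np.array([v for _, v in rows], dtype=bool)
    order = np.argsort(ages)
    ages, natural = ages[order], natural[order]
    # suffix sums give the tail counts for every candidate age in one pass
    tail_natural = np.cumsum(natural[::-1])[::-1]
    lo, hi = spec.age_scan_range
    table = []
    threshold = None
    for a in range(lo, hi + 1):
        i = np.searchsorted(ages, a, side="left")
        denom = n - i
        num = int(tail_natural[i]) if i < n else 0
        prop = num / denom if denom else None
        table.append((a, num, denom, prop))
        if threshold is None and denom > 0 and prop >= spec.cut_point:
            threshold = a
    if threshold is None:
        return ThresholdResult(
            ThresholdMethod.LEAST_CONSERVATIVE, None, n, table,
            f"natural-menopause tail proportion never reaches {spec.cut_point}",
        )
    return ThresholdResult(ThresholdMethod.LEAST_CONSERVATIVE, threshold, n, table)


_ESTIMATORS = {
    ThresholdMethod.REFERENCE: reference_threshold,
    ThresholdMethod.CONSERVATIVE: conservative_threshold,
    ThresholdMethod.LEAST_CONSERVATIVE: least_conservative_threshold,
}


def estimate_threshold(
    cohort: Sequence[ParticipantRecord],
    results: Sequence[ClassificationResult],
    spec: ThresholdSpec,
) -> ThresholdResult:
    """Filter the cohort per ``spec.method`` and run the matching estimator."""
    eligible = eligible_subcohort(cohort, results, spec)
    return _ESTIMATORS[spec.method](eligible, spec)


def estimate_all_thresholds(
    cohort: Sequence[ParticipantRecord],
    results: Sequence[ClassificationResult],
    cut_point: float = 0.90,
    **spec_kwargs,
) -> dict[ThresholdMethod, ThresholdResult]:
    """All three threshold estimates on one cohort."""
    return {
        method: estimate_threshold(
            cohort, results, ThresholdSpec(method=method, cut_point=cut_point, **spec_kwargs)
        )
        for method in ThresholdMethod
    }
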