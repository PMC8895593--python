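"""Comparison outputs: cross-tabulations, percentage and change arithmetic.

Published comparison tables report, per menopausal-status category, the
count, the percentage of the total cohort, and the change relative to the
directly self-reported status — both in percentage points of the cohort and
as a relative percentage of the self-reported count. All display rounding is
half-up to one decimal and is applied exactly once, to otherwise unrounded
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .consolidate import ConsolidatedStatus
from .detailed import ClassificationResult, DetailedStatus
from .io import AlignmentError
from .records import MenopauseResponse


def _round1(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percent_of_total(count: int, total: int) -> float:
    """100*count/total, half-up to one decimal."""
    if total <= 0:
        raise ValueError("percent_of_total is undefined for total <= 0")
    return _round1(Decimal(count) * 100 / Decimal(total))


def relative_change(before: int, after: int) -> float:
    """Signed relative change 100*(after-before)/before, half-up, one decimal."""
    if before <= 0:
        raise ValueError("relative_change is undefined for before <= 0")
    return _round1(Decimal(after - before) * 100 / Decimal(before))


def pp_change(count_a: int, count_b: int, total: int) -> float:
    """Percentage-point difference of the two shares of ``total`` (a minus b).

    Computed on unrounded percentages, then rounded half-up to one decimal.
    """
    if total <= 0:
        raise ValueError("pp_change is undefined for total <= 0")
    return _round1(Decimal(count_a - count_b) * 100 / Decimal(total))


#: Directly self-reported status collapsed to the four published rows;
#: "not sure" and missing responses share a row.
SELF_REPORT_FOUR_LEVEL = {
    MenopauseResponse.YES: "post_menopause",
    MenopauseResponse.IRREGULAR: "peri_menopause",
    MenopauseResponse.NO: "pre_menopause",
    MenopauseResponse.NOT_SURE: "not_sure_or_missing",
    MenopauseResponse.MISSING: "not_sure_or_missing",
}


@dataclass(slots=True)
class CrossTab:
    """A contingency table with margins; grand total equals the cohort size."""

    counts: pd.DataFrame  # rows: self-reported, columns: derived
    n: int

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)


def crosstab(self_reported: Sequence, derived: Sequence) -> CrossTab:
    """Self-reported (rows) against derived (columns) status counts."""
    if len(self_reported) != len(derived):
        raise AlignmentError(
            f"{len(self_reported)} self-reported vs {len(derived)} derived values"
        )
    rows = [getattr(v, "value", str(v)) for v in self_reported]
    cols = [getattr(v, "value", str(v)) for v in derived]
    counts = pd.crosstab(pd.Series(rows, name="self_reported"), pd.Series(cols, name="derived"))
    return CrossTab(counts=counts, n=len(rows))


def flow_table(
    self_reported: Sequence, detailed: Sequence, consolidated: Sequence
) -> pd.DataFrame:
    """Three-level transition counts (self-reported -> detailed -> consolidated).

    One row per observed path with a ``count`` column; counts sum to the
    cohort size at every level, so the table can feed an external Sankey
    renderer directly.
    """
    if not (len(self_reported) == len(detailed) == len(consolidated)):
        raise AlignmentError("the three status sequences differ in length")
    frame = pd.DataFrame(
        {
            "self_reported": [getattr(v, "value", str(v)) for v in self_reported],
            "detailed": [getattr(v, "value", str(v)) for v in detailed],
            "consolidated": [getattr(v, "value", str(v)) for v in consolidated],
        }
    )
    return (
        frame.groupby(["self_reported", "detailed", "consolidated"], sort=True)
        .size()
        .reset_index(name="count")
    )


def status_counts(results: Sequence[ClassificationResult]) -> dict[str, dict[str, int]]:
    """Self-reported-style four-level counts of the consolidated statuses."""
    out = {s.value: 0 for s in ConsolidatedStatus}
    for r in results:
        if r.consolidated is None:
            raise ValueError(f"result {r.participant_id!r} has no consolidated status")
        out[r.consolidated.value] += 1
    return out


def change_report(
    self_reported: Sequence[MenopauseResponse],
    results: Sequence[ClassificationResult],
) -> pd.DataFrame:
    """Per-category comparison of consolidated derived vs self-reported status.

    Columns: self-reported count and percent, derived count and percent,
    percentage-point change and relative change — the published table's
    layout, with "unknown" compared against "not sure"/missing self-reports.
    """
    if len(self_reported) != len(results):
        raise AlignmentError(f"{len(self_reported)} responses vs {len(results)} results")
    total = len(results)
    self_counts = {label: 0 for label in ("post_menopause", "peri_menopause", "pre_menopause", "not_sure_or_missing")}
    for response in self_reported:
        self_counts[SELF_REPORT_FOUR_LEVEL[response]] += 1
    derived_counts = status_counts(results)
    pair_labels = [
        ("post_menopause", "post_menopause"),
        ("peri_menopause", "peri_menopause"),
        ("pre_menopause", "pre_menopause"),
        ("not_sure_or_missing", "unknown"),
    ]
    rows = []
    for self_label, derived_label in pair_labels:
        before = self_counts[self_label]
        after = derived_counts[derived_label]
        rows.append(
            {
                "category": derived_label,
                "self_reported_n": before,
                "self_reported_pct": percent_of_total(before, total) if total else None,
                "derived_n": after,
                "derived_pct": percent_of_total(after, total) if total else None,
                "pp_change": pp_change(after, before, total) if total else None,
                "relative_change_pct": relative_change(before, after) if before else None,
            }
        )
    return pd.DataFrame(rows)
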