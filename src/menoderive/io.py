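"""Read, validate and write participant cohorts as delimiter-separated files.

The default schema is a comma-separated UTF-8 file with one header row and
columns ``id, age_baseline, menopause, mht, hysterectomy, oophorectomy,
oc_current, age_menopause, age_mht_start, age_hysterectomy, age_oophorectomy``.
An empty cell means missing. Both column names and category codes can be
remapped through a :class:`CohortSchema`, so arbitrary survey exports can be
adapted without editing the source table.

Parsing never drops rows: unrecognised categorical codes become ``MISSING``
and unparseable ages become absent, each with a flag in the accompanying
:class:`~menoderive.records.ValidationReport`; internally inconsistent
records (an event age exceeding baseline age beyond the slack) are retained
and flagged — rejection is the classifier's decision, not the reader's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .records import (
    COHORT_MIN_AGE,
    EVENT_AGE_SLACK,
    MenopauseResponse,
    MHTUse,
    ParticipantRecord,
    ValidationReport,
    YesNoMissing,
)

# flag codes
UNRECOGNISED_CODE = "UNRECOGNISED_CODE"
UNPARSEABLE_AGE = "UNPARSEABLE_AGE"
NONPOSITIVE_AGE = "NONPOSITIVE_AGE"
AGE_EXCEEDS_BASELINE = "AGE_EXCEEDS_BASELINE"
MISSING_BASELINE_AGE = "MISSING_BASELINE_AGE"
BASELINE_BELOW_COHORT_MIN = "BASELINE_BELOW_COHORT_MIN"


class SchemaError(ValueError):
    """A required column is absent or the schema config is malformed."""


class AlignmentError(ValueError):
    """Records and classification results do not line up one-to-one."""


_DEFAULT_COLUMNS = {
    "participant_id": "id",
    "age_at_baseline": "age_baseline",
    "menopause": "menopause",
    "mht": "mht",
    "hysterectomy": "hysterectomy",
    "oophorectomy": "oophorectomy",
    "oc_current": "oc_current",
    "age_at_menopause": "age_menopause",
    "age_started_mht": "age_mht_start",
    "age_at_hysterectomy": "age_hysterectomy",
    "age_at_oophorectomy": "age_oophorectomy",
}

_CATEGORICAL_FIELDS = {
    "menopause": MenopauseResponse,
    "mht": MHTUse,
    "hysterectomy": YesNoMissing,
    "oophorectomy": YesNoMissing,
    "oc_current": YesNoMissing,
}

_AGE_FIELDS = (
    "age_at_baseline",
    "age_at_menopause",
    "age_started_mht",
    "age_at_hysterectomy",
    "age_at_oophorectomy",
)


@dataclass(slots=True)
class CohortSchema:
    """Column-name and category-code mapping for a cohort file.

    ``columns`` maps record field names to file column names; ``codes`` maps,
    per categorical field, file codes to canonical codes (``no``, ``not_sure``,
    ``irregular``, ``yes``, ``never``, ``former``, ``current``). Unlisted
    codes fall through to the canonical parser.
    """

    columns: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_COLUMNS))
    codes: dict[str, dict[str, str]] = field(default_factory=dict)
    delimiter: str = ","

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSchema":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise SchemaError(f"schema file {path} must hold a mapping")
        columns = dict(_DEFAULT_COLUMNS)
        columns.update(raw.get("columns", {}))
        codes = {k: dict(v) for k, v in raw.get("codes", {}).items()}
        return cls(columns=columns, codes=codes, delimiter=raw.get("delimiter", ","))


def _parse_categorical(enum_cls, raw: str, remap: Mapping[str, str]):
    """Parse one categorical cell; returns (value, ok)."""
    text = raw.strip()
    if text in remap:
        text = remap[text]
    if text == "":
        return enum_cls.MISSING, True
    try:
        return enum_cls(text.lower()), True
    except ValueError:
        return enum_cls.MISSING, False


def _parse_age(raw: str) -> tuple[Optional[float], Optional[str]]:
    """Parse one age cell; returns (value, flag code or None)."""
    text = raw.strip()
    if text == "":
        return None, None
    try:
        value = float(text)
    except ValueError:
        return None, UNPARSEABLE_AGE
    if not value > 0:
        return None, NONPOSITIVE_AGE
    return value, None


def read_cohort(
    path: str | Path,
    schema: CohortSchema | None = None,
) -> tuple[list[ParticipantRecord], ValidationReport]:
    """Read a cohort file into records plus a validation report.

    Row count is preserved: every data row yields exactly one record. Raises
    :class:`SchemaError` if a required column is missing; an empty file (header
    only) yields an empty cohort, not an error.
    """
    schema = schema or CohortSchema()
    frame = pd.read_csv(
        path, dtype=str, sep=schema.delimiter, keep_default_na=False, encoding="utf-8"
    )
    missing_cols = [col for col in schema.columns.values() if col not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")

    records: list[ParticipantRecord] = []
    report = ValidationReport(n_read=len(frame))
    for i, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        pid = str(row[schema.columns["participant_id"]]).strip() or f"row{i + 1}"
        fields: dict = {"participant_id": pid}
        for name, enum_cls in _CATEGORICAL_FIELDS.items():
            value, ok = _parse_categorical(
                enum_cls, row[schema.columns[name]], schema.codes.get(name, {})
            )
            fields[name] = value
            if not ok:
                report.add(pid, UNRECOGNISED_CODE, f"{name}: unrecognised code {row[schema.columns[name]]!r}")
        for name in _AGE_FIELDS:
            value, code = _parse_age(row[schema.columns[name]])
            fields[name] = value
            if code is not None:
                report.add(pid, code, f"{name}: cannot use value {row[schema.columns[name]]!r}")
        record = ParticipantRecord(**fields)
        if record.age_at_baseline is None:
            report.add(pid, MISSING_BASELINE_AGE, "age_at_baseline is absent")
        elif record.age_at_baseline < COHORT_MIN_AGE:
            report.add(
                pid,
                BASELINE_BELOW_COHORT_MIN,
                f"age_at_baseline {record.age_at_baseline} < cohort minimum {COHORT_MIN_AGE}",
            )
        for name in record.inconsistent_event_ages(EVENT_AGE_SLACK):
            report.add(
                pid,
                AGE_EXCEEDS_BASELINE,
                f"{name} exceeds age_at_baseline + {EVENT_AGE_SLACK}",
            )
        records.append(record)
    return records, report


def _format_age(value: Optional[float]) -> str:
    # repr round-trips floats exactly, so write/read is bit-stable
    return "" if value is None else repr(value)


def records_to_frame(
    records: Sequence[ParticipantRecord], schema: CohortSchema | None = None
) -> pd.DataFrame:
    """Records as a string DataFrame in schema column order (missing = '')."""
    schema = schema or CohortSchema()
    data: dict[str, list[str]] = {}
    for name, col in schema.columns.items():
        if name == "participant_id":
            data[col] = [r.participant_id for r in records]
        elif name in _CATEGORICAL_FIELDS:
            enum_missing = _CATEGORICAL_FIELDS[name].MISSING
            data[col] = [
                "" if getattr(r, name) is enum_missing else getattr(r, name).value
                for r in records
            ]
        else:
            data[col] = [_format_age(getattr(r, name)) for r in records]
    return pd.DataFrame(data, dtype=str)


def write_results(
    records: Sequence[ParticipantRecord],
    results: Sequence,  # Sequence[ClassificationResult]; avoids an import cycle
    path: str | Path,
    schema: CohortSchema | None = None,
) -> None:
    """Write input columns plus derived-status columns to ``path``.

    Records and results must be aligned one-to-one by participant id; the
    output re-reads bit-exactly with :func:`read_cohort` (the extra derived
    columns are ignored on re-read).
    """
    schema = schema or CohortSchema()
    if len(records) != len(results):
        raise AlignmentError(
            f"{len(records)} records vs {len(results)} results"
        )
    for record, result in zip(records, results):
        if record.participant_id != result.participant_id:
            raise AlignmentError(
                f"record {record.participant_id!r} paired with result "
                f"{result.participant_id!r}"
            )
    frame = records_to_frame(records, schema)
    frame["intervention_category"] = [r.intervention_category.value for r in results]
    frame["detailed_status"] = [r.detailed.value for r in results]
    frame["consolidated_status"] = [
        "" if r.consolidated is None else r.consolidated.value for r in results
    ]
    frame["flags"] = [";".join(sorted(r.flags)) for r in results]
    frame.to_csv(path, index=False, sep=schema.delimiter, encoding="utf-8")


def write_cohort(
    records: Sequence[ParticipantRecord],
    path: str | Path,
    schema: CohortSchema | None = None,
) -> None:
    """Write plain records (no derived columns) to ``path``."""
    records_to_frame(records, schema).to_csv(
        path, index=False, sep=(schema or CohortSchema()).delimiter, encoding="utf-8"
    )
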